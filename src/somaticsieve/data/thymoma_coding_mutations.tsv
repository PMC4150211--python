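Gene	Gene impact	Protein location	Prediction of impact	Coordinates (hg19)
ALDH1A3	Missense	T51I	SIFT, Condel	chr15: 101 425 524 snp C>T
AP3M2	Missense	H19N	Polyphen, SIFT, Condel	chr8: 42 012 260 snp C>A
ASXL1	Frameshift	E657fs	Damaging	chr20: 31 022 486 del G>-
ATRIP	Missense	G21R	SIFT, Condel	chr3: 48 488 310 snp G>C
DNAJB12	Missense	L292V	Neutral	chr10: 74 098 021 snp G>C
DNMT3A	Missense	G728D	Polyphen, SIFT, Condel	chr2: 25 463 310 snp C>T
FAM193A	Frameshift	H303fs	Damaging	chr4: 2 648 428 ins ->T
GRM5	Nonsense	R351*	Damaging	chr11: 88 386 432 snp G>A
HECTD3	Missense	R14P	SIFT, Condel	chr1: 45 476 889 snp C>G
JPH2	Missense	V239M	Neutral	chr20: 42 788 712 snp C>T
MAGI2	Missense	R375Q	Condel	chr7: 77 807 386 snp C>T
MORC1	Missense	R597H	Neutral	chr3: 108 724 077 snp C>T
NCALD	Missense	R181C	Polyphen, SIFT, Condel	chr8: 102 701 578 snp G>A
PVRL1	Missense	L360V	Neutral	chr11: 119 510 648 snp G>C
SH3BP1	Missense	T626P	Neutral	chr22: 38 051 466 snp A>C
TBC1D8	Missense	R144G	Neutral	chr2: 101 670 771 snp T>C
TBKBP1	Missense	K75T	Polyphen, SIFT, Condel	chr17: 45 773 702 snp A>C
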