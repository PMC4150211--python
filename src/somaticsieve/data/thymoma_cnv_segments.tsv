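Type	Coordinates	Size (kb)	Dosage	Overlapping genes
Gain	chr1: 470 001–600 000	130	5	None
Gain	chr2: 145 130 001–145 310 000	180	3	ZEB2
Gain	chr2: 158 260 001–158 370 000	110	3	CYTIP
Gain	chr2: 192 770 001–192 940 000	170	3	TMEFF2
Gain	chr2: 240 110 001–240 240 000	130	3	HDAC4
Gain	chr4: 153 220 001–153 320 000	100	3	FBXW7
Gain	chr7: 27 120 001–27 240 000	120	3	HOXA gene cluster, MIR196B
Gain	chr7: 38 290 001–38 390 000	100	3	TARP
Gain	chr8: 142 200 001–142 320 000	120	3	SLC45A4, DENND3
Gain	chr9: 75 690 001–75 830 000	140	3	ANXA1, ALDH1A1
Gain	chr9: 139 420 001–139 520 000	100	3	NOTCH1, MIR4674
Gain	chr13: 114 740 001–114 920 000	180	3	RASA3
Gain	chr15: 99 410 001–99 510 000	100	3	IGF1R
Gain	chr17: 80 740 001–80 920 000	180	3	TBCD, ZNF750, B3GNTL1
Loss	chr19: 54 070 001–54 200 000	130	1	ZNF331, DPRX, MIR520 cluster
Gain	chr21: 44 690 001–44 900 000	210	3	SIK1
Gain	chr22: 46 380 001–46 550 000	170	3	MIRLET7B, MIR3619, MIR4763
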