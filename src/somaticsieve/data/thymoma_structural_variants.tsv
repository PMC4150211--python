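Type	State	Breakpoint 1	Breakpoint 2	Overlapping genes
Coamplicon	Bal	chr16: 26 382 735–26 386 932	chr16: 26 382 736–26 386 932	None
Inversion	Unbal	chr2: 87 651 839–87 656 090	chr2: 90 482 288–90 485 529	Many
Inversion	Unbal	chr2: 33 141 477–33 141 679	chr2: 242 819 853–242 820 060	Many
Coamplicon	Bal	chr7: 158 706 424–158 710 034	chr7: 158 706 425–158 710 035	WDR60
Insertion	Bal	chr7: 158 704 999–158 708 434	chr7: 158 705 000–158 709 994	WDR60
Insertion	Bal	chr9: 139 994 967–139 997 831	chr9: 139 994 968–139 998 202	MAN1B1
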