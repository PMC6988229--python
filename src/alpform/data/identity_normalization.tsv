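identity	homologs	is_alp	partial
C-terminal TaALP-by-7DS/4AL	C-terminal TaALP-by-7DS;C-terminal TaALP-by-4AL	1	1
TaALP-by-7DS/4AL/7AS	TaALP-by-7DS;TaALP-by-4AL;TaALP-by-7AS	1	0
TaALP-by-7DS/4AL	TaALP-by-7DS;TaALP-by-4AL	1	0
TaALP-ay-7DS	TaALP-ay-7DS	1	0
TaALP-ay-4AL	TaALP-ay-4AL	1	0
TaALP-bx-7DS/4AL	TaALP-bx-7DS;TaALP-bx-4AL	1	0
TaALP-bx-7AS	TaALP-bx-7AS	1	0
TaALP-ax-4AL	TaALP-ax-4AL	1	0
TaALP-ax-7AS	TaALP-ax-7AS	1	0
TaALP-ax-7DS	TaALP-ax-7DS	1	0
TaALP-ax-7AS peptide 1	TaALP-ax-7AS	1	1
TaALP-ax-7AS peptide 2	TaALP-ax-7AS	1	1
N	N	0	0
avenin-3-1A	avenin-3-1A	0	0
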