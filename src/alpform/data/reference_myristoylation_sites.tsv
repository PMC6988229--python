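alp_name	start	end	site
TaALP-ay-4AL	101	106	GQSFGQ
TaALP-ay-7AS	102	107	GQSFSQ
TaALP-ay-7DS	102	107	GQSFGQ
TaALP-ay-7DS	113	118	GQSFGQ
TaALP-ax-4AL	110	115	GQRFGQ
TaALP-ax-4AL	121	126	GQSFGQ
TaALP-ax-7AS	104	109	GQRFGQ
TaALP-ax-7AS	115	120	GQSFGQ
TaALP-ax-7DS	108	113	GQSFGQ
TaALP-by-4AL	62	67	GTPFSQ
TaALP-by-4AL	239	244	GLRMSL
TaALP-by-7AS_Mace	239	244	GLRMSL
TaALP-by-7DS	239	244	GLRMSL
TaALP-bx-7AS_Spitfire	233	238	GMYQAQ
TaALP-c-4AL	28	33	GSEQCQ
TaALP-c-4AL	115	120	GMSQSQ
TaALP-c-7AS	142	147	GIPMAR
TaALP-c-7AS	150	155	GGWVCE
TaALP-c-7DS	28	33	GSEQCQ
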