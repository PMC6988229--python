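cultivar	alp_name	n_residues	n_cys	main_hplc_peak	retention_time_min	mw_calc_kda	mw_alkylated_kda	mw_cleaved_da	mw_cleaved_alkylated_da
Mace	C-terminal TaALP-by-7DS	152	11	Mace-8	17.03	17.39	18.54
Mace	C-terminal TaALP-by-4AL	152	11	Mace-8	17.03	17.44	18.60
Mace	TaALP-ay-7DS	154	14	Mace-11	20.24	16.96	18.42	9133.37	10070.63
Mace	TaALP-ay-4AL	153	14	Mace-17	22.94	17.01	18.47	9198.44	10135.7
Mace	TaALP-ax-4AL	162	14	Mace-20	24.72	18.01	19.47	10198.54	11135.8
Mace	TaALP-ax-7AS	156	14	Mace-26	28.75	17.29	18.75	9579.93	10517.19
Mace	TaALP-ax-7DS	149	14	Mace-29	30.94	16.44	17.90	9914.25	10851.51
Mace	TaALP-by-7DS	261	19	Mace-8-12	17.03-21.02	29.97	31.95	25439.88	27406.12
Mace	TaALP-by-4AL	261	19	Mace-8-12	17.03-21.03	29.87	31.84	24533.1	26095.2
Mace	TaALP-by-7AS	261	19	Mace-8-12	17.03-21.04	29.69	31.67	25347.9	27014.14
Mace	TaALP-bx-7DS	266	18	Mace-13-23	21.61-26.34	30.59	32.46
Mace	TaALP-bx-4AL	267	19	Mace-13-24	21.61-26.35	30.88	32.86
Spitfire	C-terminal TaALP-by-7DS	152	11	Spitfire-8	17.46	17.39	18.54
Spitfire	C-terminal TaALP-by-4AL	152	11	Spitfire-8	17.46	17.44	18.60
Spitfire	TaALP-ay-7DS	154	14	Spitfire-11	20.26	16.96	18.42	9133.37	10070.63
Spitfire	TaALP-ay-4AL	153	14	Spitfire-15	23.14	17.01	18.47	9198.44	10135.7
Spitfire	TaALP-ax-4AL	162	14	Spitfire-21	27.67	17.74	19.20	10157.53	11094.79
Spitfire	TaALP-ax-7AS	156	14	Spitfire-23	29.37	17.29	18.75	9579.93	10517.19
Spitfire	TaALP-ax-7DS	149	14	Spitfire-25	31.11	16.44	17.90	9914.25	10851.51
Spitfire	TaALP-by-7DS	261	19	Spitfire-8	17.46	29.97	31.95	25439.88	27406.12
Spitfire	TaALP-by-4AL	261	19	Spitfire-8	17.46	29.87	31.84	24533.1	26095.2
Spitfire	TaALP-bx-7DS	266	18	Spitfire-13-19	21.97-26.60	30.59	32.46
Spitfire	TaALP-bx-4AL	267	19	Spitfire-13-19	21.97-26.60	30.88	32.86
Spitfire	TaALP-bx-7AS	266	18	Spitfire-13-19	21.97-26.60	30.52	32.39	24853.38	26519.62
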