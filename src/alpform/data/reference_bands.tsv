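cultivar	band_label	hplc_peak	retention_time_min	identity
Mace	8b	Mace-8	17.035	C-terminal TaALP-by-7DS/4AL
Mace	8a	Mace-8	17.035	TaALP-by-7DS/4AL/7AS
Mace	9b	Mace-9	18.325	C-terminal TaALP-by-7DS/4AL
Mace	9a	Mace-9	18.325	TaALP-by-7DS/4AL/7AS
Mace	10a	Mace-10	19.445	C-terminal TaALP-by-7DS/4AL
Mace	10b	Mace-10	19.445	TaALP-ay-7DS
Mace	11b	Mace-11	20.247	TaALP-ay-7DS
Mace	11a	Mace-11	20.247	TaALP-by-7DS/4AL/7AS
Mace	12a	Mace-12	21.017	TaALP-by-7DS/4AL/7AS
Mace	13a	Mace-13	21.612	TaALP-bx-7DS/4AL
Mace	14a	Mace-14	21.967	TaALP-bx-7DS/4AL
Mace	15a	Mace-15	22.414	TaALP-bx-7DS/4AL
Mace	16a	Mace-16	22.659	TaALP-bx-7DS/4AL
Mace	17b	Mace-17	22.941	TaALP-ay-4AL
Mace	17a	Mace-17	22.941	TaALP-bx-7DS/4AL
Mace	18b	Mace-18	23.375	TaALP-ay-4AL
Mace	18a	Mace-18	23.375	TaALP-bx-7DS/4AL
Mace	19a	Mace-19	24.414	TaALP-ax-4AL
Mace	20b	Mace-20	24.725	TaALP-ax-4AL
Mace	20a	Mace-20	24.725	TaALP-bx-7DS/4AL
Mace	21a	Mace-21	25.529	TaALP-bx-7DS/4AL
Mace	24a	Mace-24	27.387	TaALP-ax-7AS
Mace	25a	Mace-25	27.798	TaALP-ax-7AS
Mace	26a	Mace-26	28.754	TaALP-ax-7AS
Mace	27a	Mace-27	29.614	TaALP-ax-7AS
Mace	28b	Mace-28	30.178	TaALP-ax-7DS
Mace	28a	Mace-28	30.178	TaALP-ax-7AS
Mace	29a	Mace-29	30.914	TaALP-ax-7DS
Mace	30a	Mace-30	31.864	TaALP-ax-7DS
Spitfire	7b	Spitfire-7	17.467	C-terminal TaALP-by-7DS/4AL
Spitfire	7a	Spitfire-7	17.467	TaALP-by-7DS/4AL
Spitfire	9a	Spitfire-9	20.266	TaALP-ay-7DS
Spitfire	10a	Spitfire-10	21.406	TaALP-ay-7DS
Spitfire	13b	Spitfire-12	22.796	TaALP-ay-4AL
Spitfire	12a	Spitfire-12	22.796	TaALP-bx-7DS/4AL
Spitfire	13c	Spitfire-13	23.147	TaALP-ay-4AL
Spitfire	13b	Spitfire-13	23.147	TaALP-bx-7DS/4AL
Spitfire	13a	Spitfire-13	23.147	TaALP-bx-7DS/4AL
Spitfire	14a	Spitfire-14	25.004	TaALP-bx-7DS/4AL
Spitfire	16a	Spitfire-16	26.15	TaALP-bx-7DS/4AL
Spitfire	16b	Spitfire-16	26.15	TaALP-bx-7DS/4AL
Spitfire	17a	Spitfire-17	26.601	TaALP-bx-7AS
Spitfire	17a	Spitfire-17	26.601	TaALP-bx-7DS/4AL
Spitfire	17a	Spitfire-17	26.601	TaALP-bx-7DS/4AL
Spitfire	18a	Spitfire-18	27.305	TaALP-ax-4AL
Spitfire	19c	Spitfire-19	27.676	TaALP-ax-7AS peptide 1
Spitfire	19b	Spitfire-19	27.676	N
Spitfire	19a	Spitfire-19	27.676	TaALP-ax-4AL
Spitfire	20b	Spitfire-20	28.743	TaALP-ax-7AS
Spitfire	20a	Spitfire-20	28.743	TaALP-ax-4AL
Spitfire	21a	Spitfire-21	29.378	TaALP-ax-7AS
Spitfire	22c	Spitfire-22	30.058	TaALP-ax-7AS peptide 2
Spitfire	22b	Spitfire-22	30.058	TaALP-ax-7DS
Spitfire	22a	Spitfire-22	30.058	TaALP-ax-7AS
Spitfire	23a	Spitfire-23	31.115	TaALP-ax-7DS
Spitfire	23a	Spitfire-23	31.115	TaALP-ax-7DS
Spitfire	24a	Spitfire-24	32.004	TaALP-ax-7DS
Spitfire	26b	Spitfire-26	33.1	avenin-3-1A
Spitfire	26a	Spitfire-26	33.1	avenin-3-1A
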