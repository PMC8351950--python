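chrom	chrom_size	size_painted	paint_start	paint_stop	density	total_oligos	gene_density
4	18737234	18639239	282	18639521	1.5	26841	39.7
7	13944894	13868845	35931	13904776	3	42625	36.0
15	18440292	18354755	21089	18375844	1	17756	43.6
16	14337292	14275583	27737	14303320	1.5	20190	43.7
17	16840672	16806551	9415	16815966	1.5	23834	38.3
23	21465692	21339065	123188	21462253	1.5	30506	35.8
Z/1	20666287	20578020	37936	20615956	1.5	29784	32.2
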