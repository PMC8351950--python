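chrom	stripe	paint_start	paint_stop	size_mb
7	tel1	35931	2809682	2.77
7	mid	5587874	8357288	2.76
7	tel2	11131025	13904776	2.77
15	tel1	21089	3684775	3.66
15	mid	7380341	11061106	3.68
15	tel2	14748412	18375844	3.62
16	tel1	27737	2865990	2.84
16	mid	5732698	8598132	2.87
16	tel2	11464265	14303320	2.84
23	tel1	123188	1638259	1.51
23	mid	9909172	11556867	1.65
23	tel2	19815237	21462253	1.65
Z	tel1	37936	1589202	1.55
Z	mid	9538407	11119201	1.58
Z	tel2	19078122	20615956	1.53
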