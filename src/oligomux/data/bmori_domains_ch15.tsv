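domain	start	stop	size
inactive	21089	200000	178912
active	250001	850000	600000
active	900001	1000000	100000
inactive	1000001	1400000	400000
active	1400001	1950000	550000
inactive	1950001	2250000	300000
active	2250001	2550000	300000
inactive	2550001	2800000	250000
active	2850001	3200000	350000
inactive	3200001	3500000	300000
active	3550001	3850000	300000
inactive	3850001	3900000	50000
active	3950001	4100000	150000
inactive	4100001	4250000	150000
active	4250001	4350000	100000
inactive	4350001	4650000	300000
active	4650001	4750000	100000
inactive	4750001	4950000	200000
inactive	5000001	5150000	150000
active	5150001	5250000	100000
inactive	5300001	5350000	50000
active	5350001	6100000	750000
inactive	6100001	6200000	100000
active	6250001	6500000	250000
inactive	6500001	6700000	200000
active	6700001	6850000	150000
inactive	6900001	7100000	200000
active	7100001	7300000	200000
inactive	7300001	7550000	250000
active	7550001	7800000	250000
inactive	7800001	8100000	300000
active	8100001	8300000	200000
inactive	8400001	8650000	250000
active	8650001	8750000	100000
inactive	8750001	8800000	50000
active	8850001	8900000	50000
inactive	8900001	9100000	200000
active	9100001	9500000	400000
inactive	9500001	9550000	50000
active	9600001	9750000	150000
active	9800001	9950000	150000
inactive	10000001	10500000	500000
active	10500001	11200000	700000
active	11350001	11400000	50000
inactive	11400001	11500000	100000
active	11500001	11950000	450000
inactive	11950001	12000000	50000
active	12050001	12200000	150000
inactive	12200001	12250000	50000
active	12300001	12500000	200000
inactive	12500001	12600000	100000
active	12600001	12850000	250000
inactive	12850001	12950000	100000
active	12950001	13400000	450000
inactive	13450001	13600000	150000
active	13650001	13750000	100000
inactive	13750001	14150000	400000
inactive	14200001	14850000	650000
active	14900001	15050000	150000
inactive	15100001	15250000	150000
active	15300001	15500000	200000
inactive	15550001	15600000	50000
active	15600001	15750000	150000
inactive	15750001	16000000	250000
inactive	16050001	16350000	300000
inactive	16400001	17850000	1450000
inactive	17900001	18100000	200000
active	18150001	18200000	50000
inactive	18200001	18250000	50000
active	18300001	18350000	50000
inactive	18350001	18375844	25844
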