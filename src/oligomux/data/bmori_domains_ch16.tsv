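domain	start	stop	size
inactive	27737	50000	22264
active	50001	150000	100000
inactive	150001	250000	100000
active	250001	350000	100000
inactive	350001	650000	300000
active	700001	1350000	650000
inactive	1400001	1700000	300000
active	1700001	2300000	600000
inactive	2300001	2400000	100000
active	2400001	2700000	300000
inactive	2700001	3200000	500000
active	3200001	3600000	400000
inactive	3600001	4050000	450000
active	4050001	4200000	150000
inactive	4200001	4500000	300000
active	4500001	4600000	100000
active	4700001	4750000	50000
inactive	4750001	4800000	50000
active	4900001	4950000	50000
active	5000001	5250000	250000
inactive	5250001	5600000	350000
active	5600001	6000000	400000
inactive	6000001	6150000	150000
active	6200001	6250000	50000
active	6300001	6500000	200000
active	6550001	6650000	100000
inactive	6650001	6850000	200000
active	6850001	7000000	150000
inactive	7050001	7950000	900000
inactive	8000001	8500000	500000
active	8550001	8750000	200000
inactive	8800001	8900000	100000
active	8900001	9400000	500000
inactive	9400001	9450000	50000
active	9500001	10100000	600000
inactive	10100001	11450000	1350000
active	11450001	11550000	100000
inactive	11550001	11900000	350000
active	11950001	12250000	300000
inactive	12250001	12400000	150000
active	12400001	12500000	100000
inactive	12500001	12700000	200000
active	12750001	13200000	450000
inactive	13250001	13800000	550000
active	13800001	14100000	300000
inactive	14100001	14303320	203320
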