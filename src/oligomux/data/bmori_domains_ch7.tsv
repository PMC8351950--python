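domain	start	stop	size
inactive	35931	800000	764070
active	800001	900000	100000
inactive	1000001	1100000	100000
active	1100001	1250000	150000
inactive	1300001	1500000	200000
active	1500001	1600000	100000
inactive	1600001	1700000	100000
active	1700001	1850000	150000
inactive	1850001	1900000	50000
active	1950001	2000000	50000
inactive	2000001	2300000	300000
inactive	2400001	2600000	200000
active	2600001	2700000	100000
inactive	2700001	3350000	650000
active	3400001	3650000	250000
inactive	3650001	3900000	250000
active	3900001	4000000	100000
inactive	4000001	4550000	550000
active	4550001	4650000	100000
inactive	4650001	4950000	300000
active	4950001	5400000	450000
inactive	5450001	5800000	350000
active	5900001	6050000	150000
inactive	6050001	6250000	200000
inactive	6300001	6450000	150000
active	6450001	6550000	100000
inactive	6550001	6650000	100000
active	6700001	6800000	100000
active	6850001	7150000	300000
inactive	7150001	7400000	250000
active	7400001	7600000	200000
inactive	7600001	7900000	300000
active	7950001	8200000	250000
inactive	8250001	8750000	500000
inactive	8800001	9050000	250000
active	9050001	9300000	250000
inactive	9350001	9400000	50000
active	9400001	9550000	150000
inactive	9650001	10800000	1150000
active	10850001	11100000	250000
active	11150001	11400000	250000
inactive	11400001	11650000	250000
active	11650001	11950000	300000
inactive	11950001	12300000	350000
active	12300001	12600000	300000
inactive	12600001	12700000	100000
active	12700001	12750000	50000
inactive	12800001	12950000	150000
active	12950001	13150000	200000
inactive	13150001	13250000	100000
active	13350001	13450000	100000
inactive	13500001	13650000	150000
active	13700001	13849955	149955
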