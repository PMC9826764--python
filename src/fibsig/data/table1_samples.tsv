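sample_id	patient_id	tissue	condition	sex	age
1HI	B1_B2	ILEAL	CI	F	61
2HI	B1_B2	SIGMOID	CI	F	61
13UC	B13_B14	ILEAL	UC	F	52
14UC	B13_B14	SIGMOID	UC	F	52
15UC	B15_B16	ILEAL	UC	F	53
16UC	B15_B16	SIGMOID	UC	F	53
17UC	B17_B18	ILEAL	UC	M	27
18UC	B17_B18	SIGMOID	UC	M	27
19UC	B19_B20	ILEAL	UC	M	33
20UC	B19_B20	SIGMOID	UC	M	33
21UC	B21_22	ILEAL	UC	M	67
22UC	B21_22	SIGMOID	UC	M	67
23UC	B23_B24	ILEAL	UC	F	61
24UC	B23_B24	SIGMOID	UC	F	61
3CD	B3_B4	ILEAL	CD	F	52
4CD	B3_B4	SIGMOID	CD	F	52
31CD	B31_B32	ILEAL	CD	F	29
32CD	B31_B32	SIGMOID	CD	F	29
33CD	B33_B34	ILEAL	CD	M	51
34CD	B33_B34	SIGMOID	CD	M	51
35CD	B35_B36	ILEAL	CD	F	60
36CD	B35_B36	SIGMOID	CD	F	60
41HI	B41_B42	ILEAL	CI	F	62
42HI	B41_B42	SIGMOID	CI	F	62
43HI	B43_B44	ILEAL	CI	F	54
44HI	B43_B44	SIGMOID	CI	F	54
45HI	B45_B46	ILEAL	CI	M	57
46HI	B45_B46	SIGMOID	CI	M	57
47HI	B47_B48	ILEAL	CI	M	69
48HI	B47_B48	SIGMOID	CI	M	69
49HI	B49_B50	ILEAL	CI	M	58
50HI	B49_B50	SIGMOID	CI	M	58
5CD	B5_B6	ILEAL	CD	M	44
6CD	B5_B6	SIGMOID	CD	M	44
51HI	B51_B52	ILEAL	CI	F	72
52HI	B51_B52	SIGMOID	CI	F	72
53HI	B53_B54	ILEAL	CI	M	74
54HI	B53_B54	SIGMOID	CI	M	74
55HI	B55_B56	ILEAL	CI	M	55
56HI	B55_B56	SIGMOID	CI	M	55
7CD	B7_B8	ILEAL	CD	M	28
8CD	B7_B8	SIGMOID	CD	M	28
10CD	B9_B10	SIGMOID	CD	F	35
9CD	B9_B10	ILEAL	CD	F	35
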