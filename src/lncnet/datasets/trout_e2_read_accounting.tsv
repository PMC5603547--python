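sample	group	time_h	replicate	raw_reads	clean_reads	mapped_reads
CTRL_24_1	CTRL	24	1	36802826	35432594	31145250
CTRL_24_2	CTRL	24	2	61291464	52228282	46274258
CTRL_24_3	CTRL	24	3	59111132	56868138	50328302
CTRL_24_4	CTRL	24	4	50601976	48340122	42974368
CTRL_72_1	CTRL	72	1	63019266	60702946	54389838
CTRL_72_2	CTRL	72	2	60452644	58114660	52186986
CTRL_72_3	CTRL	72	3	51642380	49378116	44045278
CTRL_72_4	CTRL	72	4	63821958	60981886	53786022
E2_24_1	E2	24	1	61743118	59403804	52394128
E2_24_2	E2	24	2	37513122	35786668	30186188
E2_24_3	E2	24	3	42203620	40341512	34895386
E2_24_4	E2	24	4	47655922	45563586	40232838
E2_72_1	E2	72	1	36221406	34809018	30144800
E2_72_2	E2	72	2	41421664	39634688	34878528
E2_72_3	E2	72	3	38926574	37367184	31874208
E2_72_4	E2	72	4	37055964	34537730	29586296
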