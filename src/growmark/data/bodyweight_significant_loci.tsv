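SNP	CHR	POS	REF	ALT	Method
Chr2_26654033_A_T	2	26654033	A	T	MLM
Chr2_26654919_A_C	2	26654919	A	C	MLM
Chr2_27438480_A_C	2	27438480	A	C	MLM
Chr3_2761657_T_C	3	2761657	T	C	FarmCPU
Chr4_12232732_T_G	4	12232732	T	G	MLM
Chr5_11085808_G_A	5	11085808	G	A	MLM
Chr8_3880709_T_C	8	3880709	T	C	FarmCPU
Chr9_27523974_C_G	9	27523974	C	G	MLM
Chr9_7377675_T_C	9	7377675	T	C	MLM
Chr10_27276393_A_G	10	27276393	A	G	MLM
Chr10_3129797_A_T	10	3129797	A	T	BLINK, FarmCPU, MLM
Chr11_14239856_T_A	11	14239856	T	A	MLM
Chr11_17764223_A_G	11	17764223	A	G	MLM
Chr11_22966715_G_C	11	22966715	G	C	MLM
Chr11_22971482_G_A	11	22971482	G	A	MLM
Chr13_21261594_G_A	13	21261594	G	A	MLM
Chr13_6999213_T_A	13	6999213	T	A	MLM
Chr14_23603173_T_C	14	23603173	T	C	MLM
Chr19_24824698_A_G	19	24824698	A	G	MLM
Chr20_18903685_T_C	20	18903685	T	C	MLM
Chr20_21148254_A_G	20	21148254	A	G	BLINK, MLM
Chr20_542292_A_G	20	542292	A	G	BLINK
Chr21_21195384_G_C	21	21195384	G	C	MLM
Chr22_6261294_A_G	22	6261294	A	G	MLM
Chr23_4132299_T_C	23	4132299	T	C	MLM
Chr23_4858864_A_G	23	4858864	A	G	FarmCPU
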