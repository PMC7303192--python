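patient_id	age	sex	calcium_mm3	av_gradient_mmhg	size_mm	fluoro_diam_mm	diff_mm	diff_pct	pvl_text
S-1	85	M	385	46	29	25.3	1.0	3.8	trivial in NCC
S-2	77	M	627	48	29	27.1	-0.7	-2.7	trivial in NCC
S-3	78	M	220	67	26	26.3	-0.4	-1.6	trivial in NCC
S-4	59	F	1121	67	26	23.2	0.8	3.6	trivial in RCC
S-5	69	F	690	70	26	23.7	1.8	7.3	1 trivial jet in RCC-LCC, 1 trivial jet in NCC
S-6	76	M	751	70	26	25.0	-0.1	-0.2	No PVL
S-7	85	M	527	72	26	25.1	0.6	2.5	trivial in RCC, almost absent
S-8	78	M	1997	72	26	25.4	0.9	3.3	1 mild jet in RCC, 1 trivial jet in NCC
S-9	88	F	380	73	23	21.4	0.8	3.5	1 trivial jet LCC-NCC, 1 mild+ jet RCC-NCC
S-10	83	M	1478	76	29	25.5	0.5	1.8	trivial in NCC-RCC
S-11	78	F	221	78	26	22.7	2.7	11.2	trivial in RCC-LCC
S-12	83	M	553	83	26	25.6	-0.6	-2.3	Trivial
S-13	81	M	824	100	29	26.4	-0.1	-0.3	1 mild jet in RCC, 1 trivial jet in RCC-NCC
S-14	90	F	385	103	26	23.5	1.3	5.5	No PVL
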