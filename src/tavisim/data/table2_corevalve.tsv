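patient_id	age	sex	calcium_mm3	av_gradient_mmhg	size_mm	fluoro_diam_mm	diff_mm	diff_pct	pvl_text
C-1	91	F	26	14	26	21.1	0.1	0.4	No PVL*
C-2	64	F	957	31	26	19.7	0.6	2.8	1 mild jet in RCC-NCC 1 moderate jet in NCC-LCC
C-3	68	M	201	35	29	23.1	0.9	3.9	No PVL but free echo space
C-4	75	M	109	47	29	22.6	0.8	3.6	1 trivial jet in NCC 1 mild jet in LCC-NCC
C-5	78	M	431	61	29	22.2	1.6	7.1	1 trivial jet in NCC-LCC 1 mild jet in RCC
C-6	90	F	737	61	26	21.7	-0.4	-2.0	mild-moderate in LCC
C-7	74	M	1357	67	29	23.7	0.2	0.7	mild-moderate in RCC
C-8	68	M	1245	70	29	22.2	1.8	7.6	mild in NCC
C-9	81	M	922	73	29	23.6	0.1	0.6	trivial-mild in NCC-RCC
C-10	92	M	1098	76	26	22.0	-0.2	-0.7	1trivial jet in RCC 1 mild-moderate jet in LCC-NCC
C-11	91	M	596	83	26	19.2	1.4	7.1	trivial in LCC-NCC
C-12	87	M	1508	83	29	23.7	1.3	5.3	trivial in NCC-RCC
C-13	93	F	344	90	26	22.6	0.1	0.6	mild in NCC-LCC
C-14	89	F	53	93	26	19.2	0.3	1.4	trivial in RCC
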