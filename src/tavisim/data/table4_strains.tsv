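patient_id	strain_avg_pct	strain_absmax_pct	strain_nccrcc_pct
C-1	4.5	12.9	15.7
C-2	2.1	9.7	9.7
C-3	3.2	9.9	14.8
C-4	2.1	22.9	22.9
C-5	1.5	5.3	9.9
C-6	1.2	8.4	8.4
C-7	2.3	9.4	12.7
C-8	1.4	4.6	5.1
C-9	1.7	4.9	10.8
C-10	2.6	14.0	14.0
C-11	2.5	15.4	15.4
C-12	2.2	14.0	14.0
C-13	2.9	15.3	15.3
C-14	4.7	24.5	24.5
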