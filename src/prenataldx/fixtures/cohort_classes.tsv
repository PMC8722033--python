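class	cases	double	cnv_only	variant_only
Cardiac	265	3	30	38
Chest and respiratory tract	43	0	3	1
CNS	116	0	8	11
Facial	127	1	7	9
Gastrointestinal tract and AW	42	1	5	2
Genitourinary	94	0	6	7
Hydrops	31	2	3	3
Increased NT	20	0	3	4
Skeletal	94	3	9	27
Multisystem	127	0	25	16
Total	959	10	99	118
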