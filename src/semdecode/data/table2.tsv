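participant	full_accuracy	targeted_accuracy	reduction	ifg_features	sm1_features	other_features	all_features
P1	85.0	57.5	27.5	9	22	142	173
P2	78.8	75.0	3.8	21	4	89	114
P3	78.8	60.0	18.8	14	2	60	76
P4	76.3	83.8	-7.5	21	13	33	67
P5	76.3	71.3	5.0	23	4	72	99
P6	72.5	58.8	13.8	23	4	72	99
P7	63.8	71.3	-7.5	17	8	75	100
P8	63.8	67.5	-3.8	29	5	51	85
P9	62.5	68.8	-6.3	16	6	61	83
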