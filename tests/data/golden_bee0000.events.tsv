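# apistrack-events v1
#bee_id	bee0000
#csplus_odor	linalool
#training_order	ABBABAAB
#test_order	BAAB
#iti_s	5.0
#stimulus_duration_s	4.0
#test_gap_s	10.0
#t_first_s	5.0
#side_assignments	-1,1,-1,1,1,-1,-1,1
#shock_pulse_rate_hz	1.2
#shock_pulse_width_s	0.2
#shock_voltage_v	10.0
index	phase	t_stim_s	duration_s	odor	role	side_index	shock_onset_s	shock_dur_s
0	training	5.0	4.0	linalool	CS+	-1	2.0	3.0
1	training	14.0	4.0	nonanol	CS-	1	NA	NA
2	training	23.0	4.0	nonanol	CS-	-1	NA	NA
3	training	32.0	4.0	linalool	CS+	1	1.0	3.0
4	training	41.0	4.0	nonanol	CS-	1	NA	NA
5	training	50.0	4.0	linalool	CS+	-1	1.0	3.0
6	training	59.0	4.0	linalool	CS+	-1	1.0	3.0
7	training	68.0	4.0	nonanol	CS-	1	NA	NA
8	test	82.0	4.0	nonanol	CS-	-1	NA	NA
9	test	91.0	4.0	linalool	CS+	1	NA	NA
10	test	100.0	4.0	linalool	CS+	-1	NA	NA
11	test	109.0	4.0	nonanol	CS-	-1	NA	NA
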