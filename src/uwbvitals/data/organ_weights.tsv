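species	sex	body_kg	lungs_g	heart_g
human	M	75	1136	380
human	F	50	797	243
dog	M	9.89	86.13	76.86
dog	F	8.74	77.63	68.52
cat	MF	1.542	15	10
rabbit	MF	2.587	13.72	9.23
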