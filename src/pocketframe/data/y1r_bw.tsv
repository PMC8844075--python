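chain	residue_number	bw_code
R	86	2.50
R	93	2.57
R	97	2.61
R	100	2.64
R	120	3.32
R	124	3.36
R	128	3.40
R	138	3.50
R	142	3.54
R	163	4.50
R	173	4.60
R	176	4.63
R	208	5.35
R	211	5.38
R	212	5.39
R	219	5.46
R	223	5.50
R	231	5.58
R	234	5.61
R	238	5.65
R	260	6.32
R	261	6.33
R	265	6.37
R	272	6.44
R	276	6.48
R	279	6.51
R	282	6.54
R	283	6.55
R	286	6.58
R	287	6.59
R	298	7.31
R	302	7.35
R	306	7.39
R	310	7.43
R	317	7.50
R	320	7.53
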