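helix_id	chain	start	end
1	R	41	65
2	R	72	100
3	R	110	144
4	R	152	176
5	R	206	241
6	R	258	288
7	R	298	323
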