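sample	population	sequenced	genotyped
S08-0428	Britain	1	0
S08-0433	Britain	1	0
S08-0436	Britain	1	0
S10-0036	Iraq	1	1
S10-0039	Iraq	1	0
S14-1369	Iraq	1	0
S12-0237	Yamal, Siberia	1	1
S12-0241	Yamal, Siberia	1	1
S12-0244	Yamal, Siberia	1	1
S12-1162	Alaska, USA	1	0
S12-1600	Bylott Island, Canada	1	1
S12-1607	Eastern Canada	1	1
S12-1608	Eastern Canada	1	1
S14-0418	Eastern Canada	1	0
S14-0432	Eastern Canada	1	0
M1	Lassen Co, CA, USA	1	0
S12-1176	Gunnison, CO, USA	1	1
S12-1163	Alaska, USA	0	1
S12-1161	Alaska, USA	0	1
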