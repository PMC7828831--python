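sample	population	G_343GC	G_690CT	R_156AC	R_503CT	R_793CT	12_709CT	20_238CT	21_687CT	27_204GT	31_365AT	DBY4_-54CG	SRY_1197CT	31_209AT	11_535AG	21_982GA	21_1014TC	24_878TC	24_1434TA	28_458GA	28_524CA	29_231AC	K_79CA	K_527TC	MS41A_209CT	MS41A_248AG	MS41B_221CT	N_558TG	Q_311TG	Q_322AG	Q_613CT	R_805G
Ancestral		G	C	C	C	C	T	T	C	T	A	G	C	A	A	G	T	T	T	G	C	A	C	T	C	A	C	T	T	A	C	G
S08-0428	Britain	C	T	-	-	-	-	C	-	-	T	-	-	-	-	A	-	-	A	-	A	C	A	C	-	-	-	-	-	-	-	-
S08-0433	Britain	C	T	-	-	-	-	C	-	-	T	-	-	-	-	A	-	-	A	-	A	C	A	C	-	-	-	-	-	-	-	-
S08-0436	Britain	C	T	-	-	-	-	C	-	-	T	-	-	-	-	A	-	-	A	-	A	C	A	C	-	-	-	-	-	-	-	-
S10-0036	Iraq	C	-	-	-	-	-	C	-	-	T	-	-	-	G	A	C	-	A	-	A	C	A	C	-	-	T	-	-	-	T	A
S10-0039	Iraq	C	-	-	-	-	-	C	-	-	T	-	-	-	G	A	C	-	A	-	A	C	A	C	-	-	T	-	-	-	T	A
S14-1369	Iraq	C	-	-	-	-	-	C	-	-	T	-	-	-	G	A	C	-	A	-	A	C	A	C	-	-	-	-	-	-	T	A
S12-0237	Yamal, Siberia	-	-	A	T	T	C	-	T	G	-	-	-	-	-	-	-	-	-	A	-	C	-	-	-	-	T	G	G	G	-	-
S12-0241	Yamal, Siberia	-	-	A	T	T	C	-	T	G	-	-	-	-	-	-	-	-	-	A	-	C	-	-	-	-	T	G	G	G	-	-
S12-0244	Yamal, Siberia	-	-	A	T	T	C	-	T	G	-	-	-	-	-	-	-	-	-	A	-	C	-	-	-	-	T	G	G	G	-	-
S12-1162	Alaska, USA	-	-	A	T	T	C	-	-	G	-	C	T	-	-	-	-	C	-	A	-	C	-	-	T	-	T	G	G	G	-	-
S12-1600	Bylott Island, Canada	-	-	A	T	T	C	-	-	G	-	C	T	T	-	-	-	C	-	A	-	C	-	-	T	G	T	G	G	G	-	-
S12-1607	Eastern Canada	-	-	A	T	T	C	-	-	G	-	C	T	-	-	-	-	C	-	A	-	C	-	-	T	-	T	G	G	G	-	-
S12-1608	Eastern Canada	-	-	A	T	T	C	-	-	G	-	C	T	-	-	-	-	C	-	A	-	C	-	-	-	-	T	G	G	G	-	-
S14-0418	Eastern Canada	-	-	A	T	T	C	-	-	G	-	C	T	T	-	-	-	C	-	A	-	-	-	-	T	G	T	G	G	G	-	-
S14-0432	Eastern Canada	-	-	A	T	T	C	-	-	G	-	C	T	T	-	-	-	C	-	A	-	-	-	-	T	G	T	G	G	G	-	-
M1	Lassen Co, CA, USA	-	-	A	T	T	C	-	-	G	-	C	T	-	-	-	-	C	-	A	-	C	-	-	-	-	T	G	G	G	-	-
S12-1176	Gunnison, CO, USA	-	-	A	T	T	C	-	-	G	-	C	T	-	-	-	-	C	-	A	-	C	-	-	T	G	T	G	G	G	-	-
S12-1163	Alaska, USA	-	-	A	T	T	C	-	-	G	-	-	-	-	X	X	X	X	X	X	X	X	X	X	X	X	X	X	X	X	X	X
S12-1161	Alaska, USA	-	-	A	T	T	C	-	-	G	-	C	-	-	X	X	X	X	X	X	X	X	X	X	X	X	X	X	X	X	X	X
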