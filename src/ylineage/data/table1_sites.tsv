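locus_id	ancestral_allele	derived_allele	assayed	source_fragment	position_on_reference
G_343GC	G	C	1	G
G_690CT	C	T	1	G
R_156AC	C	A	1	R
R_503CT	C	T	1	R
R_793CT	C	T	1	R
12_709CT	T	C	1	12
20_238CT	T	C	1	20
21_687CT	C	T	1	21
27_204GT	T	G	1	27
31_365AT	A	T	1	31
DBY4_-54CG	G	C	1	DBY4
SRY_1197CT	C	T	1	SRY
31_209AT	A	T	1	31
11_535AG	A	G	0	11
21_982GA	G	A	0	21
21_1014TC	T	C	0	21
24_878TC	T	C	0	24
24_1434TA	T	A	0	24
28_458GA	G	A	0	28
28_524CA	C	A	0	28
29_231AC	A	C	0	29
K_79CA	C	A	0	K
K_527TC	T	C	0	K
MS41A_209CT	C	T	0	MS41A
MS41A_248AG	A	G	0	MS41A
MS41B_221CT	C	T	0	MS41B
N_558TG	T	G	0	N
Q_311TG	T	G	0	Q
Q_322AG	A	G	0	Q
Q_613CT	C	T	0	Q
R_805G	G	A	0	R
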