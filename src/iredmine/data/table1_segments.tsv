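id	uniprot	start1	seg1	end1	start2	seg2	end2	literature_selectivity
IRED-A	M4ZRJ3	119	GAIMIT	124	170	LYDVSLLGLMWG	181	R
IRED-B	Q1EQE0	134	GAILAG	139	185	LYDAAGLVMMWS	196	R
IRED-C	W7VJL8	120	GGIMAV	125	172	LHDVALLSAMYG	183	R
IRED-D	V7GV82	115	GGIMAV	120	165	LYDISLLTGMYG	176	R
IRED-E	J7LAY5	122	GAIMAT	127	172	LFDLALLSGMYT	183	R
IRED-F	V6KA13	121	GAVYAV	126	171	LYDVALLSGMYG	182	R
IRED-G	L8EIW6	128	GAIMVP	133	179	VYDLAMLSFFYS	190	S
IRED-H	I8QLV7	119	GAIMTT	124	169	LYDVALLGLMWS	180	R
IRED-I	M4ZS15	117	GGVQVP	122	167	MYYQAQMTIFWT	178	S
IRED-J	D2PR38	120	GGVMIP	125	170	LMYQAQLDVFLT	181	S
IRED-K	D2AWI4	118	GGVQVP	123	168	LFYQIGMDMFWT	179	S
IRED-L	K0F8R0	121	GGVMSA	126	171	VYYQALLTIFHP	182	S
IRED-M	K0K4C6	114	GGVMVP	119	164	LFYQAQLDFFLT	175	S
IRED-N	J7YM26	135	GGVQVP	140	185	LYYQIQMDIFWT	196	S
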