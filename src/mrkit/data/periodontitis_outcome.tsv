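SNP	CHR	POS	EA	OA	EAF	BETA	SE	P	N
rs1057868	NA	NA	T	C	NA	0.0063	0.017	0.71	49066
rs1956218	NA	NA	G	A	NA	0.0198	0.0157	0.21	49066
rs2472297	NA	NA	T	C	NA	0.0138	0.0204	0.50	49066
rs4410790	NA	NA	C	T	NA	0.0214	0.0159	0.18	49066
rs4719497	NA	NA	T	C	NA	0.0029	0.0223	0.90	49066
rs574367	NA	NA	T	G	NA	0.0284	0.0194	0.14	49066
rs66723169	NA	NA	A	C	NA	0.0087	0.0195	0.66	49066
rs73073176	NA	NA	C	T	NA	0.0246	0.0253	0.33	49066
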