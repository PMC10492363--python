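SNP	CHR	POS	EA	OA	EAF	BETA	SE	P	N
rs1057868	NA	NA	T	C	0.29	1.4036	0.45	5.26e-33	375833
rs1956218	NA	NA	G	A	0.56	0.9055	0.3873	3.62e-08	375833
rs2472297	NA	NA	T	C	0.27	2.1307	0.4123	5.19e-155	375833
rs4410790	NA	NA	C	T	0.63	1.9849	0.3873	5.59e-141	375833
rs4719497	NA	NA	T	C	0.87	1.0954	0.4690	4.23e-08	375833
rs574367	NA	NA	T	G	0.21	1.0247	0.4243	8.06e-09	375833
rs66723169	NA	NA	A	C	0.23	1.2124	0.4243	9.88e-17	375833
rs73073176	NA	NA	C	T	0.87	1.5199	0.4690	5.56e-25	375833
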