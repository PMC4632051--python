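aa	codon	gryllus_delta	gryllus_stars	gryllus_flag	oncopeltus_delta	oncopeltus_stars	oncopeltus_flag	parhyale_delta	parhyale_stars	parhyale_flag
# Published per-species deltaRSCU contrast table (59 degenerate-family
# codons). stars: *** P<0.001, ** P<0.05, * putative (0.05<=P<0.1).
# flag: p = published primary optimal codon (boldface); b = footnoted
# candidate codon (P at/slightly above 0.1, used via the override list).
A	GCT	0.279	***	p	0.370	***	p	0.048
A	GCC	-0.060			-0.081	*		0.028	**	p
A	GCA	-0.055			-0.120	**		0.012
A	GCG	-0.123	***		-0.101	**		-0.079
R	CGT	0.277	**	p	0.098	**	p	0.060
R	CGC	0.013			-0.101	**		-0.001
R	CGA	0.081			-0.019			-0.051
R	CGG	0.029			-0.047			-0.163
R	AGA	-0.259	**		0.050			0.122
R	AGG	-0.019			0.117			0.064
N	AAT	0.074	**	p	0.126	***	p	-0.054	**
N	AAC	-0.060	*		-0.110	***		0.078	***	p
D	GAT	0.132	***	p	0.129	***	p	0.078
D	GAC	-0.091	**		-0.113	***		-0.031
C	TGT	0.170	**	p	0.216	***	p	-0.167	**
C	TGC	-0.033			0.003			-0.013
Q	CAA	-0.070	*		0.063			-0.064	**
Q	CAG	0.097	**	p	-0.013			0.078	**	p
E	GAA	0.063	*	p	0.107	***	p	-0.005
E	GAG	-0.021			-0.091	**		0.030
G	GGT	0.180	***	p	0.317	***	p	0.021
G	GGC	-0.018			-0.183	***		0.017
G	GGA	0.011			-0.026			0.096	*	p
G	GGG	-0.133	**		-0.074	*		-0.127	***
H	CAT	0.129	**	p	0.102	**	p	0.013
H	CAC	-0.034			-0.029			-0.035
I	ATT	0.311	***	p	0.167	***	p	-0.027
I	ATC	-0.135	**		-0.033			0.136	***	p
I	ATA	-0.125	**		-0.100	**		-0.112	**
L	TTA	-0.034			0.073	*		-0.226	***
L	TTG	0.300	***	p	0.017			0.053
L	CTT	0.068			0.346	***	p	0.004
L	CTC	-0.217	***		-0.147	**		0.146	***	p
L	CTA	-0.075			-0.112	**		-0.064	**
L	CTG	-0.021			-0.177	***		0.087
K	AAA	-0.032			0.019			-0.100	***
K	AAG	0.059			-0.002			0.110	***	p
F	TTT	0.062		pb	0.118	***	p	-0.075	**
F	TTC	-0.015			-0.078	**		0.091	***	p
P	CCT	0.158	*		0.194	**	p	0.164
P	CCC	-0.190	***		-0.052			0.063	**	p
P	CCA	0.139	**	p	-0.009			-0.108	*
P	CCG	-0.038			-0.124	***		-0.129	**
S	TCT	0.297	***	p	0.359	***	p	0.015
S	TCC	-0.200	***		-0.142	**		-0.023
S	TCA	-0.024			0.123	*		0.038	**
S	TCG	-0.007			-0.127	***		0.089	**	p
S	AGT	0.024			-0.081			-0.079	**
S	AGC	-0.090			-0.131	**		-0.040
T	ACT	0.163	**	p	0.244	***	p	0.033
T	ACC	-0.104	**		-0.122	**		0.114	**	p
T	ACA	0.040			-0.033			-0.091
T	ACG	-0.114	**		-0.080	**		-0.052
Y	TAT	0.081		pb	0.176	***	p	-0.106
Y	TAC	0.061			-0.140	***		0.086		pb
V	GTT	0.243	***	p	0.261	***	p	-0.031
V	GTC	-0.141	***		-0.100	**		0.081	*	p
V	GTA	-0.126	**		-0.108	*		-0.121	**
V	GTG	0.037			-0.041			0.069	**
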