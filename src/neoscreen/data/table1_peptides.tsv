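patient	gene	hla	mutated_sequence	wt_residue	position	mut_residue	hla_score
P01	POLE	B*1502	SRYFHIPIGNLPEYISTFGSDLFFARH	D	1663	Y	88
P01	FHL1	A*0206	CFTCSNCKQVIGTVSFFPKGEDFYCVT	G	139	V	86
P01	GPM6B	DQA1*0401	TILCFSGVALFCGFGHVALAGTVAILE	C	94	F	81
P01	LRP5	B*8101	CSHICIAKGDGTPLCSCPVHLVLLQNL	R	1237	L	80
P01	DMXL1	B*1502	QLRENFQEKRQWLFKYQSLLRMFLSYC	L	2124	F	78
P01	TP53	B*8101	CMGGMNRRPILTIFTLEDSSGNLLGRN	I	3123	F	70
P01	TPBG	A*0206	SAPFLASAVSAQPLLPDQCPALCECSE	P	57	L	84
P01	HACE1	DRB1*1101	QLNRLTRSLRRARSVELPEDNETAVYT	T	20	S	70
P01	COQ3	A*0206	RYPWARLYSTSQTAVDSGEVKTFLALA	T	91	A	68
P01	RAB4A	DRB1*1101	ERMGSGIQYGDAAFRQLRSPRRAQAPN	L	199	F	53
P02	ITFG1	A*0207	CVFILAIIGILHWLEKKADDREKRQEA	Q	591	L	39
P02	OPLAH	DQA1*0501	EGAVFLSFKLVQGDVFQEEAVTEALRA	G	890	D	49
P02	BCAR1	DPA1*0202	RQGIVPGNRLKILLVVPTRVGQGYVYE	V	64	L	31
P02	TP53	A*3303	TIITLEDSSGNLLVRNSFEVRVCACPG	G	266	V	32
P02	GBF1	B*1501	SSQHASRGGQSDDYEDEGVPASYHTVS	D	1478	Y	25
P02	COP1	B*5801	ILWDGFTGQRSKVSQEHEKRCWSVDFN	Y	485	S	31
P02	ATP11B	DQA1*0301	LKNTKEIFGVAVYSGMETKMALNYKSK	T	262	S	29
P02	UPF3A	A*3303	GSQDSGAPGEAMETLGRAQRCDDSPAP	R	380	T	26
P02	IER5L	A*0207	LHKNLLVSYVLRNTRQLYLSERYAELY	A	43	T	30
P02	SNX16	B*5801	QDVWMRSRADNKPYLSFSEPENAVSEI	C	318	Y	27
P03	OSBPL6	A*0201	EVLLSASSSENEALDDESYISDVSDNI	S	513	L	19
P03	NFE2L2	A*0201	AFFAQLQLDEETGQFLPIQPAQHIQSE	E	82	Q	18
P03	SLX4	A*0201	SPTKEAPPGLNDDGQIPASQESVATSV	A	1694	G	18
P03	ACAD8	A*0201	QTDVGGSGLSRLDISVIFEALATGCTS	T	105	I	31
P03	MTREX	A*0201	EMPKLTEQLAGPLCQMQECAKRIAKVS	R	933	C	15
P03	BCAR1	A*0201	VLLSWKVLDFSGPVPQGTGQPCSCGHW	G	23	V	37
P03	SLC7A1	A*0201	KYAVAVGSLCALSSSLLGSMFPMPRVI	A	349	S	28
P03	PLCG1	A*0201	SIEDHCSIAQQRNLAQYFKKVLGDTLL	M	425	L	23
P03	PIF1	A*0201	EADLFDKLEAVARGVRQQNKPFGGIQL	A	325	G	3
P03	SSH1	A*0201	ILDASKQRHNKLWCQQTDSSLQQPVDD	R	470	C	2
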