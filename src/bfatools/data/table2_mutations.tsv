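home_environment	ploidy	gene	mutation
CLM	2N	PDR1	+/E768G
CLM	2N	PDR1	F1047V
CLM	2N	PDR1	+/C862Y
CLM	2N	PDR1	+/T817K
CLM	2N	PDR1	+/K540E
CLM	2N	PDR1	+/G282V
CLM	2N	PDR1	+/E829K
CLM	2N	PDR1	+/N733Y
CLM	2N	PDR1	+/T1043K
CLM	2N	PDR1	+/F769L
CLM	2N	PDR1	+/Y864H
CLM	2N	PDR1	+/Q762K
CLM	2N	PDR1	+/L278V
CLM	2N	PDR1	+/A826E
CLM	2N	PDR1	+/R821G
CLM	2N	PDR3	+/S773I
CLM	2N	PDR3	+/L281F
CLM	2N	PDR3	+/G957D
CLM	2N	PDR3	+/L279S
CLM	2N	PDR3	+/K272N
CLM	1N	PDR1	N1050D
CLM	1N	PDR1	P261L
CLM	1N	PDR1	P261S
CLM	1N	PDR1	L868F
CLM	1N	PDR1	V871F
CLM	1N	PDR1	H751N
CLM	1N	PDR1	H751Q
CLM	1N	PDR1	S753SVYRSFAHYS
CLM	1N	PDR1	C862W
CLM	1N	PDR1	H723N
CLM	1N	PDR1	Y270S
CLM	1N	PDR1	K540Q
CLM	1N	PDR1	R959M
CLM	1N	PDR1	E688D
CLM	1N	PDR1	N1049H
CLM	1N	PDR1	A301S
CLM	1N	PDR1	Y864H
CLM	1N	PDR1	T358R
CLM	1N	PDR1	S814Y
CLM	1N	PDR1	F607L
CLM	1N	PDR1	R747P
CLM	1N	PDR1	L867F
CLM	1N	PDR1	L714R
CLM	1N	PDR1	G875A
CLM	1N	PDR1	E491D
CLM	1N	PDR1	F511V
CLM	1N	PDR1	A863G
CLM	1N	PDR1	S259G
CLM	1N	PDR1	V819I
CLM	1N	PDR3	R794S
CLM	1N	PDR3	C707F
CLM	1N	PDR3	F710L
CLM	1N	PDR3	L249V
CLM	1N	PDR3	L959Q
CLM	1N	PDR3	Y963H
CLM	1N	PDR3	A681E
FLC4	2N	CYC8	+/Q610*
FLC4	2N	CYC8	+/L370P
FLC4	2N	HAP1	+/V638F
FLC4	2N	PDR1	+/H689N
FLC4	2N	SSO2	+/627963T>A
FLC4	2N	SSO2	+/D233G
FLC4	2N	TUP1	+/I416_fs
FLC4	2N	TUP1	+/I704N
FLC4	2N	TUP1	+/262515A>T
FLC4	2N	VPS35	+/131054G>GT
FLC4	2N	VPS35	+/S64T
FLC4	2N	YHK8	+/N337T
FLC4	2N	YHK8	+/203404T>C
FLC4	1N	CSG2	S26F
FLC4	1N	CSG2	E234D
FLC4	1N	CSG2	G258C
FLC4	1N	CYC8	G265C
FLC4	1N	CYC8	NA729_fs
FLC4	1N	CYC8	A384T
FLC4	1N	CYC8	Y268D
FLC4	1N	HAP1	646403A>C
FLC4	1N	HAP1	V1471ETHKFNCSNKRSEIDQTSSN
FLC4	1N	PDR1	S832N
FLC4	1N	PDR1	E675K
FLC4	1N	PDR3	L249I
FLC4	1N	PDR3	R210M
FLC4	1N	PDR5	P943T
FLC4	1N	PDR5	E169K
FLC4	1N	PDR5	L790I
FLC4	1N	PDR5	T912S
FLC4	1N	ROX1	Q107*
FLC4	1N	ROX1	K72T
FLC4	1N	ROX1	M1T
FLC4	1N	SKN7	D446E_fs
FLC4	1N	SKN7	D446E
FLC4	1N	SKN7	S486*
FLC4	1N	SKN7	S411P
FLC4	1N	SUR1	Y116_fs
FLC4	1N	SUR1	Y116N
FLC4	1N	SUR1	Y235C
FLC4	1N	SUR1	E263*
FLC4	1N	SUR1	Y104*
FLC4	1N	SUR1	D141E
FLC4	1N	SUR1	M1V
FLC4	1N	SUR1	R218*
FLC4	1N	SUR1	Y116*
FLC4	1N	SUR1	H176Y
FLC4	1N	SUR1	R360_fs
FLC4	1N	SXM1	SS58_fs
FLC4	1N	SXM1	E701*_fs
FLC4	1N	SXM1	G259_fs
FLC4	1N	TUP1	D699Y
FLC4	1N	UPC2	V419F
FLC4	1N	UPC2	L876R
FLC4	1N	UPC2	L876P
GlyEtOH	2N	HAP1	K1474E, V1485I
GlyEtOH	2N	HAP1	K1474E,V1485I
GlyEtOH	2N	HAP1	+/IYVTSI1483I
GlyEtOH	2N	HEM2	+/L338*
GlyEtOH	2N	HEM2	+/A248E
GlyEtOH	2N	HEM3	+/S20P
GlyEtOH	2N	HEM3	+/G10E
GlyEtOH	2N	HEM3	+/G130G_fs
GlyEtOH	2N	HEM3	+/C111F
GlyEtOH	2N	HEM3	+/Y261*
GlyEtOH	2N	HEM3	+/G157E
GlyEtOH	2N	HEM3	+/G211C
GlyEtOH	2N	IRA1	+/N66I
GlyEtOH	2N	IRA2	+/I1657N
GlyEtOH	2N	NDI1	+/I298S
GlyEtOH	2N	NDI1	+/R205G
GlyEtOH	2N	WHI2	+/S289P
GlyEtOH	2N	WHI2	+/G141*
GlyEtOH	2N	WHI2	+/410637A>T
GlyEtOH	2N	WHI2	+/VLREDLDYYC165_fs
GlyEtOH	1N	GPB2	Q602*
GlyEtOH	1N	GPB2	R509*
GlyEtOH	1N	IRA1	D1116_fs
GlyEtOH	1N	IRA1	L1429*
GlyEtOH	1N	IRA1	ILV1729I
GlyEtOH	1N	IRA1	P1827L
GlyEtOH	1N	IRA1	K2034_fs
GlyEtOH	1N	IRA1	Y2354*
GlyEtOH	1N	IRA1	L1549F_fs
GlyEtOH	1N	IRA1	E2440*
GlyEtOH	1N	IRA1	S1612*
GlyEtOH	1N	IRA1	G780_fs
GlyEtOH	1N	IRA1	G780*
GlyEtOH	1N	IRA1	S2966*
GlyEtOH	1N	IRA1	W2779L_fs
GlyEtOH	1N	IRA1	C2067*
GlyEtOH	1N	IRA1	I1862S
GlyEtOH	1N	IRA1	LLMRYLL2976_fs
GlyEtOH	1N	IRA1	Y1239*
GlyEtOH	1N	IRA1	L587*
GlyEtOH	1N	IRA1	G1716_fs
GlyEtOH	1N	IRA2	G2097*
GlyEtOH	1N	IRA2	I339R
GlyEtOH	1N	IRA2	E3063*
GlyEtOH	1N	IRA2	L598W
GlyEtOH	1N	IRA2	F2628S
GlyEtOH	1N	IRA2	R1852L
GlyEtOH	1N	IRA2	I1463_fs
GlyEtOH	1N	IRA2	E2558*
GlyEtOH	1N	IRA2	R2195_fs
GlyEtOH	1N	SSK2	G1275D
GlyEtOH	1N	SSK2	L968_fs
GlyEtOH	1N	WHI2	410536G>A
GlyEtOH	1N	YTA6	K517R
GlyEtOH	1N	YTA6	418169T>G
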