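# Carbon-atom map of glycolysis and one TCA-cycle turn, one row per carbon.
# product = CO2 marks a substrate carbon released as carbon dioxide.
# Carbon indices are 1-based from the conventional C1 numbering of each
# metabolite.  Citrate numbering: C1 acetyl carboxyl, C2 acetyl methylene,
# C3 central carbon, C4/C5 oxaloacetate C3/C4 arm, C6 central carboxyl
# (oxaloacetate C1).  2-oxoglutarate: C1 the carboxyl alpha to the keto
# carbon (released by OGDH), C5 the acetyl-derived carboxyl.
reaction	substrate	sub_carbon	product	prod_carbon
hk	GLC	1	G6P	1
hk	GLC	2	G6P	2
hk	GLC	3	G6P	3
hk	GLC	4	G6P	4
hk	GLC	5	G6P	5
hk	GLC	6	G6P	6
pgi	G6P	1	F6P	1
pgi	G6P	2	F6P	2
pgi	G6P	3	F6P	3
pgi	G6P	4	F6P	4
pgi	G6P	5	F6P	5
pgi	G6P	6	F6P	6
pfk	F6P	1	F16BP	1
pfk	F6P	2	F16BP	2
pfk	F6P	3	F16BP	3
pfk	F6P	4	F16BP	4
pfk	F6P	5	F16BP	5
pfk	F6P	6	F16BP	6
ald	F16BP	1	DHAP	1
ald	F16BP	2	DHAP	2
ald	F16BP	3	DHAP	3
ald	F16BP	4	GA3P	1
ald	F16BP	5	GA3P	2
ald	F16BP	6	GA3P	3
tpi	DHAP	1	GA3P	3
tpi	DHAP	2	GA3P	2
tpi	DHAP	3	GA3P	1
gapdh	GA3P	1	PG23	1
gapdh	GA3P	2	PG23	2
gapdh	GA3P	3	PG23	3
eno	PG23	1	PEP	1
eno	PG23	2	PEP	2
eno	PG23	3	PEP	3
pk	PEP	1	PYR	1
pk	PEP	2	PYR	2
pk	PEP	3	PYR	3
pdh	PYR	1	CO2	0
pdh	PYR	2	ACCOA	1
pdh	PYR	3	ACCOA	2
cs	ACCOA	1	CIT	1
cs	ACCOA	2	CIT	2
cs	OAA	1	CIT	6
cs	OAA	2	CIT	3
cs	OAA	3	CIT	4
cs	OAA	4	CIT	5
acn	CIT	1	ACO	1
acn	CIT	2	ACO	2
acn	CIT	3	ACO	3
acn	CIT	4	ACO	4
acn	CIT	5	ACO	5
acn	CIT	6	ACO	6
idh	ACO	1	OG2	5
idh	ACO	2	OG2	4
idh	ACO	3	OG2	3
idh	ACO	4	OG2	2
idh	ACO	5	OG2	1
idh	ACO	6	CO2	0
ogdh	OG2	1	CO2	0
ogdh	OG2	2	SUC	1
ogdh	OG2	3	SUC	2
ogdh	OG2	4	SUC	3
ogdh	OG2	5	SUC	4
sdh	SUC	1	FUM	1
sdh	SUC	2	FUM	2
sdh	SUC	3	FUM	3
sdh	SUC	4	FUM	4
fh	FUM	1	MAL	1
fh	FUM	2	MAL	2
fh	FUM	3	MAL	3
fh	FUM	4	MAL	4
mdh	MAL	1	OAA	1
mdh	MAL	2	OAA	2
mdh	MAL	3	OAA	3
mdh	MAL	4	OAA	4
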