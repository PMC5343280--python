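# Metabolite definitions for the packaged glycolysis + TCA carbon-map network.
# symmetric = 1 marks 2-fold rotational carbon symmetry (label scrambling).
id	carbons	symmetric
GLC	6	0
G6P	6	0
F6P	6	0
F16BP	6	0
DHAP	3	0
GA3P	3	0
PG23	3	0
PEP	3	0
PYR	3	0
ACCOA	2	0
CIT	6	0
ACO	6	0
OG2	5	0
SUC	4	1
FUM	4	1
MAL	4	0
OAA	4	0
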