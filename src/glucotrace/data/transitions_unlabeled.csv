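Analyte,Q1,Q3,RT,DP,CE,CXP
G6P,258.89,96.7,8.1,-20,-30,-15
F6P,259.02,96.8,9.6,-20,-30,-15
F16BP,339.08,96.9,21.9,-20,-30,-15
DHAP,168.84,97,11.9,-50,-14,-5
PG23,184.91,97,21.5,-50,-20,-5
PEP,166.83,79,22.3,-40,-18,-5
PYR,87.02,43,11.9,-45,-12,-1
CIT,190.96,110.9,22.6,-50,-18,-7
ACO,172.94,84.9,22.6,-30,-18,-5
OG2,144.95,100.8,20.5,-40,-12,-5
SUC,117,73,18.5,-45,-16,-3
FUM,115.01,70.9,21.1,-45,-12,-1
MAL,133,70.8,19.7,-40,-22,-3
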