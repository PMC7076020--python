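electrode,region
FP1,F
FP2,F
Fz,F
F7,FL
F3,FL
FC5,FL
FC1,FL
F4,FR
F8,FR
FC2,FR
FC6,FR
C3,CL
CP1,CL
CP5,CL
C4,CR
CP2,CR
CP6,CR
FT9,TL
T7,TL
TP9,TL
FT10,TR
T8,TR
TP10,TR
P7,OPL
P3,OPL
O1,OPL
P4,OPR
P8,OPR
O2,OPR
Pz,OP
Oz,OP
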