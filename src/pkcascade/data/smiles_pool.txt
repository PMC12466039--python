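CC(=O)Oc1ccccc1C(=O)O
CC(C)Cc1ccc(cc1)C(C)C(=O)O
CC(=O)Nc1ccc(O)cc1
CN1C=NC2=C1C(=O)N(C)C(=O)N2C
ClC1=CC2=C(C=C1)N(C)C(=O)CN=C2c1ccccc1
CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21
CN1CCC[C@H]1c1cccnc1
CC(C)NCC(O)COc1ccc(CC(N)=O)cc1
CC(C)(C)NCC(O)c1ccc(O)c(CO)c1
CCN(CC)CCNC(=O)c1ccc(N)cc1
COc1ccc2cc(ccc2c1)C(C)C(=O)O
OC(=O)c1ccccc1O
NC(=O)c1ccccc1O
Clc1ccccc1C(=O)Nc1ccccc1
CC(C)(C)NC(=O)C1CN(CC1)Cc1ccccc1
OCC(O)CO
NCCc1ccc(O)c(O)c1
NC(Cc1ccc(O)c(O)c1)C(=O)O
CNCC(O)c1ccc(O)c(O)c1
OC(CNC(C)C)c1ccc(O)c(O)c1
CC(N)Cc1ccccc1
CNC(C)Cc1ccccc1
OC(=O)CC(O)(CC(=O)O)C(=O)O
CCCCC(=O)O
CCCCCCCCCCCCCCCC(=O)O
C1CCNCC1
c1ccc2[nH]ccc2c1
NC(Cc1c[nH]c2ccccc12)C(=O)O
OC(=O)C1CCCN1
NC(CO)C(=O)O
NC(CS)C(=O)O
CC(O)C(N)C(=O)O
NC(CCC(=O)O)C(=O)O
NC(CCCCN)C(=O)O
NC(=N)NCCCC(N)C(=O)O
Nc1ncnc2[nH]cnc12
Nc1ccn(C2OC(CO)C(O)C2O)c(=O)n1
CC1=CN(C2CC(O)C(CO)O2)C(=O)NC1=O
OCC1OC(O)C(O)C(O)C1O
CC(=O)NC1C(O)OC(CO)C(O)C1O
OC1=CC(=O)c2c(O)cc(O)cc2O1
COc1cc(C=CC(=O)O)ccc1O
Oc1ccc(C=CC(=O)O)cc1
CC(C)=CCCC(C)=CC=O
CC12CCC3c4ccc(O)cc4CCC3C1CCC2O
CC12CCC(=O)C=C1CCC1C2CCC2(C)C(O)CCC12
CC(=O)C1CCC2C3CCC4=CC(=O)CCC4(C)C3CCC12C
CCC(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC(O)CC(O)CC(=O)O)C12
CC(C)c1ccc(cc1)C(C)C(=O)O
COC(=O)c1ccccc1O
CCOC(=O)c1ccccc1N
Cc1ccccc1N
COc1ccccc1OCCN
ClCCN(CCCl)N=O
FC(F)(F)c1ccc(cc1)C(O)CCCN1CCC(CC1)C(O)(c1ccccc1)c1ccccc1
Clc1ccc(cc1)C(c1ccccc1)N1CCN(CCOCCO)CC1
COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1
CC(C(=O)O)c1ccc2c(c1)cc(cc2)OC
Cc1c(cccc1Cl)Nc1ccccc1C(=O)O
OC(=O)c1cc(ccc1O)N=Nc1ccc(cc1)S(=O)(=O)Nc1ccccn1
CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O
CC1(C)SC2C(NC(=O)C(N)c3ccccc3)C(=O)N2C1C(=O)O
CC1(C)SC2C(NC(=O)C(C(=O)O)c3ccccc3)C(=O)N2C1C(=O)O
Cc1ccc(cc1)S(=O)(=O)NC(=O)NN1CC2CCC1CC2
CCCCCCNC(=O)NS(=O)(=O)c1ccc(C)cc1
OCCN1CCN(CCCN2c3ccccc3Sc3ccc(Cl)cc32)CC1
Clc1ccc2c(c1)C(=NCC(=O)N2)c1ccccc1
OC1(CCN(CCCC(=O)c2ccc(F)cc2)CC1)c1ccc(Cl)cc1
Fc1ccc(cc1)C(=O)CCCN1CCC(=CC1)N1C(=O)Nc2ccccc21
CN1CCN(CC1)C1=Nc2cc(Cl)ccc2Nc2ccccc21
CC(CN1c2ccccc2Sc2ccccc21)N(C)C
CN(C)CCOC(c1ccccc1)c1ccccc1
CN(C)CCCN1c2ccccc2CCc2ccc(Cl)cc21
OC(=O)COc1ccc(Cl)cc1
CCCCc1oc2ccccc2c1C(=O)c1cc(I)c(OCCN(CC)CC)c(I)c1
CCC(C)C1(CC)C(=O)NC(=O)NC1=O
CCC1(C(=O)NC(=O)NC1=O)c1ccccc1
O=C1N(C(=O)C2(CCCCC2)C1)C
NC(=O)C1(CCN(CC1)CCC(C#N)(c1ccccc1)c1ccccc1)N1CCCCC1
Clc1cccc(Cl)c1N=C1NCCN1
OC(=O)CCCCCCC(=O)O
NS(=O)(=O)c1cc2c(cc1Cl)NC(NS2(=O)=O)C1CC2CC=C1C2
NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O
CCOC(=O)C1=C(C)NC(C)=C(C1c1cccc(c1)[N+](=O)[O-])C(=O)OC
COC(=O)C1=C(C)NC(C)=C(C1c1cccc(c1)[N+](=O)[O-])C(=O)OCCN(C)Cc1ccccc1
CCOC(=O)C1=C(COCCN)NC(C)=C(C1c1ccccc1Cl)C(=O)OC
CC(=O)SC1CC2=CC(=O)CCC2(C)C2CCC3(C)C(CCC3(O)C#C)C12
CN(C)C1C(O)=C(C(N)=O)C(=O)C2(O)C(O)=C3C(=O)c4c(O)cccc4C(C)(O)C3CC12
CN1CCCC(CC2c3ccccc3Sc3ccccc23)C1
Clc1ccc(CC2CCNCC2)cc1
OC(c1ccc(F)cc1)(c1ccc(F)cc1)C1CCNCC1
CC(C)(C)c1ccc(cc1)C(O)CCCN1CCC(CC1)C(O)(c1ccccc1)c1ccccc1
CCN(CC)CC(=O)Nc1c(C)cccc1C
CCCCN1CCCCC1C(=O)Nc1c(C)cccc1C
CN1CCCN(C)c2ccccc21
CC(=O)OCC(=O)C1(O)CCC2C3CCC4=CC(=O)CCC4(C)C3C(O)CC12C
CC1CC2C3CCC4=CC(=O)C=CC4(C)C3(F)C(O)CC2(C)C1(O)C(=O)CO
OCC1OC(n2cnc3c2NC=NC3=O)C(O)C1O
NC1CCCCC1N
OC(=O)c1cc2ccccc2nc1O
Oc1cccc2cccnc12
Clc1ccc(cc1)c1ccccc1
CN(C)c1ccc(cc1)C(=O)O
NC(=O)NO
NC(=O)NC1CCCCC1
OC(=O)c1ccncc1
NC(=O)c1ccncc1
CNC(=O)c1ccncc1
Cc1ncc([N+](=O)[O-])n1CCO
OCC(NC(=O)C(Cl)Cl)C(O)c1ccc(cc1)[N+](=O)[O-]
CC(O)=NNC(=O)c1ccncc1
NNC(=O)c1ccncc1
CCONC(=O)c1ccncc1
NC(=S)c1ccncc1
CC12CCC3c4ccccc4CCC3C1CCC2=O
CC(CCc1ccc(O)cc1)NCCc1ccc(O)c(O)c1
CNCC(O)c1cccc(O)c1
NCC(O)c1ccc(O)c(O)c1
CNC(C)C(O)c1ccccc1
OC(CNC(C)(C)C)c1cccc(Cl)c1
CC(C)NCC(O)COc1cccc2ccccc12
CC(C)NCC(O)COc1ccc(COCCOC(C)C)cc1
CCOc1ccccc1OCCNC(C)Cc1ccc(OC)cc1
CC(C)NCC(O)COc1ccccc1CC=C
OCCN1CCN(CC1)C(c1ccccc1)c1ccc(Cl)cc1
CCOC(=O)N1CCN(CC1)C(=O)C(O)c1ccccc1
COc1ccc(CCN2CCC(CC2)NC(=O)c2cc(Cl)c(N)cc2OC)cc1
Cc1cccc(C)c1NC(=O)CN(CC(=O)O)CC(=O)O
CCN(CC)C(=O)C1CN(C)C2Cc3c[nH]c4cccc(C2=C1)c34
CN1CCC(CC1)=C1c2ccccc2CCc2sccc21
CN1CCC(CC1)=C1c2ccccc2COc2ccc(CC(=O)O)cc21
OC(=O)c1ccc2ccccc2c1O
CC(C)Oc1cc(N)c(Cl)cc1C(=O)NC1CCN(CCc2ccccc2)CC1
COc1cc2c(cc1OC)C(=O)C(CC1CCN(Cc3ccccc3)CC1)C2
O=C(N1CCCCC1)N1CCCCC1
O=S(=O)(c1ccccc1)c1ccccc1
Clc1ccccc1c1ccccc1
Nc1nc(N)c2nc(CNc3ccc(cc3)C(=O)NC(CCC(=O)O)C(=O)O)cnc2n1
OC(=O)CCC(=O)O
OC(=O)C=CC(=O)O
CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O
CCC(=O)Nc1ccc(cc1)N1CCN(CC1)CCc1ccccc1
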