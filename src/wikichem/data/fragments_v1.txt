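#version: wikichem-fragfp-v1
# one fragment per line: SMILES<TAB>min_count; line order = bit order
C	1
C	2
C	3
C	4
C	5
C	6
C	7
C	8
C	10
C	12
C	14
C	16
C	20
C	24
C	28
C	32
N	1
N	2
N	3
N	4
N	5
N	6
O	1
O	2
O	3
O	4
O	5
O	6
O	8
S	1
S	2
S	3
P	1
P	2
F	1
F	2
F	3
F	6
Cl	1
Cl	2
Cl	3
Br	1
Br	2
I	1
B	1
[O-]	1
[N+]	1
[NH+]	1
[NH2+]	1
[NH3+]	1
[N-]	1
[S-]	1
[nH]	1
[O-]	2
[N+]	2
cc	1
cc	2
cc	3
cc	4
cc	5
cc	6
cc	8
cc	10
cc	12
ccnc	1
ccnc	2
ccnc	3
c[nH]	1
cccc	1
cccccc	1
cccc	2
cccc	3
cccc	4
CC	1
CN	1
CO	1
CS	1
CP	1
CF	1
CCl	1
CBr	1
CI	1
CB	1
NN	1
NO	1
NS	1
NP	1
OO	1
OS	1
OP	1
SS	1
C=C	1
C=N	1
C=O	1
C=S	1
N=N	1
N=O	1
S=O	1
P=O	1
C#C	1
C#N	1
N#N	1
CC	2
CC	4
CC	8
CC	12
CN	2
CN	4
CO	2
CO	4
C=O	2
C=C	2
cc	7
cc	9
cc	11
ccnc	4
CCC	1
CCN	1
CCO	1
CCS	1
CNC	1
CNN	1
CNO	1
CNS	1
COC	1
CON	1
COO	1
COS	1
CSC	1
CSN	1
CSO	1
CSS	1
NCN	1
NCO	1
NCS	1
OCO	1
OCS	1
SCS	1
CCCC	1
CCCN	1
CCCO	1
CCNC	1
CCNN	1
CCNO	1
CCOC	1
CCON	1
CCOO	1
CNCN	1
CNCO	1
CNNC	1
CNOC	1
COCN	1
COCO	1
COOC	1
NCCN	1
NCCO	1
OCCO	1
NCCCC	1
OCCCC	1
CNCCC	1
COCCC	1
CCNCC	1
CCOCC	1
CCCCC	1
NCCCCC	1
OCCCCC	1
CNCCCC	1
COCCCC	1
CCNCCC	1
CCOCCC	1
CCCCCC	1
CCC	2
CCC	4
CCCC	2
CCCCC	2
CCCCCC	2
CCO	2
CCN	2
C=CC	1
C=CC=C	1
CC=CC	1
C=CC=O	1
CC(=O)C	1
CC#N	1
CC#C	1
N=CC	1
O=CN	1
O=CO	1
C=NC	1
C=CO	1
C=CN	1
CC=O	1
CCC=O	1
CC(=O)O	1
CC(=O)N	1
C1CC1	1
C1CCC1	1
C1CCCC1	1
C1CCCCC1	1
C1CCCCCC1	1
C1CCCCCCC1	1
N1CC1	1
O1CC1	1
S1CC1	1
N1CCC1	1
O1CCC1	1
S1CCC1	1
N1CCCC1	1
O1CCCC1	1
S1CCCC1	1
N1CCCCC1	1
O1CCCCC1	1
S1CCCCC1	1
N1NCCC1	1
N1CNCC1	1
N1NCCCC1	1
N1CNCCC1	1
N1CCNCC1	1
N1OCCC1	1
N1COCC1	1
N1OCCCC1	1
N1COCCC1	1
N1CCOCC1	1
N1SCCC1	1
N1CSCC1	1
N1SCCCC1	1
N1CSCCC1	1
N1CCSCC1	1
O1OCCC1	1
O1COCC1	1
O1OCCCC1	1
O1COCCC1	1
O1CCOCC1	1
C1CCCCC1C	1
C1CCCC1C	1
O=C1CCCCC1	1
O=C1CCCC1	1
O=C1CCCCC1C	1
C1CCNCC1C	1
C1CCOCC1C	1
c1ccccc1	1
c1ccncc1	1
c1ccncn1	1
c1cnccn1	1
c1cnncc1	1
c1cc[nH]c1	1
c1ccoc1	1
c1ccsc1	1
c1c[nH]cn1	1
c1cn[nH]c1	1
c1cocn1	1
c1cscn1	1
c1conc1	1
c1csnc1	1
c1ncncn1	1
c1ccccc1	2
c1ccccc1	3
c1ccncc1	2
c1ccc2ccccc2c1	1
c1ccc2[nH]ccc2c1	1
c1ccc2occc2c1	1
c1ccc2sccc2c1	1
n1ccc2ccccc2c1	1
[nH]1cnc2ccccc21	1
c1nc2ccccc2n1C	1
c1ncc2[nH]cnc2n1	1
c1ccc2c(c1)cccc2C	1
c1ccc2c(c1)OCO2	1
Cc1ccccc1	1
Nc1ccccc1	1
Oc1ccccc1	1
Sc1ccccc1	1
Fc1ccccc1	1
Clc1ccccc1	1
Brc1ccccc1	1
Ic1ccccc1	1
Cc1ccncc1	1
Nc1ccncc1	1
O=Cc1ccccc1	1
OC(=O)c1ccccc1	1
NC(=O)c1ccccc1	1
Cc1ccccc1C	1
Cc1ccc(C)cc1	1
Cc1cccc(C)c1	1
Oc1ccccc1O	1
Oc1ccc(O)cc1	1
Nc1ccccc1N	1
Clc1ccccc1Cl	1
Cc1ccccc1O	1
Cc1ccccc1N	1
COc1ccccc1	1
CNc1ccccc1	1
CCc1ccccc1	1
C=Cc1ccccc1	1
N#Cc1ccccc1	1
Fc1ccccc1F	1
c1ccccc1c1ccccc1	1
c1ccccc1Cc1ccccc1	1
c1ccccc1Nc1ccccc1	1
c1ccccc1Oc1ccccc1	1
c1ccccc1CCC	1
c1ccccc1CN	1
c1ccccc1CO	1
Cn1cccc1	1
Cn1ccnc1	1
Sc1ncccc1	1
C(=O)OC	1
CC(=O)OC	1
CNC(=O)C	1
C(=O)NC	1
[N+](=O)[O-]	1
C[N+](=O)[O-]	1
[O-][N+](=O)c1ccccc1	1
S(=O)(=O)O	1
S(=O)(=O)N	1
CS(=O)(=O)C	1
CS(=O)C	1
P(=O)(O)O	1
OP(=O)(O)O	1
COP(=O)(O)O	1
NC(=N)N	1
NC(=O)N	1
NC(=O)O	1
OC(=O)O	1
C(F)(F)F	1
C(Cl)(Cl)Cl	1
C(F)F	1
CC(C)C	1
CC(C)(C)C	1
CN(C)C	1
N=C=O	1
N=C=S	1
OCC=O	1
N=CN	1
OC(C)C	1
OCC(O)C	1
C=C(C)C	1
CC(N)C	1
OC1CCCCC1	1
NC1CCCCC1	1
CC(=O)CC(=O)	1
CN1CCCCC1	1
CN1CCCC1	1
O=C1NCCC1	1
O=C1NC(=O)NC1	1
FC(F)(F)c1ccccc1	1
CC(=O)Nc1ccccc1	1
CN1CCNCC1	1
C1CCOC1C	1
SCCC	1
Brc1ccccc1Br	1
FC(F)(F)Oc1ccccc1	1
CC(C)Cc1ccccc1	1
CC(=O)c1ccccc1	1
CCOC(=O)C	1
CCN(CC)CC	1
CC(C)(C)N	1
OC(=O)CN	1
OC1CCCC1	1
OC1CCC1	1
CC1CCCCC1C	1
C1CC2CCC1CC2	1
C1CCC2CCCCC2C1	1
C1CCC2CCCC2C1	1
O1CCOCC1C	1
O=S1(=O)CCCC1	1
O=C1CCCCN1	1
O=C1OCCC1	1
O=C1OC(=O)CC1	1
CC1(C)CCCCC1	1
N1CCNCC1C	1
OCC1CCCCC1	1
NCC1CCCCC1	1
ClCC	1
ClCCC	1
BrCC	1
FCC	1
ICC	1
ClC(Cl)C	1
FC(F)C	1
ClC=C	1
FC=C	1
Clc1ccc(Cl)cc1	1
Fc1ccc(F)cc1	1
Cc1ccc(Cl)cc1	1
Cc1ccc(F)cc1	1
Cc1ccc(O)cc1	1
Cc1ccc(N)cc1	1
COc1ccc(C)cc1	1
COc1ccccc1O	1
Nc1ccc(O)cc1	1
Oc1ccccc1C=O	1
Oc1ccccc1C(=O)O	1
NS(=O)(=O)c1ccccc1	1
CS(=O)(=O)N	1
CSSC	1
C=CCC	1
C=CCCC	1
CC=CCC	1
C=C(C)CC	1
CC(C)=CC	1
C#CCC	1
CC#CC	1
O=CCC=O	1
OC=CC	1
NC=CC	1
CN=CC	1
CC(N)C(=O)O	1
CC(O)C(=O)O	1
NC(C)C(=O)N	1
OCC(N)C=O	1
NCCS	1
OCCS	1
NCCCN	1
OCCCO	1
NCCCCN	1
c1ccccc1CCN	1
c1ccccc1CCO	1
c1ccccc1CC=O	1
c1ccccc1C(=O)OC	1
c1ccccc1OC(=O)C	1
c1ccccc1C(=O)NC	1
c1ccccc1CS	1
c1ccccc1CCCC	1
c1ccccc1C(C)C	1
c1ccccc1C(C)(C)C	1
c1ccccc1C(O)C	1
c1ccccc1C(N)C	1
Cc1cccnc1	1
Cc1ccccn1	1
Cc1cccs1	1
Cc1ccco1	1
Cc1cc[nH]c1	1
Cn1cccc1C	1
Oc1ccncc1	1
Nc1ccncc1C	1
c1ccnc(c1)N	1
c1ccnc(c1)O	1
c1ccnc(c1)Cl	1
O=c1cc[nH]cc1	1
O=c1ccocc1	1
CC(=O)N1CCCC1	1
CC(=O)N1CCCCC1	1
C1CCCCCC1C	1
C1CCCCCCC1C	1
C=C	3
C=O	3
C(=O)O	2
C(=O)N	2
COC	2
CNC	2
OCO	2
Cl	4
F	4
F	8
O	10
O	12
N	8
CCCC	4
CCCCCC	3
c1ccccc1	4
CC(C)C	2
CO	6
CN	6
CC	16
CC	20
CC	24
cc	14
cc	16
CC	6
CC	10
CCC	3
CCC	6
CCCC	3
CO	5
CN	3
CN	5
C=C	4
cc	13
N	7
O	7
O	9
S	4
Cl	5
Br	3
CCN	3
CCO	3
CCO	4
c[nH]	2
C1CCCCC1	2
C=CC	2
C=CC	3
CC=O	2
CC=O	3
CCCCC	3
OCCO	2
C#N	2
C	33
C	34
C	35
C	36
C	37
C	38
C	39
C	40
C	41
C	42
C	43
C	44
C	45
C	46
C	47
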