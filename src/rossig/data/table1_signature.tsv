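gene_id	log2fc	weight
KRT1	1.39649507	1
BCL2	1.21684097	1
TYSND1	1.028826515	1
DHRS4	1.023064207	1
EPHX2	0.998809446	1
IFNG	0.990314958	1
CCL5	0.978813828	1
MYC	0.942214034	1
SRC	0.919788893	1
PRDX4	0.905019227	1
GSS	0.868091871	1
HACL1	0.806398241	1
DNAJA3	0.796338833	1
GSTP1	0.718004102	1
PRDX2	0.709937194	1
PTGS2	0.704762302	1
HSPD1	0.68481934	1
FMO5	0.677398254	1
DNAJC9	0.676712675	1
CCT4	0.676162928	1
IL12RB1	0.634905263	1
HSPA9	0.627851503	1
CROT	0.625008985	1
CCT3	0.62440571	1
JUN	0.61663915	1
SLC27A2	0.595969275	1
GSR	-0.613066934	-1
JAK2	-0.639496536	-1
DNAJC5	-0.682604763	-1
DNAJC4	-0.746858619	-1
RHOU	-0.825335335	-1
GCLM	-0.904446168	-1
MSRA	-0.984304987	-1
SOCS3	-1.259719259	-1
PECR	-1.476257053	-1
CYP1B1	-1.517326189	-1
ARG1	-1.546803504	-1
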