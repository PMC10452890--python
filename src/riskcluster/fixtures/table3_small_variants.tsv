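gene	rsid	hrls	irls	lrls	af_1000g	region	cancer_related	crc_related	oncogenic_class	tumor_driver	track	bold
PABPC3	rs79397892	Yes	Yes	Yes	0.0054	EX	-	-	Passenger	True	coding	0
PABPC3	rs78826513	Yes	Yes	Yes	NA	EX	-	-	Driver	True	coding	0
PABPC3	rs78552667	Yes	Yes	Yes	NA	EX	-	-	Passenger	True	coding	0
PABPC3	rs201411821	Yes	Yes	-	NA	EX	-	-	Driver	True	coding	0
PABPC3	rs80261016	Yes	Yes	Yes	NA	EX	-	-	Driver	True	coding	0
KRT18	rs78343594	Yes	Yes	Yes	NA	EX	-	-	Passenger	False	coding	0
KRT18	rs77999286	Yes	Yes	Yes	NA	EX	-	-	Passenger	False	coding	0
KRT18	rs75441140	Yes	Yes	Yes	NA	EX	-	-	Passenger	False	coding	0
KRT18	NA	Yes	Yes	Yes	NA	EX	-	-	NA	NA	coding	0
CNN2	rs77830704	Yes	Yes	Yes	NA	EX	-	-	Passenger	False	coding	0
CNN2	rs75676484	Yes	Yes	-	NA	EX	-	-	Passenger	False	coding	0
SLC25A5	rs753913830	Yes	Yes	Yes	NA	EX	-	-	Passenger	False	coding	0
SLC25A5	rs199707714	-	Yes	-	NA	EX	-	-	Passenger	False	coding	0
MYH13	rs186137259	Yes	Yes	Yes	0.0016	EX	-	-	Passenger	False	coding	0
DNAH2	rs140035206	Yes	Yes	Yes	0.0022	EX	-	-	Passenger	False	coding	0
ANP32B	rs76167314	Yes	Yes	-	NA	EX	-	-	Passenger	False	coding	0
CNKSR1	rs140685957	Yes	Yes	-	NA	EX	-	-	Passenger	False	coding	0
CTNNBIP1	rs138271667	Yes	Yes	-	0.0018	EX	-	-	Passenger	False	coding	0
DNAH3	rs147732992	Yes	Yes	-	0.0034	EX	-	-	Passenger	False	coding	0
KDM1A	rs144822945	Yes	Yes	-	0.0015	EX	-	-	Passenger	False	coding	0
PRSS3	rs141382822	Yes	Yes	Yes	NA	EX	-	-	Passenger	False	coding	0
PRSS3	rs751456445	Yes	-	-	NA	EX	-	-	Passenger	False	coding	0
AATK	rs61738829	Yes	-	-	0.0088	EX	-	-	Passenger	False	coding	0
ALPK3	NA	Yes	-	-	NA	EX	-	-	NA	NA	coding	0
ANKRD34B	rs145614517	Yes	-	-	0.0030	EX	-	-	Passenger	False	coding	0
ATXN2	rs374319477	Yes	-	-	NA	EX	-	-	Passenger	False	coding	0
CUX2	rs202242120	Yes	-	-	0.0040	EX	-	-	Passenger	False	coding	0
ERAP2	rs145045143	Yes	-	-	0.0010	EX	-	-	Passenger	False	coding	0
FAM136A	rs80277652	Yes	-	-	NA	EX	-	-	Passenger	False	coding	0
MACF1	rs201602708	Yes	-	-	0.0002	EX	-	-	Driver	True	coding	0
MLH1	rs63750539	Yes	-	-	NA	EX	Leukemia; Lymphoma; Melanoma; Pancreatic; Liver; Fallopian; Endometrial; Ovarian; Breast; Prostate; Bladder; Thyroid; Esophageal; Lung	Lynch syndrome; Colorectal melanoma; Microsatellite Instability; Hereditary non-polyposis; Colon; Gastric; Stomach	Driver	True	coding	1
PCSK5	rs372055352	Yes	-	-	NA	EX	-	-	Passenger	False	coding	0
PLA2G6	NA	Yes	-	-	NA	EX	-	-	NA	NA	coding	0
PPP1R13B	rs373141354	Yes	-	-	NA	EX	Melanoma	-	Passenger	False	coding	1
RIMKLA	rs34142209	Yes	-	-	0.0082	EX	-	-	Passenger	False	coding	0
RNF207	NA	Yes	-	-	NA	EX	-	-	NA	NA	coding	0
SIPA1L3	rs201766021	Yes	-	-	0.0002	EX	-	-	Passenger	False	coding	0
XIRP1	rs147417919	Yes	-	-	0.0032	EX	-	-	Passenger	False	coding	0
CD8A	rs200750291	-	Yes	-	0.0012	EX	-	-	Passenger	False	coding	0
LAMA5	rs551763507	-	Yes	-	NA	EX	Neuroblastoma	-	Passenger	False	coding	1
MRPL24	rs561581574	-	Yes	-	NA	EX	-	-	Passenger	False	coding	0
NLRP14	rs76670455	-	Yes	-	0.0058	EX	Leukemia	-	Passenger	False	coding	1
TAAR5	rs9493386	-	Yes	-	0.0026	EX	-	-	Passenger	False	coding	0
PRH1-TAS2R14	rs763119571	-	-	Yes	NA	EX	-	Colorectal	Passenger	False	coding	1
TMEM8B	rs148540551	-	-	Yes	0.0014	EX	-	-	Passenger	False	coding	0
PODN	rs544153916	-	-	Yes	0.0002	NA	-	-	Not protein-affecting	False	noncoding	0
SCP2	rs116197074	-	-	Yes	0.0056	INT	-	-	Not protein-affecting	False	noncoding	0
MAML3	rs116526711	-	-	Yes	0.007	INT	-	-	Not protein-affecting	False	noncoding	0
FTO	rs115378978	-	-	Yes	0.0078	INT	Prostate	-	Not protein-affecting	False	noncoding	1
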