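key	key_type	cancer_types	crc_types	crc_related	oncogenic_class	tumor_driver	source
rs79397892	rsid			false	Passenger	true	CGI
rs78826513	rsid			false	Driver	true	CGI
rs78552667	rsid			false	Passenger	true	CGI
rs201411821	rsid			false	Driver	true	CGI
rs80261016	rsid			false	Driver	true	CGI
rs201602708	rsid			false	Driver	true	CGI
rs63750539	rsid	Leukemia; Lymphoma; Melanoma; Pancreatic; Liver; Fallopian; Endometrial; Ovarian; Breast; Prostate; Bladder; Thyroid; Esophageal; Lung	Lynch syndrome; Colorectal melanoma; Microsatellite Instability; Hereditary non-polyposis; Colon; Gastric; Stomach	true	Driver	true	OncoKB
rs373141354	rsid	Melanoma		false	Passenger	false	GAD
rs551763507	rsid	Neuroblastoma		false	Passenger	false	GAD
rs76670455	rsid	Leukemia		false	Passenger	false	GAD
rs763119571	rsid		Colorectal	true	Passenger	false	CGI
rs115378978	rsid	Prostate		false	Not protein-affecting	false	SNPnexus
RELN	gene	Leukemia; Lung; Hepatocellular	Gastric	true	unknown	false	OncoKB
IRS2	gene	Esophageal	CRC; Intestinal; Stomach	true	unknown	false	My Cancer Genome
FOXP1	gene	Bladder; Endometrial; Lung; Salivary Gland; Breast; Skin; Hepatobiliary; Prostate; Glioma	Esophagogastric; Gastrointestinal; CRC	true	unknown	false	My Cancer Genome
RRAS2	gene	Breast; Ovarian		false	unknown	false	My Cancer Genome
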