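gene	sv_id	lrls	irls	hrls	af_1000g	location	cancer_related	crc_related	bold
ADAM10	15_58912864_58912865_BND_1	Yes	-	-	NA	INT	-	-	0
ADAM10	15_58913242_58913243_BND_1	Yes	-	-	NA	INT	-	-	0
ATP11A	13_113518019_113519165_DEL_1	Yes	-	-	NA	INT	-	-	0
ATP11A	13_113499584_113500055_DEL_1	-	-	Yes	NA	INT	-	-	0
GIGYF2	2_233668385_233668386_BND_1	Yes	-	-	NA	INT	-	-	0
GIGYF2	2_233668758_233668759_BND_1	Yes	-	-	NA	INT	-	-	0
LINC01137	1_37938257_37938258_BND_1	Yes	-	-	NA	INT	-	-	0
LINC01137	1_37938376_37938377_BND_1	Yes	-	-	NA	INT	-	-	0
RELN	7_103463079_103463080_BND_1	-	-	Yes	0.0001	INT	Leukemia; Lung; Hepatocellular	Gastric	1
RELN	7_103463462_103463463_BND_1	-	-	Yes	0.0001	INT	Leukemia; Lung; Hepatocellular	Gastric	1
DIP2C	10_523437_523544_DEL_1	Yes	-	-	NA	INT	-	-	0
WDR37	10_1164005_1164234_DEL_1	Yes	-	-	NA	INT	-	-	0
DCAKD	17_43129091_43129429_DEL_1	Yes	-	-	NA	INT	-	-	0
CDH4	20_60216779_60217071_DEL_1	Yes	-	-	0.0003	INT	-	-	0
MOV10L1	22_50585735_50585941_DEL_1	Yes	-	-	NA	INT	-	-	0
DNA2	10_70222778_70222779_BND_1	Yes	-	-	NA	INT	-	-	0
SBF2	11_10293916_10293917_BND_1	Yes	-	-	NA	INT	-	-	0
ANO5	11_22214883_22214884_BND_1	Yes	-	-	NA	EX	-	-	0
CHPT1	12_102107161_102107162_BND_1	Yes	-	-	NA	INT	-	-	0
MYO5B	18_47698458_47698459_BND_1	Yes	-	-	NA	INT	-	-	0
PLCB1	20_8414039_8414040_BND_1	Yes	-	-	0.0005	INT	-	-	0
APOL1	22_36651344_36651345_BND_1	Yes	-	-	0.0015	INT	-	-	0
NOP14	4_2941531_2941532_BND_1	Yes	-	-	NA	INT	-	-	0
MRPS18A	6_43655533_43655534_BND_1	Yes	-	-	NA	EX	-	-	0
CNTNAP2	7_147571596_147571597_BND_1	Yes	-	-	NA	INT	-	-	0
DPP6	7_153760690_153760691_BND_1	Yes	-	-	NA	INT	-	-	0
B4GALT1	9_33130549_33130550_BND_1	Yes	-	-	NA	INT	-	-	0
IRS2	13_110418067_110419056_DEL_1	-	Yes	-	NA	INT	Esophageal	CRC; Intestinal; Stomach	1
RAP1GAP2	17_2904534_2904873_DEL_1	-	Yes	-	NA	INT	-	-	0
ASIC2	17_31596693_31596759_DEL_1	-	Yes	-	NA	INT	-	-	0
MMP20	11_102472245_102472246_BND_1	-	Yes	-	NA	INT	-	-	0
KCNIP4	4_20933624_20933792_DEL_1	-	Yes	-	NA	INT	-	-	0
ADGRE4P	19_6987869_6987870_BND_1	-	Yes	-	0.0007	INT	-	-	0
DYNLRB1	20_33116231_33116232_BND_1	-	Yes	-	NA	INT	-	-	0
DTX2	7_76128462_76128463_BND_1	-	Yes	-	NA	INT	-	-	0
FIRRE	X_130813255_130974327_INV_1	-	Yes	-	NA	TX	-	-	0
BCCIP	10_127513335_127513754_DUP_1	-	-	Yes	NA	INT	-	-	0
MGAT5	2_134966704_134970130_DEL_1	-	-	Yes	NA	INT	-	-	0
COL18A1	21_46930863_46930934_DEL_1	-	-	Yes	NA	INT	-	-	0
FOXP1	3_71242366_71242638_DEL_1	-	-	Yes	NA	INT	Bladder; Endometrial; Lung; Salivary Gland; Breast; Skin; Hepatobiliary; Prostate; Glioma	Esophagogastric; Gastrointestinal; CRC	1
CTNND2	5_11816774_11817546_DEL_1	-	-	Yes	NA	INT	-	-	0
FSTL4	5_132918980_132924990_DEL_1	-	-	Yes	NA	INT	-	-	0
DLGAP2	8_1047119_1047802_DEL_1	-	-	Yes	0.0001	INT	-	-	0
PPP2R5A	1_212472702_212472703_BND_1	-	-	Yes	NA	INT	-	-	0
BMS1P4	10_75489277_75489278_BND_1	-	-	Yes	NA	INT	-	-	0
IFITM3	11_308031_320995_INV_1	-	-	Yes	NA	TX	-	-	0
RRAS2	11_14348706_14348707_BND_1	-	-	Yes	NA	INT	Breast; Ovarian	-	1
PRKRA	2_179314967_179314968_BND_1	-	-	Yes	NA	INT	-	-	0
NA	17_41438043_41440177_DEL_1	Yes	-	-	NA	NA	NA	NA	0
NA	11_1961293_1961294_BND_1	Yes	-	-	NA	NA	NA	NA	0
NA	17_38679442_38679443_BND_1	Yes	-	-	NA	NA	NA	NA	0
NA	19_17459958_17459959_BND_1	Yes	-	-	NA	NA	NA	NA	0
NA	6_28863601_28863602_BND_1	Yes	-	-	0.0002	NA	NA	NA	0
NA	6_28863898_28863899_BND_1	Yes	-	-	0.0002	NA	NA	NA	0
NA	17_41436517_41442619_DUP_1	-	-	Yes	NA	NA	NA	NA	0
NA	9_107816642_107816643_BND_1	-	-	Yes	NA	NA	NA	NA	0
NA	9_107817348_107817349_BND_1	-	-	Yes	NA	NA	NA	NA	0
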