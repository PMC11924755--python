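gene	pathway	esf
XRCC4	NHEJ	1.0
XRCC5	NHEJ	1.0
XRCC6	NHEJ	1.0
PRKDC	NHEJ	1.0
LIG4	NHEJ	1.0
NHEJ1	NHEJ	1.0
DCLRE1C	NHEJ	1.0
POLL	NHEJ	1.0
POLM	NHEJ	1.0
TP53BP1	NHEJ	1.0
APLF	NHEJ	1.0
PAXX	NHEJ	1.0
POLH	TLS	1.0
POLI	TLS	1.0
POLK	TLS	1.0
REV1	TLS	1.0
REV3L	TLS	1.0
MAD2L2	TLS	1.0
POLN	TLS	1.0
RAD18	TLS	1.0
UBE2A	TLS	1.0
UBE2B	TLS	1.0
XPA	NER	1.0
XPC	NER	1.0
ERCC1	NER	1.0
ERCC2	NER	1.0
ERCC3	NER	1.0
ERCC4	NER	1.0
ERCC5	NER	1.0
ERCC6	NER	1.0
ERCC8	NER	1.0
DDB1	NER	1.0
DDB2	NER	1.0
RAD23A	NER	1.0
RAD23B	NER	1.0
CETN2	NER	1.0
GTF2H1	NER	1.0
GTF2H5	NER	1.0
MNAT1	NER	1.0
CCNH	NER	1.0
CDK7	NER	1.0
XAB2	NER	1.0
POLQ	MMEJ	1.0
PARP1	MMEJ	1.0
LIG1	MMEJ	1.0
BRCA1	HR	1.0
BRCA2	HR	1.0
RAD51	HR	1.0
RAD51B	HR	1.0
RAD51C	HR	1.0
RAD51D	HR	1.0
XRCC2	HR	1.0
XRCC3	HR	1.0
RAD52	HR	1.0
RAD54L	HR	1.0
RAD54B	HR	1.0
PALB2	HR	1.0
BARD1	HR	1.0
BRIP1	HR	1.0
MRE11	HR	1.0
RAD50	HR	1.0
NBN	HR	1.0
BLM	HR	1.0
WRN	HR	1.0
RBBP8	HR	1.0
FANCA	FA	1.0
FANCB	FA	1.0
FANCC	FA	1.0
FANCD2	FA	1.0
FANCE	FA	1.0
FANCF	FA	1.0
FANCG	FA	1.0
FANCI	FA	1.0
FANCL	FA	1.0
FANCM	FA	1.0
UBE2T	FA	1.0
SLX4	FA	1.0
FAAP24	FA	1.0
FAAP100	FA	1.0
ATM	Checkpoint	1.0
ATR	Checkpoint	1.0
ATRIP	Checkpoint	1.0
CHEK1	Checkpoint	1.0
CHEK2	Checkpoint	1.0
TP53	Checkpoint	1.0
MDC1	Checkpoint	1.0
H2AX	Checkpoint	1.0
TOPBP1	Checkpoint	1.0
CLSPN	Checkpoint	1.0
RAD9A	Checkpoint	1.0
RAD1	Checkpoint	1.0
HUS1	Checkpoint	1.0
RAD17	Checkpoint	1.0
TIMELESS	Checkpoint	1.0
TIPIN	Checkpoint	1.0
WEE1	Checkpoint	1.0
CDC25A	Checkpoint	1.0
CDC25C	Checkpoint	1.0
RNF8	Checkpoint	1.0
MLH1	MMR	1.0
MLH3	MMR	1.0
MSH2	MMR	1.0
MSH3	MMR	1.0
MSH6	MMR	1.0
PMS1	MMR	1.0
PMS2	MMR	1.0
EXO1	MMR	1.0
RFC1	MMR	1.0
PCNA	MMR	1.0
XRCC1	BER	1.0
APEX1	BER	1.0
APEX2	BER	1.0
OGG1	BER	1.0
MUTYH	BER	1.0
NTHL1	BER	1.0
NEIL1	BER	1.0
NEIL2	BER	1.0
NEIL3	BER	1.0
UNG	BER	1.0
SMUG1	BER	1.0
TDG	BER	1.0
MBD4	BER	1.0
POLB	BER	1.0
FEN1	BER	1.0
LIG3	BER	1.0
PNKP	BER	1.0
PARP2	BER	1.0
MGMT	DR	1.0
ALKBH2	DR	1.0
ALKBH3	DR	1.0
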