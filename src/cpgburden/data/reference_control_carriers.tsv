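gene	control_carriers
PMS2	4
NBN	4
FH	0
RET	2
DMBT1	2
RAD50	3
ATRIP	3
BLM	7
ERCC2	8
LIG3	1
MSH3	6
SLX4	2
AXIN1	0
ERCC5	0
ERCC6	0
EXO1	2
FANCA	7
FANCD2	0
FANCG	2
HOXB13	4
MCPH1	10
MDC1	0
MLH3	1
MMP8	5
NHEJ1	0
PIK3CG	0
PMS1	2
RAD1	0
RECQL5	6
SBDS	13
SETX	10
SMARCA4	0
TLR2	1
TLR4	2
XRCC1	7
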