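gene	role	partner	relation
TGFBR2	ts_target	CDKN1A	upregulates
CDKN1A	ts_target	RB1	activates
LATS2	ts_target	CDK2	inhibits
RBL2	ts_target	E2F1	represses
ZBTB7A	ts_target	RB1	stabilizes
PTEN	ts_target
RB1	ts_target	E2F1	inhibits
E2F1	transcription_factor	MCM7	transactivates
E2F2	transcription_factor	MCM7	transactivates
E2F3	transcription_factor	MCM7	transactivates
MYC	transcription_factor	MIR17HG	transactivates
MCM7	host_gene
MIR17HG	host_gene
CDK2	cell_cycle
CDC25A	cell_cycle
CCNA2	cell_cycle
MKI67	cell_cycle
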