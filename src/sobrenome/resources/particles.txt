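# Non-significant name particles removed before matching (full-token matches).
DA
DE
DO
DAS
DOS
E
DEL
VON
VAN
DI
LA
LE
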