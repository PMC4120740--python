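code	term_id
10011224	OAE_0001007
10012431	OAE_0001009
10016558	OAE_0001006
10034835	OAE_0001004
10038738	OAE_0002001
10039083	OAE_0001003
10044302	OAE_0001005
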