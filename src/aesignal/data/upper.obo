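format-version: 1.4

[Term]
id: OAE_0000001
name: adverse event

[Term]
id: OAE_0000003
name: causal adverse event
is_a: OAE_0000001 ! adverse event

[Term]
id: OAE_0000004
name: vaccine adverse event
is_a: OAE_0000001 ! adverse event

[Term]
id: OAE_0000005
name: drug adverse event
is_a: OAE_0000001 ! adverse event

[Term]
id: OAE_0000006
name: severe adverse event
is_a: OAE_0000001 ! adverse event

[Term]
id: OAE_0000007
name: causal adverse event hypothesis
is_a: OAE_0000001 ! adverse event
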