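format-version: 1.4

[Term]
id: OAE_0000001
name: adverse event

[Term]
id: OAE_0000003
name: causal adverse event
is_a: OAE_0000001 ! adverse event

[Term]
id: OAE_0001001
name: inflammation AE
is_a: OAE_0000001 ! adverse event

[Term]
id: OAE_0001002
name: respiratory system inflammation AE
is_a: OAE_0001001 ! inflammation AE
relationship: located_in UBERON_0001004 ! respiratory system

[Term]
id: OAE_0001003
name: rhinitis AE
is_a: OAE_0001002 ! respiratory system inflammation AE
relationship: located_in UBERON_0000004 ! nose
xref: MedDRA:10039083

[Term]
id: OAE_0001004
name: pharyngitis AE
is_a: OAE_0001002 ! respiratory system inflammation AE
relationship: located_in UBERON_0001042 ! pharynx
xref: MedDRA:10034835

[Term]
id: OAE_0001005
name: tracheitis AE
is_a: OAE_0001002 ! respiratory system inflammation AE
relationship: located_in UBERON_0003126 ! trachea
xref: MedDRA:10044302

[Term]
id: OAE_0001006
name: fever AE
is_a: OAE_0000001 ! adverse event
xref: MedDRA:10016558

[Term]
id: OAE_0001007
name: cough AE
is_a: OAE_0000001 ! adverse event
xref: MedDRA:10011224

[Term]
id: OAE_0001009
name: dermatitis AE
is_a: OAE_0001001 ! inflammation AE
relationship: located_in UBERON_0002097 ! skin of body
xref: MedDRA:10012431

[Term]
id: OAE_0002001
name: respiratory system AE
is_a: OAE_0000001 ! adverse event
intersection_of: OAE_0000001 ! adverse event
intersection_of: located_in UBERON_0001004 ! respiratory system
xref: MedDRA:10038738

[Term]
id: UBERON_0000004
name: nose
relationship: part_of UBERON_0001004 ! respiratory system

[Term]
id: UBERON_0000970
name: eye

[Term]
id: UBERON_0001004
name: respiratory system

[Term]
id: UBERON_0001042
name: pharynx
relationship: part_of UBERON_0001004 ! respiratory system

[Term]
id: UBERON_0002097
name: skin of body

[Term]
id: UBERON_0003126
name: trachea
relationship: part_of UBERON_0001004 ! respiratory system
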