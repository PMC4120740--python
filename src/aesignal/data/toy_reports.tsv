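report_id	intervention	vax_date	onset_date	age	sex	causality	ae_codes
R001	V1	2013-01-05	2013-01-06	34	F	possibly related	10016558
R002	V1	2013-01-07	2013-01-08	2	M		10039083
R003	V2	2013-02-01	2013-02-02	45	F	not related	10016558;10034835
R004	V2	2013-02-03		61	M		10044302
R005	V3	2013-03-01	2013-03-04	60	M	probably related	10039083
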