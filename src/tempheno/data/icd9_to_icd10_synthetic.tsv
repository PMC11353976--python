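icd9	icd10
410.1	I21.0
410.9	I21.9
250.00	E11.9
250.01	E10.9
272.4	E78.5
401.9	I10
414.01	I25.10
428.0	I50.9
496	J44.9
530.81	K21.9
715.90	M19.90
724.2	M54.5
285.9	D64.9
300.00	F41.9
311	F32.9
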