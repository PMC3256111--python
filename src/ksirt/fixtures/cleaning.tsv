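reason	n_removed	percent
Depressive Disorder	80	1.09
Bipolar Disorder	76	1.03
No Diagnoses provided	3	0.04
PANSS Item Score missing	2	0.03
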