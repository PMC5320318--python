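# Published shared-epitope dose counts among RA cases.
population	n_individuals	n_single_dose	n_double_dose
Tunisian	132	66	12
French	173	100	35
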