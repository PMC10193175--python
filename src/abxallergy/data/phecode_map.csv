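icd10_prefix,phecode_label
L23,contact_dermatitis
L24,contact_dermatitis
L25,contact_dermatitis
T78.2,anaphylactic_shock_nos
L50,urticaria
T78.4,allergies_other
Z91.0,allergies_other
T36,ae_antibiotic_penicillin
T36.0X5,ae_antibiotic_penicillin
T50.905,ae_nonspecific_drug
R21,rash_skin_erupt
R23,symptoms_affecting_skin
L29,symptoms_affecting_skin
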