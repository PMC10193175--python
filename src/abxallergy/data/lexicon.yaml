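# Default clinical-note keyword lexicon for allergic-type reaction screening.
# A note flags positive when it contains at least one NON-negated symptom
# term and at least one medication term (case-insensitive, word-boundary,
# phrases matched as contiguous token runs). Substitute your own lexicon by
# passing a file of the same shape.
symptom_terms:
  - rash
  - hives
  - urticaria
  - itching
  - pruritus
  - swelling
  - angioedema
  - anaphylaxis
  - wheeze
  - wheezing
  - shortness of breath
  - flushing
medication_terms:
  - cefazolin
  - cephalexin
  - ceftriaxone
  - cefuroxime
  - vancomycin
  - doxycycline
  - minocycline
  - amoxicillin
  - ampicillin
  - penicillin
  - nafcillin
  - sulfamethoxazole
  - trimethoprim
  - clindamycin
  - daptomycin
  - ciprofloxacin
  - levofloxacin
  - moxifloxacin
  - meropenem
  - ertapenem
  - azithromycin
  - erythromycin
  - antibiotic
negation_triggers:
  - "no"
  - denies
  - without
  - negative for
  - "not"
negation_scope_tokens: 5
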