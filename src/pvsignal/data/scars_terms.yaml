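# Default severe-cutaneous-adverse-reaction (SCARs) MedDRA preferred terms.
# This is a plain configurable list, not a licensed SMQ export; edit or replace
# it via CohortConfig.event_terms to use a different term set.
scars_terms:
  - STEVENS-JOHNSON SYNDROME
  - TOXIC EPIDERMAL NECROLYSIS
  - DRUG REACTION WITH EOSINOPHILIA AND SYSTEMIC SYMPTOMS
  - ACUTE GENERALISED EXANTHEMATOUS PUSTULOSIS
  - DRUG-INDUCED HYPERSENSITIVITY SYNDROME
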