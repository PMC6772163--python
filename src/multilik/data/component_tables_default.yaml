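# PLACEHOLDER lookup tables and parameters for non-segregation evidence
# components.  The pathology and family-history values below stand in for
# externally published calibrations and must be replaced with the published
# estimates before clinical use; the structure (information levels, age bands,
# category names) is what the pipeline relies on.
pathology:
  # Unset marker fields are wildcards.  age_max is exclusive.
  - {gene: BRCA1, er: negative, grade: 3, age_max: 50, lr: 3.73}
  - {gene: BRCA1, er: negative, grade: 3, age_min: 50, lr: 2.41}
  - {gene: BRCA1, er: negative, pr: negative, her2: negative, grade: 3, age_max: 50, lr: 9.99}
  - {gene: BRCA1, er: negative, pr: negative, her2: negative, grade: 3, age_min: 50, lr: 5.28}
  - {gene: BRCA1, er: negative, lr: 1.67}
  - {gene: BRCA1, er: positive, lr: 0.40}
  - {gene: BRCA1, grade: 3, lr: 1.49}
  - {gene: BRCA1, grade: 1, lr: 0.25}
  - {gene: BRCA1, grade: 2, lr: 0.73}
  - {gene: BRCA2, er: negative, grade: 3, lr: 1.20}
  - {gene: BRCA2, er: positive, grade: 3, lr: 1.77}
  - {gene: BRCA2, er: negative, lr: 0.81}
  - {gene: BRCA2, er: positive, lr: 1.06}
  - {gene: BRCA2, grade: 3, lr: 1.19}
  - {gene: BRCA2, grade: 1, lr: 0.51}
  - {gene: BRCA2, grade: 2, lr: 0.79}
family_history:
  # Category labels index a family-history profile score band.
  band_0: 0.18
  band_1: 0.92
  band_2: 1.48
  band_3: 2.64
  band_4: 8.13
  band_5: 28.61
cooccurrence:
  theta_pathogenic: 0.0001
  theta_neutral:
    BRCA1: 0.0008
    BRCA2: 0.0012
case_control:
  assumed_rr:
    BRCA1: 10.0
    BRCA2: 8.0
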