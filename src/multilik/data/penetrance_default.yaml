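# PLACEHOLDER penetrance configuration.
#
# The age-bracket structure (seven brackets: <30, 30-39, ..., 70-79, 80+) and
# the carrier/population hazard-ratio parameterisation are fixed by the model,
# but the numeric values below are illustrative placeholders ONLY.  Users must
# substitute published baseline incidence and hazard-ratio estimates for the
# gene and population under analysis before interpreting segregation LRs.
bracket_starts: [0, 30, 40, 50, 60, 70, 80]
open_bracket_width: 20
allele_frequency: 0.001
cancers:
  breast_female:
    baseline: [1.0e-05, 4.0e-04, 1.5e-03, 2.0e-03, 2.5e-03, 3.0e-03, 3.0e-03]
    hazard_ratio: [20.0, 20.0, 11.0, 11.0, 7.0, 5.0, 4.0]
  ovarian:
    baseline: [1.0e-06, 2.0e-05, 1.0e-04, 2.5e-04, 4.0e-04, 4.5e-04, 4.5e-04]
    hazard_ratio: [4.0, 30.0, 30.0, 18.0, 10.0, 6.0, 4.0]
  breast_male:
    baseline: [1.0e-07, 1.0e-06, 5.0e-06, 1.0e-05, 2.0e-05, 3.0e-05, 3.0e-05]
    hazard_ratio: [10.0, 10.0, 10.0, 10.0, 10.0, 10.0, 10.0]
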