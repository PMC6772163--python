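# multilik

Quantitative classification of *BRCA1*/*BRCA2* sequence variants with the
multifactorial likelihood model, plus the calibration machinery for mapping
evidence types onto ACMG/AMP code strengths.

The model combines a prior probability of pathogenicity (assigned upstream
from bioinformatic prediction) with multiplicative likelihood ratios (LRs)
from independent clinical evidence types — co-segregation, breast tumor
pathology, co-occurrence in trans with a pathogenic variant, reported family
history, and case-control data — via the odds-form Bayes rule, and maps the
posterior onto the IARC five-tier scale (Class 1 Benign … Class 5
Pathogenic). Variants whose combined LR falls strictly between 0.5 and 2 are
gated as uninformative and receive no posterior.

## Modules

| Module | What it does |
| --- | --- |
| `multilik.model_core` | Evidence data model, prior assignment, LR combination, informativeness gate, Bayes posterior, IARC classification, common-variant Class 1 rule |
| `multilik.segregation` | Pedigree co-segregation Bayes factor (causal vs neutral) by exact variable elimination over untyped genotypes, with an age-bracket hazard penetrance model and censoring rules |
| `multilik.evidence_components` | Pathology LR lookup, co-occurrence LR, family-history lookup, case-control profile-likelihood LR, population-frequency categorisation |
| `multilik.calibration` | Cross-tab LRs with zero-cell convention, log-scale Wald 95% CIs, ACMG/AMP strength mapping, concordance counting |
| `multilik.synthetic_data` | Seeded generators for pedigrees (ascertained through an affected carrier proband), evidence cohorts, and per-population allele-count tables |
| `multilik.io_cli` / `multilik.cli` | TSV/YAML dialects, packaged fixtures, pipeline entry points, `multilik` command line |

Packaged fixtures (`src/multilik/data/`) include the published reference set
of 94 (Likely) Pathogenic classifications, the published calibration
cross-tabs (splicing, protein function, population frequency), and clearly
labelled **placeholder** penetrance and component lookup tables — substitute
published estimates before interpreting real data.

## CLI

```bash
multilik classify  --evidence evidence.tsv --out outdir       # TSV + summary
multilik segregate --pedigrees ped.tsv --penetrance pen.yaml --out outdir
multilik calibrate --out outdir                                # packaged cross-tabs
multilik calibrate --crosstabs mytabs.tsv --out outdir
multilik simulate pedigrees --seed 7 --n 100 --hypothesis causal --out outdir
multilik version
```

File dialects are documented in `multilik/io_cli.py`; identical inputs and
seeds produce byte-identical outputs.

## Example

```python
from multilik import VariantEvidence, classify_variant

evidence = VariantEvidence(
    gene="BRCA1",
    hgvs_c="c.131G>T",
    prior=0.81,
    components={"segregation": [156.17], "pathology": [41.24]},
)
result = classify_variant(evidence)
result.posterior     # 0.99997...
result.iarc_class    # IARCClass.C5
```
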