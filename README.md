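# relapse-evo

Genomic analysis toolkit for paired primary/relapse tumor cohorts:

* **Scar scores** from allele-specific copy-number segments: LOH events
  >15 Mb, telomeric allelic imbalance, large-scale state transitions, their
  unweighted sum, the HR-deficiency phenotype call (score ≥ 42 or bi-allelic
  BRCA1/2), the fraction of the autosomal genome with non-diploid total copy
  number, and whole-genome-doubling detection.
* **HR-pathway classification**: per-lesion bi-allelic LOF / bi-allelic VUS /
  mono-allelic status for a configurable 102-gene homologous-recombination
  gene list, covering all eight enumerated germline/somatic mechanism
  combinations, the putative-LOF upgrade for HR-deficient lesions, and
  shared-event detection across lesion pairs.
* **Clonal architecture**: clone abundances from inclusive cancer-cell
  fractions, Shannon and Gini–Simpson diversity, trunk/branch labeling, and
  classification of primary→relapse evolution into three models (de novo
  subclone emergence, minor-survivor HR-deficient relapse, selective
  expansion) with an explicit unclassified fallback.
* **Mutational signatures**: 96-trinucleotide-context catalogs with
  pyrimidine-strand collapsing, de novo extraction by KL-divergence NMF
  (best of restarts, seed-deterministic), cosine-similarity catalog matching,
  exposure summaries, and a signature–gene OLS screen with
  Benjamini–Hochberg correction.
* **Actionability reporting**: local rule-table lookup plus HR-deficiency
  biomarkers, clone/CCF/trunk-branch annotation, cohort summaries, exact
  small-sample paired signed-rank tests, and Pearson correlation.
* **Synthetic cohorts**: a generator that plants scar events, evolution-model
  clone trees, signature mixtures, and HR-gene variant scenarios with exact,
  machine-checkable ground truth.

## CLI

```bash
relapse-evo simulate  --seed 42 --out cohort/            # synthetic cohort + truth ledger
relapse-evo scar      --segments cohort/segments.tsv --out scar.tsv
relapse-evo biallelic --variants cohort/hr_variants.tsv --hrd scar.tsv --out biallelic.tsv
relapse-evo clonal    --trees cohort/trees --scar scar.tsv --out clonal.tsv
relapse-evo signatures --mutations cohort/mutations.tsv --rank 3 --seed 1 --out sig/
relapse-evo report    --scar scar.tsv --trees cohort/trees --out report/
relapse-evo summarize                                     # bundled clinical table
```

Coordinates are 1-based closed intervals (SEG convention). The bundled
assembly is hg19 (22 autosomes + X; only autosomes are scored); pass
`--assembly` to `scar` to override it, and a YAML `--config` to override any
analysis constant.

## Layout

```
src/relapse_evo/
  genome_reference.py       coordinate model + shared analysis constants
  io_formats.py             SEG/MAF-lite/tree-JSON/catalog readers & writers
  synthetic_cohort.py       ground-truth cohort generator
  scar_genomics.py          scar scores, CIN fraction, WGD, HRD phenotype
  hr_pathway.py             bi-allelic HR-gene classification
  clonal_architecture.py    diversity indices + evolution-model calls
  mutational_signatures.py  96-context catalogs, NMF, matching, BH screen
  actionability_report.py   actionability, clinical summaries, paired stats
  cli.py                    click entry point (`relapse-evo`)
  data/                     assembly, clinical/actionability tables, rules,
                            signature fixtures, HR gene list
```
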