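# driverfis

Identification of cancer driver genes from somatic-mutation cohorts using
per-mutation functional-impact scores (FIS).

Most somatic mutations in a tumor are passengers; driver genes are the
minority whose mutations confer a growth advantage. Frequency-based callers
ask whether a gene is mutated more often than expected. `driverfis` instead
asks whether a gene's mutations are more *damaging* than expected: it sums
MutationAssessor-style impact scores per gene and tests that total against a
gene-specific background expectation learned from genomic covariates. It is
aimed at anyone with a cohort MAF (TCGA-style Mutation Annotation Format), a
substitution-level FIS lookup table, and per-gene covariate annotations.

## Model

For gene *g* with observed FIS total
y_g = Σ_i f_i (sum over its mutations' filled scores), the background is a
normal GLM with identity link over p = 12 standardized genomic covariates
(expression level, replication time, HiC compartment, coding length,
missense constraint, expression hubness, regulator status, CNV, methylation,
plus three computed from the MAF: total mutations, harmful mutations, sd of
per-patient FIS):

    y_g = x_gᵀβ + ε_g,   ε_g ~ N(0, σ₀²)

fitted by maximum likelihood (closed-form least squares; σ̂₀² = RSS/n). The
predicted background y_g^b = x_gᵀβ̂ is then shrunk toward the gene's **FIS
circle** — its nearest feature-space neighbors whose observed scores pass a
two-sided standard-normal similarity test Q ≤ 0.1, capped at 100 members:

    y_g^fb = λ·y_g^b + (1−λ)·y_g^neighbor,

where y_g^neighbor is the inverse-distance-weighted mean of the circle's
observed scores (empty circle: y_g^fb = y_g^b; default λ = 0.5). The
observed total is re-weighted by two ratiometric factors,

    w₁ = m^harm / m^total ∈ [0,1],   w₂ = exp(m^harm-samples / M) ∈ [1,e],

and y^w = w₁·w₂·y_g is tested upper-tail against N(y_g^fb, σ₀²); genes with
no harmful (nonsilent/null) mutation receive p = 1. Benjamini–Hochberg
q-values at q ≤ 0.05 define the driver calls. Missing covariate cells are
imputed from the K = 100 nearest genes before standardization; missing FIS
values are filled from cohort effect-class means (or fixed severity
constants when a class has no observed score).

## Worked example

`examples/02_micro_walkthrough.py` scores a hand-checkable 6-gene,
4-sample cohort against a preset N(2, 1) background:

```
         y_obs  m_total  m_harm_mut  m_harm_samples     w1     w2     y_w  p_value  q_value  is_driver
FOXTROT 9.0000        4           4               4 1.0000 2.7183 24.4645   0.0000   0.0000       True
CHARLIE 6.5000        2           2               1 1.0000 1.2840  8.3462   0.0000   0.0000       True
ALPHA   4.0000        4           2               2 0.5000 1.6487  3.2974   0.0972   0.1945      False
DELTA   1.0000        1           1               1 1.0000 1.2840  1.2840   0.7630   1.0000      False
BRAVO   0.8000        2           0               0 0.0000 1.0000  0.0000   1.0000   1.0000      False
ECHO    1.2000        2           0               0 0.0000 1.0000  0.0000   1.0000   1.0000      False
```

FOXTROT carries harmful mutations in all 4 samples, so w₂ hits its maximum
e and its weighted score 9e lands far in the null's upper tail; BRAVO and
ECHO have no harmful mutation and are assigned p = 1 outright. The other
examples simulate full cohorts (`01_simulate_and_call.py`), sweep λ
(`03_lambda_sweep.py`), and benchmark call sets against reference panels
(`04_evaluate_panels.py`). The same pipeline is available from the shell:

```sh
driverfis simulate --out cohort/ --n-drivers 5 --seed 1
driverfis run --maf cohort/cohort.maf --fis-table cohort/fis_table.tsv \
    --features cohort/features.tsv --out results/
```

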