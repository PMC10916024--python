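# Methods

## Scope and notation

`driverfis` calls cancer driver genes from three inputs: a cohort mutation
table (MAF), a substitution-level functional-impact score (FIS) lookup
table, and a per-gene covariate table. Per gene *g* it forms an observed
FIS total y_g, an expected background y_g^fb, and an upper-tail p-value for
the re-weighted observed total; drivers are the genes with BH q ≤ 0.05.

## Effect classes and score filling

Each MAF `Variant_Classification` maps through an editable two-column
dictionary (shipped default patterned on the MutSigCV mutation-type
dictionary) onto four effect classes — silent, nonsilent, noncoding, null —
plus `ignore` for unmapped categories; ignored records are excluded from
every downstream sum. "Harmful" means nonsilent or null.

Only single-nucleotide substitutions are looked up in the FIS table, keyed
by (chromosome, 1-based position, ref, alt) after normalizing labels (strip
`chr`, `MT`→`M`). Every unmatched mutation — lookup miss or non-SNV — is
filled with the cohort mean of the *observed* scores in its effect class;
the class means are computed once before any filling, so the operation is
idempotent and order-independent. A class with no observed score at all
falls back to fixed severity constants (silent 0, noncoding 1, nonsilent 2,
null 3). Indels and other multi-nucleotide events therefore always travel
the filling path; no attempt is made to key them against the
substitution-level table.

## Covariates and imputation

The design has 12 columns: nine external annotations and three computed
from the MAF itself — total mutation count, harmful mutation count, and the
sample sd (n−1) of per-patient FIS totals over patients carrying the gene
(0 for a single patient). The per-patient aggregation (rather than
per-mutation) was a genuinely open choice; per-patient totals match how the
observed statistic y_g accumulates.

Missing external cells are imputed before standardization. For a missing
entry (g, k), donors are genes with feature k observed; distances to g are
Euclidean over the other features, computed on values rescaled per column
to zero mean/unit sd over observed entries only (raw columns live on wildly
different scales — replication time runs to 1500, indicator columns are
0/1 — so unscaled distances would be dominated by one feature). Pairs where
either coordinate is missing are skipped rather than rescaled by the count,
so imputation never chains off imputed values. The K = 100 nearest donors
(ties at the cut broken lexicographically by gene symbol, for determinism)
contribute their mean; K is lowered with a warning when donors are scarce.
After imputation every column is z-scored across genes (sample sd, n−1); a
zero-variance column is a hard error naming the feature. Genes present in
the MAF but absent from the covariate table are kept under study with all
nine external cells treated as missing and imputed; genes absent from the
MAF are not under study (their observed total is undefined).

## Background model

With an identity link and normal errors, the GLM's maximum-likelihood
solution is ordinary least squares, so the fit is closed-form (numpy
`lstsq`, QR-backed) — exact and deterministic, with no iterative optimizer
to tune. σ̂₀² uses the ML divisor n; an `unbiased_variance` flag exposes
n−p−1. A rank-deficient design raises an error listing the collinear
columns. A numerically zero residual (RSS < 1e-12, e.g. noiseless toy
input) warns and floors σ₀ at 1e-8 so downstream p-values stay defined.

## Shrinkage

The FIS circle of gene *g* admits, scanning candidates nearest-first in
standardized feature space (full 12-feature Euclidean distance, ties by
symbol), genes whose observed scores pass the similarity statistic
Q = 2·min(Φ(y_g−y_i), 1−Φ(y_g−y_i)) against the gate Q ≤ 0.1, stopping at
100 members. Two deliberate escape hatches: `complement_ge` flips the gate
to Q ≥ 0.1 (the literal Q ≤ 0.1 rule admits *dissimilar* scores, which
contradicts the similarity rationale; the default follows the rule as
stated, the flag follows the rationale), and `scale_by_sigma0` divides the
score difference by σ̂₀ before the standard-normal reference (raw FIS
differences are not unit-variance). Neither alternative is the default.

The neighbor score is the inverse-distance-weighted mean of circle members'
observed scores, with distances floored at 1e-8 to keep weights finite.
The final background is y^fb = λ·y^b + (1−λ)·y^neighbor for a nonempty
circle, else y^b. λ is accepted on the closed interval [0, 1]: λ = 1
reproduces the unshrunken pipeline bit-for-bit and λ = 0 is pure
neighborhood, both useful operating points for the sweep.

## Testing

w₁ = m^harm/m^total (a mutation count ratio) and w₂ = exp(m̃/M) where m̃
counts *samples* with ≥ 1 harmful mutation — the two numerators are
deliberately distinct quantities. p = P(N(y^fb, σ₀²) ≥ w₁w₂·y_g), one-sided
upper because drivers are a positive excess; genes with zero harmful
mutations get p = 1 and stay in the BH family (they can only inflate the
correction, never benefit from it). σ₀ is the GLM's estimate, not
re-estimated after shrinkage. BH adjustment is delegated to
statsmodels (`fdr_bh`) and cross-checked in the tests against a literal
step-up implementation; calls use q ≤ 0.05 inclusive.

## Synthetic cohorts

The generator emulates the model's own generative assumptions, not real
tumor biology: no mutational signatures, trinucleotide context, or
chromosomal clustering, and positions are bookkeeping keys. Two levels:

* `simulate_regression` draws X ~ N(0,1) (standardized) and
  y = Xβ + N(0, σ₀²) directly — the clean probe for parameter recovery,
  where coefficient errors can be compared against analytic standard
  errors.
* `simulate_cohort` builds the full file set. Mutation counts are
  1 + Poisson(mean − 1) per gene (default mean 3), effects drawn from a
  fixed mixture (silent .25, nonsilent .55, null .10, noncoding .10),
  samples uniform over the cohort (default 200 samples, 2,000 genes).
  y_g is drawn from the GLM over the nine externals, the two realized
  counts, and a latent FIS-dispersion value; per-mutation scores are then
  shifted so each gene's total equals its draw (the pipeline's recomputed
  sd-of-FIS column therefore correlates with, but does not equal, the
  latent draw — full self-consistency there would be circular, since the
  covariate depends on the scores being allocated). Default σ₀ = 2.
  Spiked drivers receive driver_effect = 70 total excess FIS as 20
  nonsilent mutations of 3.5 each in distinct samples — "strong effect"
  territory, chosen so the excess stands far outside σ₀ even after the
  count covariates absorb their share. Missingness defaults: 5% of feature
  cells, 30% of FIS lookups (MutationAssessor-style tables miss many
  sites), so every filling/imputation path is exercised by default.

Because the weighted statistic w₁w₂·y_g is below y_g for typical genes
(w₁ < 1 dominates w₂ ≥ 1), null p-values are conservative rather than
uniform; the false-positive rate under a global null sits far below the
nominal 5%, which the acceptance checks confirm but which also means
passing them says nothing about calibration on real cohorts, where the
background model may be misspecified.

## Problem sizes and numerics

The acceptance checks use 3,000 genes for parameter recovery, 20 cohorts
of 500 genes for null error control, and 20 seeds of the 2,000-gene /
200-sample / 20-driver condition for recovery — sizes at which the
O(n²) distance matrix and circle construction stay comfortable on one
core while the statistics are stable. All pairwise work is vectorized
(scipy `pdist`, one stable argsort of the distance matrix with columns
pre-ordered by symbol so distance ties break lexicographically).
Determinism: every generator takes an explicit seed; identical
configuration and inputs reproduce results byte-for-byte, and the run
manifest records config plus input checksums.

## Limitations

Real-cohort performance depends on covariate quality and on the normality
of FIS totals, neither of which the synthetic generator stresses. The
literal Q ≤ 0.1 circle gate admits score-dissimilar neighbors (see above).
Duplicate mutation rows are kept unless `dedup` is set. No transcript- or
domain-level aggregation, no liftover, no VCF ingestion, and no
re-computation of external covariates or of the impact scores themselves.
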