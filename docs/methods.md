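# Methods

`epiclock` builds and evaluates blood-based DNA-methylation age clocks for
adolescents and young adults. This note documents the models and procedures
the package implements, the choices made where the design was genuinely
open, and what the synthetic cohorts do and do not establish.

## The clock model

A clock is a sparse linear predictor over CpG beta values,

    score(x) = b0 + sum_j w_j * x_j,        x_j in [0, 1],

whose response is chronological age passed through a piecewise
log-linear map

    F(a) = log((a + 1) / (A + 1))       a <= A
    F(a) = (a - A) / (A + 1)            a >  A

with "adult age" knot A = 20 y by default. F is continuous and strictly
increasing; predictions are reported in years through its exact inverse.
The transform compresses childhood, where methylation drifts quickly, and
is kept optional (`use_transform=False`) because over a narrow adolescent
span the fit is nearly indifferent to it; it is enabled by default because
it never hurts and matters when a broad age span is used.

Coefficients are estimated by the elastic net with standardized predictors:

    (1/2n) * ||y - b0 - X b||^2 + lambda * (alpha*|b|_1 + (1-alpha)/2*|b|_2^2)

at mixing parameter alpha = 0.5. The penalty lambda is chosen by 10-fold
cross-validation of mean squared error over a geometric path of 100 values,
from the smallest lambda that zeroes every coefficient down four orders of
magnitude. Folds are contiguous blocks of one random shuffle (no
stratification). Two selection rules are exposed: `min` (argmin of CV
error) and `1se` (largest lambda within one standard error of that
minimum, where the SE is the across-fold standard deviation of fold-mean
losses divided by sqrt(k)). The default is `1se`: it costs little CV error,
roughly halves the number of selected sites, and in our repeated-split
experiments transfers better to an independent cohort — the same
qualitative trade observed when such clocks are built on real arrays
(hundreds of sites at `min` vs fewer than three hundred at `1se`).

The solver is coordinate descent (`sklearn.linear_model.enet_path`) with
warm starts along the path; the pure-ridge limit alpha = 0 is solved in
closed form per lambda because coordinate descent has no soft threshold to
exploit there. The test suite checks the solutions against an independent
proximal-gradient (ISTA) solver to 1e-6 on small instances. The
coordinate-descent duality-gap tolerance defaults to 1e-4, which keeps a
full 10-fold path fit on 900 x 2000 data under a minute on one CPU;
tighten `TrainingConfig.tol` when coefficient-level reproducibility across
solvers matters more than speed.

## Evaluation

Prediction error is summarized as MAD: the **median of absolute errors in
years** between predicted and chronological age — not the
median-absolute-deviation-from-median scale estimator. The repeated-split
protocol draws ten random 2/3–1/3 splits of the training cohort, fits a
full cross-validated clock on each 2/3, and records MAD on the held-out 1/3
and on an external cohort whose sample ids must be disjoint from training.
Per-repeat seeds derive deterministically from the configured seed, so a
given configuration always reproduces the same splits and the same MAD
distribution.

## Preprocessing

Beta values are `M / (M + U + offset)` with offset 100; the offset
stabilizes low-intensity probes and keeps betas strictly below 1. Probe
blacklists (SNP-associated, cross-reactive, absent-from-EPIC lists) are
supplied as plain-text files and removed with first-match attribution.
Sample QC is deliberately flag-only: a sample is reported when its missing
fraction exceeds 5% or its median beta leaves [0.2, 0.8], and nothing is
deleted automatically — array QC decisions belong to a human looking at
the report. These two criteria are objective stand-ins for the richer
chip-level diagnostics a full array pipeline would consult; background/
dye-bias normalization and reference-based cell deconvolution are upstream
methods the package consumes (normalized betas, cell-fraction columns),
not ones it reimplements.

## Multimodal-site removal

Probes overlapping common genetic variants produce beta distributions with
2–3 discrete clusters (roughly genotype classes) rather than an age trend,
and penalized fits happily pick them up as spurious predictors. The
detector runs a Gaussian KDE per site with Silverman bandwidth clipped to
at least 0.02 (avoiding spiky densities at large n), evaluated on a grid
extending beyond [0, 1] — truncating the density at the data boundary
would erase the prominence of clusters hugging 0 or 1. Local maxima with
prominence at least 10% of the peak density are kept, maxima closer than
0.2 beta are merged (keeping the higher), and a site is multimodal when
two or more modes survive. The prominence criterion is what separates a
genuine second cluster from the broad, gently skewed density of an
age-trending site. Sites with fewer than 10 non-missing values are
reported unimodal with a `low_n` note rather than guessed at. KDE peak
counting was chosen over a dip-statistic test because it also yields mode
locations for reports and gives a directly tunable specificity against
age-trend gradients. On planted data the defaults reach at least 95%
sensitivity on two-cluster sites 0.4 apart and at most 5% false flags on
age-trend sites; exact agreement with any particular published site count
is not a goal — such detectors are threshold-sensitive and residual
multimodal sites survive in real clocks.

## Batch correction

The adjustment is the standard parametric empirical-Bayes location/scale
recipe: per site, an OLS fit of batch indicators plus protected covariates;
standardization to residual scale; per-batch location (gamma) and scale
(delta^2) estimates shrunk across sites with moment-matched normal and
inverse-gamma priors (joint posterior-mode iteration, elementwise relative
convergence at 1e-4); adjustment back to the pooled level. In **reference
mode** all adjustments are expressed relative to one chosen batch — its
grand mean and pooled variance come from the reference batch alone, its
gamma* is 0 and delta*^2 is 1, and its samples pass through bit-identical.
Reference mode is the variant of practical interest: a clock trained on
reference-corrected data travels to a new cohort by mapping that cohort
onto the same reference. The implementation reproduces `sva::ComBat`
(default and `ref.batch` modes) to ~1e-6 on test fixtures, with one
deliberate divergence: adjusted betas are clipped to [0, 1] (they are
proportions) and the clipped count is logged.

Correction operates on the beta scale by default; a logit option exists
but is off, since the practical pipelines this mirrors apply the
adjustment to betas directly. Only the parametric EB variant is provided.
A protected covariate is one whose association with methylation must
survive the adjustment. Protecting age preserves planted age-beta slopes
to within 10% in the test suite, while correcting age-confounded batches
*without* protection measurably destroys the age signal — that failure
mode is pinned down as a property test, not offered as a mode. For cohorts
whose age is unknown (the forensic setting) the package can protect the
clock's own predicted age instead (`protect_with_predicted_age`).

The PCA diagnostic reports, per principal component of the mean-centered
sample matrix, the one-way ANOVA F statistic of batch labels on the scores;
successful correction drives the largest per-PC F down sharply.

## Synthetic cohorts

The generator emulates the structure an adolescent blood 450K cohort
presents to this pipeline. Defaults — chosen once, as a realistic desk-scale
rendering of such a study — are 900 samples, ages uniform on 12–25 y, in
three studies of 300 with logit-scale shifts (0, +0.2, −0.2); 2000 CpGs of
which 2% trend with age, 5% are SNP-like multimodal, the rest flat noise;
residual beta noise sd 0.03. Signal sites follow
`logistic(b0 + slope * F(age))` with |slope| uniform on 0.8–2.0 logit units
per transformed-age unit and random sign, so the piecewise log-linear
transform is exactly the right link during recovery tests; a `linear_age`
mode misspecifies the link on purpose, and a `slope_change_at` knot makes
slopes differ between age segments (used to show that training on a narrow
12–25 window predicts 18-year-olds better than training on 10–60 when old
and young segments obey different site-age relations). Multimodal sites
draw a 2–3 component cluster per sample, independent of age, component
means at least 0.4 apart and mixing probabilities floored at 0.15. Batch
shifts are applied on the logit scale (keeping betas in range before the
final clip); Gaussian noise is added on the beta scale and values clipped
to [0, 1] (clipping touches well under 1% of values at defaults). Optional
leukocyte fractions are Dirichlet-distributed with a blood-like
concentration and, by default, **no** effect on methylation — the null
under which adding cell-fraction covariates must not move MAD. External
validation cohorts reuse a training draw's per-site parameters with new
individuals at a single target age (default 18.5 ± 0.5 y) and no batch
shift.

Everything is driven by NumPy's PCG64 generator from one integer seed;
identical configs give bit-identical cohorts.

What passing on these cohorts does **not** show: the generator has no
Infinium I/II chemistry, no dye bias, no probe-intensity heteroscedasticity,
no correlated CpG blocks, no genotype linkage between sites, and its age
effects are exactly (or deliberately almost) the fitted link. Recovery
here demonstrates that the machinery is correct, not that a clock trained
on these draws transfers to real arrays; MAD values on synthetic cohorts
(typically ~0.2 y at defaults) are correspondingly cleaner than the
~0.7 y a real independent cohort yields.

## Problem sizes and numerics

Default desk-scale sizes keep a full CV fit under a minute and the entire
acceptance computation comfortably on one CPU: 900 x 2000 training draws,
200-sample external cohorts, 10 evaluation repeats for headline numbers and
3–5 for paired comparisons (down-sampling, cell fractions), 100-lambda
paths. Degenerate inputs fail loudly rather than silently: constant
response, singleton batches, collinear protected designs, missing betas at
training time, unknown batch labels at apply time, and age ≤ −1 y in the
transform are all errors. Prediction-time missing model sites are an error
by default; the opt-in `impute_half` policy substitutes beta = 0.5 and
reports the imputed count per sample — in forensic age assessment silent
imputation is dangerous. Ties in the 1se rule resolve to the larger
(sparser) lambda; equal-height KDE modes merge toward the first-found peak.

## Known limitations

- The QC criteria are two objective screens, not a full array-QC pipeline.
- The modality detector's thresholds trade sensitivity against false flags
  on skewed unimodal sites; heavily skewed low-n sites near a boundary are
  the hard case.
- Non-parametric EB priors, surrogate-variable methods and M-value-scale
  correction are out of scope.
- The package does not execute other published clocks; comparisons are
  site-overlap arithmetic on supplied site lists.
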