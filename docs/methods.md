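# Methods

This note records the models, numerical choices and design decisions behind
`chemspec`, and what the synthetic-data generators do and do not emulate.

## Ionization

The percent-ionized of a weak base is the logistic
`100·10^(pKa−pH)/(1+10^(pKa−pH))`, evaluated in the numerically safe form
`100/(1+e^x)` with `x = ln10·(pH−pKa)` branch-split on the sign of `x`, so
no overflow occurs for any finite inputs. The function satisfies the exact
reflection identity `f(pKa, pH) = 100 − f(pKa, 2·pKa − pH)` and is
monotone decreasing in pH; both are property-tested. Output is a
full-precision float; `format_percent` rounds to one decimal for display.

## FT-IR preprocessing

The chain is fixed as **CO₂ excision → EMSC → autoscaling**. Each step's
open choices:

* **CO₂ window.** The atmospheric CO₂ asymmetric stretch sits near
  2350 cm⁻¹; the default excision window is 2275–2400 cm⁻¹, configurable.
  Channels are deleted, not interpolated, so no artifact energy can leak
  into the multivariate models. Excising first also means the EMSC
  reference (default: mean spectrum of the analysis set) is computed on the
  retained channels only, which makes excision-then-EMSC identical to EMSC
  restricted to the retained channels (tested to 1e−10).
* **EMSC.** Each spectrum is fitted by ordinary least squares to
  `a·1 + b·m + Σ_{j=1..p} d_j λ̃^j`, with `m` the reference and λ̃ the
  wavenumber axis rescaled to [−1, 1] for conditioning. The constant
  polynomial term is `a` itself — a separate degree-0 term would be exactly
  collinear. Default polynomial order is 2 (quadratic baseline), the common
  EMSC choice. The corrected spectrum is `(x − a − Σ d_j λ̃^j)/b`. A fitted
  `|b| < 1e−8` marks the spectrum as failed and passes it through
  uncorrected with an `ok=False` flag — never a division by near-zero.
  Supplying an external reference supports train/test separation inside
  resampling loops. EMSC is idempotent (second pass gives a≈0, b≈1, d≈0)
  and exactly inverts the generator's scatter model on noise-free data when
  the reference equals the true clean spectrum; both are tested.
* **Autoscaling.** Column standardisation with the n−1 standard deviation;
  constant columns are dropped and logged rather than divided by zero. PCA
  centring after autoscaling is then a no-op by construction.

## PCA, PC-DFA and bootstrap validation

PCA is computed by SVD of the column-centred matrix. Explained-variance
fractions are taken relative to the total over all `min(n−1, p)`
components so they sum to one at full rank. All loadings carry a
deterministic sign convention (largest-magnitude element positive) so score
plots are reproducible across platforms.

PC-DFA retains `n_pcs` score dimensions (defaults: 20 for FT-IR, 25 for
GC-MS, always user-settable) and solves the symmetric-definite generalized
eigenproblem `Bv = λWv` for the between/within scatter of the PC scores.
At most `n_classes − 1` discriminant functions are kept; canonical vectors
are scaled so the pooled within-class covariance of DF scores is the
identity. A singular W falls back to a ridge `W + εI`,
`ε = 1e−8·tr(W)/n_pcs`, with a logged warning. Classification is nearest
class centroid in DF space with ties broken by class sort order — the
simplest rule consistent with reporting "% correct classification", and
prior-free (irrelevant for balanced designs anyway).

Bootstrap validation resamples the **biological replicate** within class
(technical replicates of one culture are not exchangeable with other
cultures; spectrum-level resampling is available by passing per-row
groups). Each iteration refits the entire scaling→PCA→DFA chain on the
in-bag rows and classifies the out-of-bag rows — held-out assessment, not
resubstitution. A class with every unit in-bag contributes no estimate for
that iteration; such iterations are counted, and a class usable in fewer
than half the iterations triggers a warning. Summaries are the per-class
mean percent-correct and the 2.5th/97.5th percentile interval. The
conventional iteration count is 1000; the tests and the acceptance script
run 200, which this package treats as its standard validation size — the
CI endpoints at the separable and chance extremes are already stable there.

## Consensus (multi-block) PCA

The CPCA iteration per component: block loadings `p_b = X_bᵀt/(tᵀt)`
(normalised), block scores `t_b = X_b p_b`, consensus matrix
`T = [w_1 t_1 … w_B t_B]` with block weights `w_b = 1/√K_b` (switchable
off), super weights `w = Tᵀt/(tᵀt)` (normalised), new super score `t = Tw`;
convergence when the super score changes by ≤1e−10 (relative for large
norms), at most 500 iterations, then every block is deflated by its own
score/loading pair. Non-convergence raises an error naming the component
and residual. With one block this reduces to NIPALS PCA (block scores equal
SVD scores up to sign, tested at 1e−8); identical blocks receive equal
super weights by symmetry.

Two block layouts are supported. Classic CPCA blocks partition
**variables**. The per-pH "block scores" view of this study instead groups
**samples**; the package implements that as a documented transposition —
blocks partition the rows, the matrix is analysed transposed, and the
per-sample coordinates of a block are its loadings in the transposed
problem, exposed as `sample_scores(block)`. This is an interpretation of
the sample-grouped multiblock figure style, flagged as such.

## GC-MS statistics

* **QC-RSD filter.** RSD = 100·sd/mean (n−1 sd) over pooled-QC injections;
  default threshold 30%, the usual QC-acceptance criterion in untargeted
  GC-MS, exposed as a parameter. Zero-QC-mean features are removed with an
  explicit reason. The filter is monotone in the threshold (tested).
* **Student t.** Pooled-variance two-sample t (Welch by flag) on natural-log
  abundances, technical replicates averaged per biological replicate first
  so degrees of freedom reflect biology. Zeros are treated as missing — the
  feature is skipped with a flag, never offset. Zero pooled variance is
  resolved explicitly (equal means → t=0, p=1; unequal → p=0, flagged
  degenerate). Benjamini–Hochberg adjusted p values are reported alongside
  raw p; selection uses raw p by default, adjusted by flag.
* **Mining.** A feature is "significant" iff it passes the p cut **and**
  its back-projected DFA loading (PCA loadings composed with the DFA
  canonical vectors, max |weight| over DF1/DF2) ranks in the top fraction
  (default 25%). The intersection (rather than a two-stage screen) is the
  implemented reading of "combination of loadings and significance
  testing"; an empty intersection is a logged, valid outcome.

## Growth and calibration

MIC is operationalised as the lowest tested dose whose OD at the readout
time (default: last time point, interpolable) is at or below
blank + threshold (default 0.05), requiring a growing control; "all doses
grow" returns `inf`. Raising the threshold can only lower the MIC
(tested). Calibration is unweighted OLS by default with an optional 1/x
weighting for poor low-end signal; quantification inverts the line and
flags values below the lowest standard as outside the working range.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (config, seed). The spectral model is
a sum of Gaussian absorbance bands at typical dried-biomass positions whose
heights carry three signals: a pH band-shift (small within-class variance),
a dose-response band pattern on disjoint bands whose amplitude grows
monotonically with dose and is ~3× stronger at pH 7 than pH 5
(susceptibility follows the non-ionized fraction), and biological
heterogeneity placed **multiplicatively on the dose response**. That last
choice is deliberate: it gives the dose axis the largest total variance
(so unsupervised PC1 isolates the pH 7 top-dose class) while keeping the
pH axis the best between/within ratio (so supervised DF1 splits pH) — the
same dissociation the real fingerprints show. Recorded spectra add
log-normal multiplicative and Gaussian additive scatter, a quadratic
baseline, a CO₂ band at 2350 cm⁻¹ and white noise — exactly the distortion
family the preprocessing chain removes, which makes recovery testable to
floating-point tolerances on noise-free configurations.

Peak tables are log-normal with a shipped signed effect-direction table for
19 named level-1 metabolites (trehalose up, sugars and nucleotides down at
pH 7; amino acids up; aspartate down at both pH; guanine up at pH 5),
scaled by the same monotone dose-response weights; the remaining features
are null fillers completing the 43/20/4/92 MSI composition. Biological
log-dispersion (0.20) is well above QC dispersion (0.05). Effect
magnitudes are free parameters chosen once for testability — the study
source reports directions, not sizes — and are not biological claims.

Growth curves are logistic with capacity ordering pH 7 > pH 5 > pH 9 and a
hard suppression rule at the per-pH MIC (0.2 mg L⁻¹ at pH 7). Calibration
standards are a 20-point linear gradient.

Not emulated: real band shapes and water-vapour interference, instrument
drift and retention-time shifts, peak deconvolution artifacts,
heteroscedastic intensity-dependent noise, and any absolute abundance
scale. Passing tests therefore demonstrate algorithmic correctness and the
qualitative geometry of the design, not instrument-level realism.

## Problem sizes

The default test and acceptance runs use the full 144-spectrum / 8-class
design, 159-feature peak tables with 48 samples + 8 QCs, 200 bootstrap
iterations, and 20-seed batteries for the null-uniformity and
planted-recovery checks — sizes at which every reported quantity is stable
across seeds.
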