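# Methods

This document records the models implemented in `soilcnet`, the parameter
defaults and why they were chosen, what the synthetic data generator emulates,
the numerical choices that matter for reproducibility, and the limitations of
the approach. Every number quoted here is either a fixed parameter of the code
or a quantity computed by the test suite / `scripts/acceptance.py`.

## 1. Study design emulated by the generator

The default `synth.SynthDesign` encodes the experimental layout the analyses
are built for: three treatments — `NPK` (mineral fertilizer), `GM` (+ green
manure), `GMC` (+ green manure and biochar) — with 8 replicate pots each
(24 samples), a 30-day incubation with trap openings on days
1, 3, 5, 7, 10, 15, 20, 25 and 30, and fluorescence measured on an instrument
lattice of excitation 200–450 nm in 5 nm steps by emission 250–600 nm in 1 nm
steps. These defaults *are* the study conditions; tests may shrink problem
sizes for speed but never redefine the science.

### 1.1 EEM generator

Each sample cube is a rank-3 trilinear signal
`sum_r score[i,r] * ex_load[:,r] * em_load[:,r]` plus a shared scatter
background plus i.i.d. Gaussian noise.

- **Components.** Gaussian excitation/emission profiles with default peaks
  280/401 nm ("microbial humic acid-like"), 355/443 nm and 275/468 nm
  ("terrestrial humic acid-like"), widths 25 nm (ex) and 35 nm (em). Peaks are
  validated to sit on the instrument lattice and to respect the Stokes shift
  (em > ex); off-lattice or anti-Stokes peaks raise errors rather than being
  silently snapped.
- **Scores.** Lognormal sample-to-sample variation (log-sd 0.3) times
  treatment multipliers {NPK (1, 1, 1), GM (1.1, 1.05, 0.95),
  GMC (1.35, 1, 0.7)}: amendments shift DOC toward the microbially derived
  component and away from the most humified one, which is what makes BIX rise
  under GMC.
- **Noise.** sd = 0.5% of the noiseless maximum by default (`noise_frac`);
  `noise_sd` overrides it absolutely, and `noise_sd=0` yields exact trilinear
  cubes used for machine-precision recovery tests.
- **Scatter.** Rayleigh and Raman ridges are added identically to samples and
  to the blank, so blank subtraction cancels them up to noise; the corrector
  additionally excises the ridges (below).

### 1.2 Community generator

Log-abundances are a lognormal baseline per taxon plus latent-factor modules:
taxa in module *m* share `module_weight * factor[m, sample]` on the log scale.
The default `module_weight = 3.0` against per-taxon log-noise sd 1.0 was
calibrated (before any network test was written) so that realized
within-module Spearman correlations average about 0.8 — strong enough for
module recovery, weak enough that edges are not trivially saturated. Defaults:
300 taxa, 4 planted modules of 30 taxa, counts drawn Poisson with 2%
zero-inflation (sparse but mostly prevalent, matching the strict 50%
prevalence filter).

Treatment structure enters twice: multiplicative `treatment_effect` factors on
a designated set of `effect_taxa`, and `silenced_modules` — modules whose taxa
are zeroed out in specific treatments (defaults: module 3 silenced in NPK,
module 4 in GM, nothing in GMC). Silencing removes those taxa from the
treatment's subnetwork after prevalence filtering, which is the mechanism that
orders network complexity GMC ≥ GM ≥ NPK in the synthetic study.

### 1.3 Mineralization generator

Daily emission follows `base_rate[T] * exp(-decay * (day - 1))` mg CO2-C/kg
with `decay = 0.05`/day. Base rates {NPK 162.7, GM 184.2, GMC 215.6} were
chosen by inverting the discrete cumulative sum over the default opening
schedule (the interval-sum factor is ≈ 15.93) so the true 30-day totals land
near 2592 / 2934 / 3434 mg/kg — amended treatments mineralize more carbon,
with biochar co-incorporation highest. The generator then *inverts the trap
stoichiometry*: it converts true interval emissions into blank and sample HCl
titration volumes (with optional volume noise, clipped at the blank volume),
so that `cumulative_mineralization` must round-trip the chemistry to recover
the truth. Base rates may be zero (a zero-emission jar titrates like a blank)
but not negative.

## 2. EEM correction and indices

`correct_eems` applies, in order: (1) Raman-area normalization — the blank's
emission scan at ex 350 nm integrated (trapezoid) over em 371–428 nm, the
conventional water-Raman window, putting intensities in Raman units;
(2) blank subtraction; (3) clipping of small negative residuals to zero;
(4) excision of first- and second-order Rayleigh scatter (em within ±10 nm of
ex and of 2·ex) to NaN. Correction is recorded in cube metadata and a second
application raises rather than silently double-correcting.

Indices (closed forms verified to 1e-9 by hand-built cubes):

- **BIX** = F(em 380)/F(em 430) at ex 310 nm; samples with BIX > 0.8 are
  flagged autochthonous (microbially derived).
- **HIX** = Σ F(435–480) / (Σ F(300–345) + Σ F(435–480)) at ex 254 nm, the
  Ohno (2002) bounded form (HIX ∈ [0, 1]). 254 nm is off the 5-nm lattice, so
  the ex column is linearly interpolated between 250 and 255 nm
  (weights 0.2/0.8).
- **FI** = F(em 450)/F(em 500) at ex 370 nm.

Zero denominators yield NaN with a warning instead of infinities.

## 3. Non-negative PARAFAC

`fit_parafac` is an alternating-least-squares decomposition with non-negative
loadings, written for cubes with NaN-excised scatter:

- **Missing cells** are handled EM-style: excised cells are imputed from the
  current model each sweep; the monitored loss is over observed cells only and
  is asserted non-increasing.
- **Non-negative row updates** solve each row by Cholesky on the Gram matrix
  with an active-set fallback to `scipy.optimize.nnls` when negativity
  appears.
- **Multi-start** is two-phase: all random starts run a short exploration
  (60 iterations), only the best continues to convergence. This keeps
  multi-start robustness at roughly the cost of a single full run.
- **Convergence** uses a relative loss-decrease criterion plus an absolute
  floor `loss ≤ 1e-15 · ||cube||²`: on exact trilinear data the loss decays
  geometrically toward zero and a purely relative criterion never triggers.
- **Identification.** Loadings are normalized to unit norm (magnitude carried
  in scores), components are sorted by ascending emission peak, and scores
  are reported as Fmax (score × max ex loading × max em loading), the
  conventional per-sample component maximum.
- **Validation.** Split-half analysis fits independent halves and matches
  components by Tucker congruence (TCC) under an optimal assignment
  (`scipy.optimize.linear_sum_assignment`); a split passes when matched TCC
  exceeds 0.95 in both spectral modes. Components are also matched against a
  small library of humic-like references by TCC.

Observed behavior (acceptance suite): on 24-sample cubes with 0.5% noise the
fit recovers the planted spectra with minimum TCC > 0.999 and explained
variance > 0.999; split-half passes on structured cubes and fails on
pure-noise cubes across seeds.

## 4. Community analyses

- **Bray–Curtis** distances via `scipy.spatial.distance.pdist`.
- **PCoA** is classical metric MDS: eigendecomposition of the double-centered
  squared-distance matrix, keeping positive eigenvalues. Each axis gets a
  deterministic sign (the coordinate largest in absolute value is made
  positive) so results are equivariant under sample permutation — eigenvector
  sign is otherwise arbitrary. Verified against scikit-bio.
- **PERMANOVA** uses the Gower-centered sum-of-squares pseudo-F with a
  permutation p-value `(1 + #{F_perm ≥ F_obs}) / (B + 1)` (B = 999 default).
  The pseudo-F matches scikit-bio to 1e-10 relative; the add-one p-value form
  is exact-valid (the smallest attainable p is 1/(B+1)). Calibration is
  checked empirically: null rejection rates at α = 0.05 fall in 5% ± 2% over
  hundreds of simulations.

## 5. Co-occurrence networks

- **Prevalence filter**: a taxon is kept when present in strictly more than
  the cutoff fraction of samples (default 0.5); "strictly" is tested against a
  brute recount.
- **Spearman correlations** are computed vectorized on rank-transformed data.
  P-values use the t approximation for n ≥ 10, exact permutation enumeration
  for n ≤ 7, and the t approximation with a warning in between (the exact null
  has 7! ≤ 5040 states, cheap to enumerate; the t approximation is standard
  and accurate from n ≈ 10).
- **Multiple testing**: Benjamini–Hochberg over the upper triangle
  (`statsmodels`), edges kept at adjusted p < 0.01. Under simulated
  independence the mean significant-edge fraction is ≤ 0.01 (observed 0.0 in
  the acceptance run).
- **Topology**: average clustering coefficient (ACC, the complexity proxy)
  and degrees via `networkx`, verified against brute-force triangle
  enumeration on random graphs.
- **Modules**: Louvain on |ρ|-weighted graphs with a fixed seed; labels are
  re-indexed by descending module size so output is deterministic. Planted
  modules are recovered with adjusted Rand index ≥ 0.8 across seeds.
- **Eigengenes**: first left singular vector of the standardized
  member-abundance matrix, sign-oriented to correlate positively with the
  mean member profile (matches PCA up to sign).
- **Associations**: module-eigengene × environment Pearson correlations with
  two-sided permutation p-values and significance stars (`*` p < 0.05,
  `**` p < 0.01; with B permutations the smallest attainable p is 1/(B+1), so
  `**` requires B ≥ 199). Mantel tests are one-sided permutation tests on
  distance-matrix Pearson correlation with explicit ID alignment.

## 6. Driver analysis

- **Random forest** regression is a small in-package ensemble over
  scikit-learn `DecisionTreeRegressor`s (default max_features = p/3,
  bootstrap resampling) exposing out-of-bag (OOB) predictions. Importance is
  %IncMSE: the increase in OOB MSE when one predictor is permuted. Per-predictor
  p-values follow the rfPermute scheme — refit with that predictor's column
  permuted to build an importance null — and a model-level p permutes the
  response. The forest is hand-rolled because OOB permutation importance with
  rfPermute-style p-values is the primitive under test; tree fitting itself is
  delegated to scikit-learn.
- **Variance partitioning (VPA)** for two predictor blocks uses linear-model
  R² (`lstsq`): unique fractions are R²(full) − R²(other block alone), the
  shared fraction is the remainder, and the residual completes the sum to
  exactly 1 (enforced to 1e-12). Negative shared fractions (suppression) are
  reported with a flag, not clipped. On centered orthogonalized blocks the
  shared fraction is < 0.02 by construction.
- **Within-category shares** report each predictor's standalone R² as a
  percentage of the block, plus an LMG-style averaged-over-orderings variant.
  An all-uninformative block raises; the pipeline catches this on degenerate
  (tiny) configurations and records a warning instead of failing.

Observed: with y = 2·x1 + noise among 5 predictors, the forest ranks x1 first
with permutation p < 0.05 in ≥ 18/20 seeds (20/20 in tests).

## 7. Mineralization

`CO2-C (mg/kg) = (V_blank − V_sample) · M_HCl · 12.01 / 2 / m_soil`, the back
titration of residual NaOH: each mole of trapped CO2 consumes two protons'
worth of titrant, and 12.01 g/mol carries carbon mass. The worked constant
check: 5 mL excess at 0.4 M HCl and 30 g soil gives 400.33 mg/kg. Daily rates
divide interval masses by interval length; sample volumes slightly above the
blank (small negative masses) are clipped to zero silently below a tolerance
and with a warning above it; missing schedule days raise with the jar and day
named. With the noisy generator at n = 8, recovered treatment means land
within 2% of the generating truth (≈ 0.4% in the acceptance run).

## 8. Pipeline and determinism

`run_pipeline` executes inputs → eem → parafac → community → network →
mineralization → drivers → report, either simulating data or reading provided
files, writing all artifacts as text (CSV/TSV/JSON). Determinism rests on:

- a single integer seed, from which every stage derives its own stream via
  `derive_seed(base, tag) = SHA-256(base:tag) mod (2^31 − 1)` — adding a stage
  never perturbs another stage's randomness;
- seeded Louvain, seeded permutation tests, and deterministic tie-breaking
  (size-ordered module labels, sign conventions in PCoA/eigengenes, components
  sorted by emission peak);
- a `report_hash` over the rounded stage outputs and warnings (excluding the
  config hash and output path), so two runs can be compared with one string.

Two runs from the same config are bit-identical, verified at the report level
and byte-for-byte on edge lists, driver tables and PARAFAC scores.

## 9. Numerical and build-vs-buy choices

Delegated to established libraries: distance metrics, NNLS, eigensolvers and
assignment (scipy), BH adjustment (statsmodels), graph metrics and Louvain
(networkx), decision trees (scikit-learn). Implemented in-package because the
primitive is the point: the missing-data non-negative ALS, Tucker congruence
and split-half matching, PERMANOVA, PCoA sign conventions, Spearman
edge-screening with exact small-n p-values, OOB permutation importance with
rfPermute-style p-values, VPA, and the titration stoichiometry. scikit-bio is
used only in tests, as an independent oracle.

Tolerances used in tests reflect the arithmetic: closed forms to 1e-9–1e-12,
cross-library comparisons to ~1e-10 relative, and iterative or Monte-Carlo
results by margins sized from their observed variability (e.g. calibration
rates use hundreds of simulations so the binomial sd is near 1%).

## 10. Limitations

- The generator is a statistical emulation, not a biogeochemical model: no
  real spectra, sequencing error model, compositionality (counts are
  independent Poisson given the latent factors), or soil chemistry beyond the
  trap stoichiometry.
- The driver table broadcasts treatment-level network metrics (ACC from the
  treatment subnetwork) to all replicates of the treatment, a pseudo-replicated
  design with only 3 independent network observations; the pipeline records an
  explicit warning and the RF/VPA results should be read descriptively, as in
  the underlying study design.
- Spearman networks capture monotone pairwise association only; p-values for
  8 ≤ n ≤ 9 use the t approximation with a warning.
- PARAFAC multi-start reduces but does not eliminate the risk of local minima;
  split-half validation is the guard, and the number of starts is a
  user-facing knob.
- VPA fractions are linear-model R² decompositions; shared fractions are not
  causal quantities and can be negative under suppression.
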