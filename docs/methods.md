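# Methods

This note documents the statistical model, the synthetic-data design, the
numerical choices, and the limitations of `nmrmwas`.

## The association model

For each spectral feature *xⱼ* (intensity at one ppm grid point) and a
continuous outcome *y* (ln(CAC+1) or log₁₀ IMT), the scan fits

  y = β·zⱼ + γᵀc + ε,  zⱼ = (xⱼ − x̄ⱼ)/sd(xⱼ),

by ordinary least squares, where *c* is the covariate vector of the chosen
model (Model 1: age, sex, ethnicity, measurement phase, plus cohort when
cohorts are pooled; Model 2 adds LDL, HDL, systolic blood pressure,
smoking status, diabetes, and lipid/blood-pressure treatment). β is the
standardized coefficient per SD of the feature; the two-sided *p* comes
from the *t* statistic of β. The partial Spearman correlation is the
Pearson correlation of the average-tie ranks of the residuals of *y* and
*zⱼ* after projecting both off the covariate design.

The scan is computed through the Frisch–Waugh–Lovell identity: the
covariate design is orthonormalised once (SVD basis, rank-revealing with a
relative 1e-10 cutoff so collinear columns are harmless), outcome and all
features are residualised against it, and β, se, *t* and *p* follow from
the residual cross-products. This is algebraically identical to per-feature
OLS (a unit test checks agreement with `statsmodels` to 1e-8) and makes
the permutation stage a sequence of matrix products. Complete-case
analysis is used throughout; constant features yield flagged skip records.

## Metabolome-wide significance (MWSL) and ENT

Spectral features are strongly dependent (multiplet structure, overlapping
resonances), so Bonferroni over the raw feature count is far too strict.
The per-variable threshold α′ is estimated by permutation: the outcome
vector is randomly re-allocated across participants (covariates stay
attached to their samples, so the permutation also breaks
outcome–covariate association — the procedure mimics the global null),
the scan is re-run, and the minimum *p* over features recorded. With
n_perm permutations and family-wise error target α, α′ is the *k*-th
smallest minimum with k = ⌈α·n_perm⌉ — the 500th of 10 000 at α = 0.05 —
and ENT = α/α′ is the equivalent number of independent tests. Since the
minimum *p* is a monotone transform of the maximum |correlation| between
the residualised permuted outcome and the residualised features, each
permutation costs one matrix–vector product; permutations are processed in
blocks of 256. Closed-form checks: one feature gives α′ ≈ α; M
independent features give α′ ≈ 1 − (1−α)^(1/M), ENT ≈ M; total
duplication gives ENT ≈ 1.

Degenerate permutations (including re-drawing the identity) are not
excluded; at the sample sizes involved their probability is negligible.

## Two-stage design

Discovery hits (*p* < α′ in the discovery cohort) are tested in the
replication cohorts with the same adjustment plus cohort; a hit replicates
when *p* < 0.05 (two-sided) with the same sign. Within each SRV cluster
the sentinel is the member with the smallest discovery *p*; exact ties
break to the smaller feature index.

## SRV clustering

Adjacent-feature Pearson correlations are computed across samples; maximal
runs in which **every adjacent pair** reaches r ≥ 0.9 and which span ≥ 10
features become clusters (the chain rule is this package's
operationalisation of the recoupling criterion; the original landscape
construction is not reproduced here and the choice is exposed for
sensitivity analysis via `SRVParams`). Sub-minimum runs stay as unassigned
features and are exported for review — an automated stand-in for the
manual curation pass such studies apply. Neighbouring clusters whose
mean-intensity profiles correlate at the threshold share a supercluster,
aggregated greedily left-to-right with a hard cap of three members; the
greedy split is a convention, since no tie-break rule is standard.
Lowering the threshold can only extend runs, so the clustered-feature
count is monotone in it.

## Downstream stages

- **Cox stage**: partial likelihood (Efron ties) via `lifelines`, hazard
  ratio per SD of metabolite, adjusted for the Model-2 confounders;
  proportional hazards tested by correlating scaled Schoenfeld residuals
  with the rank of event time.
- **Bootstrap stepwise selection**: forward–backward search by an AIC
  criterion (Gaussian likelihood, penalty 2 per parameter) over candidate
  metabolites with the confounders forced in, repeated over bootstrap
  resamples of individuals (default 1000); reported as selection counts and
  sign-change counts. The sign reference is the full-sample stepwise fit,
  falling back to the all-candidate forced model for variables it never
  selects. Rank-deficient resamples are redrawn and counted.
- **PCA rule**: the smallest k components of the column-standardized
  matrix explaining ≥ 95% of variance sets a Bonferroni level α/k (0.005
  for k = 10).
- **Correlation matrix**: covariate-adjusted Spearman correlations,
  reordered by average-linkage hierarchical clustering on 1 − |r|, with
  Bonferroni flags over all distinct pairs.
- **STOCSY**: Pearson correlation and covariance of a driver feature
  (specified in ppm, snapped to the nearest grid point) with the whole
  spectrum; resonances sharing a concentration light up near r = 1.
- **Metabonetwork**: compounds are nodes, reaction pairs undirected,
  unweighted edges; the subnetwork is the union over all hit pairs of all
  nodes and edges on any shortest path (a node v is on a shortest a–b path
  iff d(a,v)+d(v,b)=d(a,b)). Using *all* shortest paths rather than one
  arbitrary path makes the result independent of traversal order.
  Unreachable pairs and unmapped hits are reported, not errors.

## Spectral processing

Processing follows the standard serum 1D chain: exponential apodization
exp(−π·lb·t) with lb = 0.3 Hz, zero filling by a factor of two (65 536
time-domain points → 131 072 frequency-domain points), FFT with the first
point halved (the DC correction for one-sided sequences), zero-order
automatic phasing, baseline correction, and calibration of the ppm axis so
the tallest local maximum within ±0.05 ppm of 5.233 ppm (the anomeric
glucose signal) lands exactly on 5.233.

Numerical choices:

- **Phasing** is zero-order only (first-order phase is out of scope; the
  synthetic FIDs have none). The initial phase estimate is the argument of
  the spectral integral — exact for all-positive absorption patterns — and
  a bounded (±20°) minimisation of the squared negative area refines it; a
  small positive-area reward in the objective removes the degeneracy of
  inputs with no dispersion component, where shrinking the whole real part
  would also shrink the negative area.
- **Baseline**: asymmetric least squares (second-difference smoothness
  penalty 10⁶, asymmetry 0.001, 10 reweighting iterations). The algorithm
  is configurable since no specific method is canonical.
- **Calibration failure** (no local maximum in the search window) flags
  the sample; strict mode raises, pipeline mode passes the spectrum
  through uncalibrated with the flag set.
- **Regridding** onto the common ppm axis is linear; splines were rejected
  to avoid ringing at sharp lines. The ppm axis is ascending internally;
  TSV writers emit descending (NMR display convention, stated in the file
  header).

## Synthetic cohorts

The generator emulates a three-cohort atherosclerosis study design:

- **Spectra**: each metabolite template contributes Lorentzian multiplets
  (line FWHM = 1/(π·T2) Hz) scaled by a per-sample log-normal
  concentration, so all features of one metabolite share a latent variable
  and form the near-perfectly correlated runs SRV expects. A broad
  baseline of five short-T2 components stands in for lipoprotein bands and
  the protein background; the CPMG variant multiplies exactly this
  component by `cpmg_attenuation`, leaving metabolite signals and noise
  unchanged (same substream draws). The default grid is 0.5–9.5 ppm at
  32 768 points — a desk-scale stand-in for full-resolution profiles of
  ~30k features; tests and examples use 1 024–8 192 points with
  correspondingly broader template lines so multiplets still span ≥10 grid
  points.
- **Phenotypes**: CAC is two-part — a Bernoulli zero state (per-cohort
  zero probability, matching the practice of reporting CAC>0 percentages
  separately) and, for positives, ln(CAC+1) normal with mean shifted by
  the planted per-SD effects of the metabolite scores plus age and sex
  terms. IMT is log-normal with effects on the log₁₀ scale. Event times
  are exponential with log-hazard linear in metabolite scores and age,
  censored uniformly over an 8–12-year follow-up window — the simplest
  generator matching a Cox analysis.
- **Effect sizes**: the default template library plants standardized CAC
  coefficients of 0.12–0.28 per SD with the direct/inverse pattern typical
  of serum screens (sugars and several amino acids direct; glutamine,
  citrate, ketone bodies inverse), spanning the range of standardized
  coefficients reported for replicated serum metabolites at cohort scale;
  at n ≈ 3 900 these give discovery *t* statistics of roughly 4–8.
  Concentration log-SD is 0.3 throughout. Because effects are planted on
  the transformed outcome for CAC-positive individuals, zero inflation
  attenuates the marginal slope; parameter-recovery checks therefore use
  `cac_zero_probability = 0`.
- **Randomness**: a single master seed feeds named substreams
  (concentrations, baseline, noise, phenotypes, events), so stages can be
  regenerated independently and the standard-1D/CPMG pair of one cohort is
  coherent. Identical spec + seed reproduce outputs bit-identically.

What the generator does **not** emulate: chemical-shift drift between
samples (positional noise), first-order phase errors, water/solvent
artefacts, peak-overlap crowding at real density, lipoprotein subclass
structure, and outcome-dependent missingness. Passing tests therefore
demonstrate correctness of the statistical machinery under a clean,
known-truth regime, not robustness to every artefact of real serum
spectra.

## Problem sizes

The test suite and the acceptance script run the same algorithms at
reduced scale, chosen as the package's own desk-scale defaults: grids of
256–8 192 points, cohorts of 150–7 436 individuals, 2 000–10 000
permutations, 600–800 null replicates for the family-wise-error
calibration, and ≥100 seeds for the coverage checks of the linear and Cox
stages. The MWSL machinery is O(n_perm · n · M) via matrix products and
handles the full 30k-feature, 10k-permutation setting in minutes.

## Known limitations

- Only zero-order phasing; strongly first-order-twisted real spectra need
  external pre-phasing.
- The SRV chain rule can split a true multiplet at a low-correlation
  saddle if noise is high; the unassigned-feature export is the review
  channel for this.
- The stepwise procedure uses a fixed AIC-like penalty; no small-sample
  correction.
- The permutation scheme tests the global null of no outcome–feature and
  no outcome–covariate association, as stated; it is not a conditional
  permutation.
- KEGG reaction-pair lists must be supplied by the user (no network
  client); "main pair" filtering is upstream of this package.
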