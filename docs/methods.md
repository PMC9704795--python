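# Methods

This note documents the models, conventions and design decisions behind
`connage`, in the order data flows through the pipeline.

## Functional connectivity

FC between two nodes is the Pearson correlation of their mean time series
(≥32 time points; the default emulated acquisition is 300 volumes with the
first 4 discarded, i.e. 296 retained). Edges are screened for significance
against **phase-randomized surrogates**: each node series is Fourier
transformed, the phases of all positive-frequency bins are replaced by
independent uniform draws (DC and, for even length, Nyquist bins untouched so
the inverse transform is real and the mean preserved), and the transform
inverted. This preserves each series' amplitude spectrum — hence its variance
and autocorrelation — while destroying cross-series dependence, which is the
correct null for correlations between autocorrelated signals (an i.i.d.
shuffle is anti-conservative there). Choices the procedure's verbal
description leaves open, fixed here:

- **both** series of an edge are surrogated, for exchangeability;
- the per-edge null is that edge's own surrogate correlation distribution;
- the p-value is **two-sided on |r|** (both signs are analyzed downstream),
  with the +1 permutation correction, p = (1 + #{|r*| ≥ |r|}) / (S + 1), so
  p is never 0; ties count against significance;
- α applies per edge, uncorrected, as the procedure states (p ≥ α ⇒ edge set
  to 0). Default S = 1000 surrogates.

Retained correlations are Fisher-transformed (z = atanh r, with |r| clipped to
1 − 1e−7 to guard degenerate finite-sample r = ±1; zeros map to zeros, so
masking and transforming commute) and split into FC_pos = max(z, 0) and
FC_neg = max(−z, 0), analyzed separately because summing signed weights into
strengths would let positive and negative coupling cancel.

## Structural connectivity

SC weights are consumed, not computed (tractography is upstream). The only
transform is log10 compression; since a bare log10 is undefined at absent
edges (w = 0) and negative for w < 1, the implementation uses
**log10(1 + w)** (offset configurable), which maps absence to exactly 0 and
preserves order. A transformed matrix carries a flag and a second application
is refused. Edge lists use the upper triangle only (N(N−1)/2 edges; the
diagonal is excluded throughout).

## Strength features

Per node and per matrix kind, an intra-network and an inter-network strength:
the sum of the node's edge weights to nodes inside (outside) its network,
divided by a possible-edge count. The intra denominator is the network-level
n(n−1)/2, kept exactly as the source procedure words it even though it pairs
a per-node sum with a network-level count — fidelity over elegance. The
inter denominator is ambiguous in the source ("the number of the respective
edges"); the default is the per-node count N − n, symmetric with the per-node
sum, and the network-total reading n(N − n) is available via
`inter_denominator="network-total"`. Strengths are linear in edge weights.
The predictor block orders columns node-major — (SC, FC_pos, FC_neg) ×
(intra, inter) per node — with COG appended last; per-column tags carry
(kind, scope, node, network, lobe).

## Cognition composite

Fixed order: screen → impute → outlier-exclude → KMO → PCA.

- Subjects with ≥3 missing of the 16 tests are excluded; 1–2 missing entries
  are replaced by the median of the subject's sex × age-decade stratum. The
  decade labels are 55–64, 65–74, 75–84, 85+ (the source prints "75–80, and
  >85", which neither covers 80–85 nor makes contiguous decades; it is
  resolved to 75–84 / ≥85 rather than silently assumed correct).
- Outliers: any score outside its test's mean ± 3 SD (computed on the
  screened sample) excludes the subject; a zero-variance test excludes nobody.
- KMO: overall Kaiser–Meyer–Olkin index, Σr²ᵢⱼ / (Σr²ᵢⱼ + Σq²ᵢⱼ) over i ≠ j,
  with anti-image partial correlations q from the inverse correlation matrix
  (condition number > 1e12 ⇒ error).
- PCA runs on the correlation matrix (tests standardized — their native units
  are incommensurate; the source does not state this and it is the natural
  choice). COG is the first-PC score, standardized to mean 0 / SD 1 over the
  retained subjects, with the sign set so the majority of test loadings are
  positive (higher COG = better performance).

## PLS regression and model selection

Predictors (never the response) are residualized on intercept + sex +
education by least squares. PLS1 is fit by NIPALS: per component,
w ∝ Xᵀy (iterated to Δw ≤ 1e−12, max 500 iterations — for a univariate
response the fixed point is reached immediately, but the check runs), scores
t = Xw, loadings p = Xᵀt/tᵀt, q = yᵀt/tᵀt, then X and y are deflated.
Scores are mutually orthogonal (asserted at 1e−8); predictions at any
cumulative depth are reproducible from the stored factors, and jointly
flipping a component's (w, p, q, t) leaves predictions invariant. Columns are
centered but **not unit-scaled** by default: after residualization the
strength features are commensurate, and the COG column is already
standardized (`scale=True` is available; the source is silent on scaling).

Depth selection: leave-one-out cross-validation gives RMSEP(k) for
k = 0..K (k = 0 is the mean-only model; K defaults to 10), each held-out
subject predicted by a model refit without it. A **van der Voet–style
sign-randomization test** on the paired per-subject squared errors then picks
the smallest k whose errors are not significantly worse (one-sided p ≥ α,
α = .01, 1999 randomizations) than the global-minimum-RMSEP depth. This is
the randomization interpretation of "permutation test on RMSEP" implemented
by the standard PLS cross-validation framework the source cites.

Validation follows the study design: **scrambled null models** permute the
rows of every predictor column independently and permute the response,
preserving all marginals while destroying X–y and inter-column dependence
(whether the source permuted columns jointly or independently is unstated;
independent permutation is the stronger scrambling and is the default), each
null cross-validated at the same fixed depth as the real model; and
**repeated random splits** (default 1000 × 80/20, fractions 90/10, 70/30,
60/40 supported; train size = ⌊n·fraction⌋, giving 458/115 at n = 573) fit on
the train part and evaluate held-out RMSEP and r(predicted, actual age) at
every cumulative depth. Per-split child seeds derive deterministically from
one master seed and are recorded. Variance accounting reports, per cumulative
depth, the % of centered predictor sum-of-squares captured by the
score/loading reconstruction (Σₐ‖tₐ‖²‖pₐ‖² over ‖X_c‖²_F) and the training R²
of age on the scores, both as percentages.

## Aging profiles

PLS component signs are arbitrary and component order can swap across
resamples, so before averaging, every split's components are matched to the
full-sample reference model (greedy one-to-one on |corr| of loading vectors;
ties within 1e−6 fall back to index order with a warning) and sign-flipped
jointly to agree with it. The **orientation convention** is a single global
rule: reference components are flipped so each score–age correlation is ≤ 0
(equivalently y-loading q ≤ 0). A positive reported loading therefore always
means the predictor is *lower at higher age*, and the cognition loading is
positive when performance declines with age. (The source's text describes
negative score–age correlations while printing positive r magnitudes; this
convention reproduces the signs of its loading figures and treats the printed
r values as magnitudes.)

Profile summaries: per-predictor mean and SD of loadings across splits; the
COG loading reported separately; unweighted network-wise means per predictor
family; a two-sided two-sample t-test (pooled variance; Welch optional) of
node-level mean loadings, frontal vs rest, for a chosen family (default
intra-network SC); and Pearson correlations of component scores with age.

## Synthetic cohorts

The generator supplies the statistical structure the analysis assumes, at two
levels.

**Raw level** (time series, SC, battery): ages uniform on [55, 85] — chosen
over the reference cohort's empirical age histogram to maximize
identifiability at small n — balanced sexes, education grades 3–10
(mean ≈ 6.5, SD ≈ 1.9). Node signals are a latent-factor model: network
latent + global latent (both AR(1), φ = 0.5, giving BOLD-like smoothness) +
white noise, with the network-latent weight falling (0.005/yr from 0.8) and
the global-latent weight rising (0.006/yr from 0.3) with age — so
within-network correlation exceeds between-network correlation while the gap
narrows in older subjects. No hemodynamics, motion or scanner noise is
modelled. SC weights are continuous log-normal "SIFT-2-like" weights (not
streamline counts — tractography is out of scope), denser and heavier within
networks, with an exponential per-year decline that is 2.5× faster
(ratio 0.4) on frontal-incident edges (0.02/yr vs 0.008/yr): the
frontal-first decline narrative encoded as one plausible instantiation, not
as fact. The 16-test battery shares one latent factor with population
correlation −0.44 to age and +0.35 to education, plus per-test unique noise
(SD 0.6 on the loading scale) and fixed test-native offsets/scales;
missingness, when requested, is completely at random (the source does not
state its mechanism).

**Feature level** (planted components): X = Σₖ cₖ sₖ vₖᵀ + E with orthonormal
stored loading vectors vₖ over the 6N+1 predictors, scores
sₖ = z(age) + 0.5·noise, X-scales c = (3, 1) and feature noise SD 0.05
(≈ the per-feature signal scale at p = 601). The unequal X-scales are
essential: two planted directions that carry the age signal identically *and*
have identical X-variance collapse into a single optimal predictive
direction, making the planted dimensionality unidentifiable in principle.
With unequal scales the first PLS component overweights the high-variance
direction and a second component is genuinely required, so component-count
recovery is a meaningful test. Default planted patterns mimic the three
qualitative profiles the analysis is designed to find (global SC decline with
frontal emphasis + within-network FC_pos decline; frontal-only SC decline with
globally rising FC and the strongest cognition loading; preserved SC with
globally low FC), Gram-Schmidt orthonormalized.

What passing tests show — and don't: recovery on these cohorts demonstrates
the statistical machinery (thresholding, selection, alignment, null
separation) is correct and well-calibrated under the planted model; it does
not certify performance on real data, whose noise structure, parcellation
mismatch and physiological confounds the generator deliberately omits.

## Numerical choices and degenerate inputs

- Fisher clip 1e−7 before atanh (disable with `clip=None`, then |r| = 1
  raises). Pearson matrices are symmetrized exactly ((r + rᵀ)/2) and clipped
  to [−1, 1].
- NIPALS raises, naming the component, when the remaining X–y covariance is
  numerically zero (rank exhausted); LOO folds that lose rank carry the
  deepest available prediction forward, and a fully degenerate fold predicts
  the training mean.
- Zero-variance node series, negative SC weights, asymmetric matrices
  (> 1e−9), singleton networks, rank-deficient covariate designs, empty
  imputation strata and kind-tag mismatches on load all raise informative
  errors rather than propagating.
- A zero-variance test excludes nobody in outlier screening (SD = 0 edge
  case).

## Problem sizes

Default analysis scale in this repository: 80-subject, 100-node cohorts with
296 time points, 199 surrogates, 100–200 splits and 100–200 nulls; recovery
experiments use 50 cohorts of n = 300 at 100 nodes (601 predictors) with LOO
over up to 10 components. These sizes were chosen so the planted effects are
comfortably identifiable while the full suite runs on a laptop-class machine;
all counts scale up by configuration (e.g. 400 nodes, 1000 surrogates, 1000
splits/nulls) without code changes.

## Known limitations

- PLS1 only (univariate response); no PLS2, sparse, or kernel variants.
- The surrogate test assumes stationary signals; strong nonstationarity would
  make the amplitude-spectrum null inexact.
- The generator's FC and SC are conditionally independent given age; real
  coupling between structure and function is richer.
- No cortical-surface rendering; outputs are tables keyed by node/network
  tags.
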