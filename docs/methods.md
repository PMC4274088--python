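# Methods

This note documents the models, defaults and numerical choices behind
`fcdiscrim`, and what the synthetic validation does and does not show.

## Generative model of a cohort

Each subject contributes a T × N matrix of ROI signals drawn as i.i.d.
rows from a multivariate normal with a group-specific correlation matrix
(sampled through its Cholesky factor). The correlation matrix is modular:
`r_within` inside each of `n_modules` contiguous ROI blocks, `r_between`
across blocks, unit diagonal. In the patient groups (TPD, NTPD), every
within-module entry incident to a node in `affected_nodes` is reduced by
`effect_delta`. Because block constructions with decrements can be
indefinite, the matrix is projected to the nearest positive-definite
matrix by eigenvalue clipping (floor 1e-6) and rescaled to unit diagonal.

Confounds: six AR(1) head-motion series plus AR(1) white-matter and CSF
signals (coefficient 0.9, unit innovations). A standardised mixture of all
eight, scaled by `nuisance_loading`, is added to every ROI — a shared
global contaminant of the kind nuisance regression exists to remove.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| `n_per_group` | 20 NC / 15 TPD / 10 NTPD | the emulated study's group sizes |
| `n_volumes`, `tr` | 180, 2 s | the emulated acquisition (first 5 volumes dropped downstream) |
| `n_rois` | 128 | desk scale; set 1024 to mirror the full-resolution template |
| `n_modules` | 8 | the canonical count of large-scale resting-state systems |
| `r_within` | 0.6 | see calibration below |
| `r_between` | 0.1 | weak cross-system coupling |
| `effect_delta` | 0.25 | planted patient effect on `affected_nodes` (default nodes 0–9) |
| `cerebellum_nodes` | 96–127 | the designated "cerebellar" block excluded in the second template arm |
| `nuisance_loading` | 0.5 | ~20 % of signal variance as shared confound, a realistic contamination level |
| ages / genders | uniform 40–80 y, Bernoulli(0.55 male) | loose match to a late-adult clinical cohort |

**Calibration of `r_within`.** The 0.01–0.1 Hz ideal band-pass at TR = 2 s,
T = 175 retains 32 rFFT bins, i.e. ≈ 64 effective degrees of freedom, so
post-filter correlation estimates have Fisher-z SE ≈ 0.12 (verified by
simulation). The Bonferroni edge-survival boundary at N = 128 is
r* ≈ 0.334. For control networks to express the modular topology rather
than a coin-flip version of it, within-module correlations must clear that
boundary by ≳ 2.3 SE: z(r_within) ≥ z(0.334) + 2.33·0.12, i.e.
r_within ≥ 0.56. The default 0.6 is a typical strong within-system
resting-state correlation satisfying this; the planted patient value
0.6 − 0.25 = 0.35 then falls at the boundary and loses roughly half its
edges, which is what makes affected nodes detectable.

### What the generator does not emulate

No spatial structure (no 4-D volumes, slice timing, realignment or
smoothing), no temporal autocorrelation of the neural signal itself (rows
are i.i.d.; the band-pass induces autocorrelation downstream), no
heavy-tailed motion artefacts or spike volumes, no age/gender effects on
connectivity (covariate regression is validated as a no-harm step, not as
a confound remover), and no attempt to match real effect sizes. Passing
tests therefore demonstrate the *inferential machinery* — selection
recovers planted nodes, classification is calibrated at chance on null
cohorts — not performance on real fMRI.

## Temporal preprocessing

Order: drop initial volumes → linear detrend → ideal DFT band-pass
(0.01–0.1 Hz) → nuisance regression (24-parameter motion expansion
{p, p_lag, p², p_lag²} + WM + CSF + intercept). Global-signal regression is
deliberately not performed. Choices:

- **Ideal filter** (zero the out-of-band DFT coefficients): exactly
  characterisable in tests; a Butterworth alternative was considered and
  rejected as the default for that reason. Edge effects are accepted —
  T = 175 with the band well inside Nyquist.
- **Matched-band regression.** The assembled nuisance design is detrended
  and band-passed exactly like the data before the regression. Regressing
  band-limited data on broadband confounds leaves residual in-band
  contamination (the frequency-mismatch problem); with matched filtering,
  confounds that are linear mixtures of the regressors are removed
  exactly.
- **Detrend before band-pass.** A linear trend is broadband; removing it
  first keeps its energy out of the pass band. Each stage is an orthogonal
  projection and individually idempotent to machine precision, but the
  stages do not commute, so the composed chain re-applied is *not* a
  no-op (detrending band-limited data removes a non-trivial line, ~4 %
  relative): pipelines should apply the chain once.

## Network construction

m = N(N−1)/2 Bonferroni tests (each unordered pair once — the two
triangles are not independent tests); exact t-distribution p-values rather
than the normal approximation (T is finite); positive correlations only;
weights are Fisher z of the surviving r. Since z is monotone, applying the
transform after thresholding changes no edge decisions, only reported
weights. Isolated nodes are retained so that N, and hence every efficiency
denominator and feature index, is constant across subjects.

## Graph metrics

Edge length = 1/weight (the standard convention in weighted-efficiency
analyses); shortest paths by Dijkstra; unreachable pairs contribute zero
inverse distance. Local efficiency of node i is the global efficiency of
the subgraph induced by its neighbours with the original weights, i
excluded; subgraphs with < 2 nodes score 0. The clustering coefficient
and characteristic path length are computed on the binarised topology
because their formulas count nodes and edges; L_p averages hop distance
over reachable ordered pairs only, and the unreachable fraction is logged.

The null model rewires the binary topology by double edge swaps
(10 × edge count attempts), preserving every degree exactly, then permutes
the original weight multiset onto the rewired edges — matching the two
first-order confounds (degree sequence and weight distribution) at once.
Normalisation: Gamma = E_loc/⟨E_loc⟩_null, Lambda = E_glob/⟨E_glob⟩_null,
Sigma = Gamma/Lambda, with 100 nulls by default.

## Feature selection and classification

Residualisation fits one least-squares model (intercept, age, gender) on
the combined sample of the contrasted groups; constant covariates are
dropped with a warning. The permutation test uses the pooled-variance
two-sample t, Monte-Carlo reassignment (the assignment space is far too
large to enumerate), and add-one two-tailed p-values, minimum 1/(P+1).
Null draws operate on a content-sorted copy of the pooled sample and
always select subsets of the smaller group's size, which makes p-values
exactly invariant to subject ordering and to exchanging the group labels.

MLDA: pooled within-class covariance, eigendecomposition, every
eigenvalue below the mean raised to the mean, discriminant
w = (S*)⁻¹(μ₁−μ₂), midpoint threshold (equal priors), ties assigned to
the patient class (deterministic, favours sensitivity; `tie_label` flips
it). When all eigenvalues are equal the regularisation is a no-op and
MLDA coincides with classical LDA — used as an independent cross-check
against scikit-learn in the tests.

LOOCV sorts subjects into a canonical order and derives each fold's
permutation seed from the held-out subject's identifier, so results are
independent of input ordering. `nested` mode refits residualisation and
selection inside every fold (per-fold permutation count defaults to 1,000
at desk scale, overridable to 10,000); `paper_faithful` selects once on
the full sample first, reproducing a selection-before-validation protocol
— on effect-free cohorts it inflates accuracy by ≈ 0.2 over the nested
mode's ≈ 0.5, which is exactly the leakage it exists to demonstrate. If a
fold selects no feature, the single smallest-p feature is used.

## Pipeline

The orchestrated experiment runs both template arms (the
`without_cerebellum` arm drops the masked nodes before correlation, which
is exactly equivalent to deleting their rows/columns from the full
correlation matrix and re-thresholding with the reduced pair count),
all four contrasts (PD-vs-NC pooled, TPD-vs-NC, NTPD-vs-NC, TPD-vs-NTPD)
and one classification cell per metric (local / nodal efficiency),
mirroring a sensitivity × specificity × accuracy results table. All stage
seeds derive from one master seed; a rerun reproduces the report byte for
byte.

## Problem sizes used in validation

Unit tests run on cohorts of ~15 subjects with 16–32 ROIs; acceptance
checks use the full stated design (45 subjects × 128 ROIs), 100
random graphs of ≤ 8 nodes against brute-force path enumeration, 20
effect-free cohorts for calibration/chance/leakage checks, and 20-null
small-world references at N = 100.

## Known limitations

- Desk-scale discrimination accuracy saturates around 0.85–0.95 across
  cohort draws. The band-pass leaves ~64 effective temporal dof and the
  26-column matched-band regression removes ~27 more, so correlation
  estimates carry SE(z) ≈ 0.16; with a 0.25 correlation decrement the two
  operating points (intact vs affected edges) are only ~0.3 z-units
  apart, bounding per-node effect sizes near d ≈ 1. An oracle classifier
  given the true affected features does no better on weak cohort draws.
- The permutation test's Monte-Carlo null has resolution 1/(P+1); per-fold
  selection at P = 1,000 is correspondingly coarse.
- `paper_faithful` mode is intentionally biased and should never be used
  for reporting performance.
- Parcellation region-growing requires each input region to be
  6-connected; disconnected regions raise rather than silently merging.
- With `positive_only=False`, negative surviving correlations enter as
  absolute Fisher-z weights, since the path-length convention requires
  nonnegative weights; signed-network analysis is out of scope.
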