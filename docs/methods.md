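# Methods

## Model

The observable is the mean number of 53BP1 foci per nucleus at time t
(hours) after targeted irradiation with radiation quality Q. The model
decomposes it additively — radiation-induced and non-radiation foci are
assumed statistically independent:

    m_Q(t) = m_s(t) + Σ_n k̄_Q(n) · P_Q(t | n)
    m_s(t) = n̄_b + n̄_s · exp(−β0 (t − t_M))

* `n̄_b` — mean background foci per nucleus (constant in time);
* `n̄_s` — mean foci induced by the nucleus-recognition step (Hoechst
  staining + 399 nm illumination) at the reference time, repaired at rate
  β0 and assumed always repairable;
* `k̄_Q(n)` — mean number per nucleus of clusters of n tracks whose foci
  are not separable optically; a fixed input from the geometry simulation;
* `P_Q(t|n)` — probability that the site of an n-track cluster still shows
  at least one focus.

Foci along one track are Poisson with mean `n̄_Q` at the reference time
t_M = 0.5 h (the post-irradiation maximum of focus counts; the model is not
defined before t_M and evaluation there is a domain error, not an
extrapolation). Each focus is independently persistent with probability
`p_Q`; a normal focus survives to t with probability e^(−β1 Δ), a
persistent one with e^(−β2 Δ), Δ = t − t_M. Poisson thinning gives

    P_Q(t|n) = 1 − exp(−n n̄_Q [(1−p_Q) e^(−β1 Δ) + p_Q e^(−β2 Δ)])   (fraction form)
             = 1 − exp(−n [(n̄_Q − p̄_Q) e^(−β1 Δ) + p̄_Q e^(−β2 Δ)])  (mean-number form)

with `p̄_Q = n̄_Q p_Q`. The two forms are algebraically identical but are
kept as distinct fitting parameterizations because the optimisation
geometry (and hence, on rough χ² landscapes, the found optimum) differs.
Saturation of the repair machinery is assumed absent (the five-track doses
are well below 1 Gy), and repair rates are shared across radiation
qualities by default.

### Label symmetry

The two-class survival mixture is exactly invariant under swapping
(β1, p_Q) ↔ (β2, 1 − p_Q) simultaneously for all qualities, so every
optimum of the default fit has an equal-χ² mirror image. Reported optima
are therefore canonicalised to the convention that the *persistent* class
is the slower one (β2 ≤ β1) whenever the swap is an exact symmetry of the
fitted variant (β0 free, shared β1, β2 free, mirror inside the bounds).
In variants where the symmetry is broken (β0 = β1 ties the sham rate to one
class; per-quality β1; β2 fixed), no relabelling is done and a β2 > β1
optimum is reported with a warning. β1 ≥ β2 is deliberately not imposed as
a hard constraint.

## Geometry simulation

Each nucleus is aimed at with five ions (corners + centre of a 4 µm square,
orientation fixed in the lab frame, centroid at the nucleus centre). Per
aim point the counter delivers 0/1/2 ions with probabilities p0/p1/p2
(defaults 0.05/0.90/0.05 — the miscounting phenomenon is documented for
this beamline, its probabilities are not, so they are configuration
values); each delivered ion lands at the aim point plus isotropic Gaussian
scatter with σ = FWHM/(2√(2 ln 2)), FWHM 4 µm. Nuclei are ellipses; the
half-axes (a, b) are bivariate normal specified in principal-component
form (defaults: means 8 and 5 µm, PC standard deviations 2 and 1 µm, PC
rotation 0), rejected until a ≥ b > 0.5 µm, with orientation uniform on
[0, π). Everything is 2-D: the ~2.4 µm nucleus thickness matters for LET
metadata, not for which tracks cross the outline.

Tracks inside the ellipse are grouped by single linkage: two tracks connect
when their planar distance is ≤ the proximity radius (default 2.0 µm, the
order of a focus diameter at the imaging resolution used for counting);
clusters are connected components. `k̄_Q(n)` is the tally of n-track
clusters divided by the number of simulated nuclei. Two invariants are
checked continuously: cluster sizes partition the in-nucleus track count
(Σ n·k̄(n) equals an independently kept track tally exactly), and without
miscounting and with an all-covering nucleus the mean track count is
exactly 5.

All geometric defaults (pattern side, FWHM, delivery probabilities,
half-axis distribution, proximity radius) are exposed in the configuration
rather than hard-coded, because they are facility- and image-analysis-
specific calibrations.

## Regression

The minimised quantity is χ² = Σ_j ((obs_j − model_j)/sd_j)² over all
datasets at once: each irradiated series uses the full model, the sham
series the sham term alone, with identical weighting. `sd` is the
between-dish standard deviation of the replicate-dish means; a non-positive
or missing sd is a hard error (the caller must apply a weight floor or
exclude the point). The optimiser is SciPy's trust-region-reflective
bounded least squares (ftol = xtol = gtol = 1e-12, numerical Jacobian) run
from multiple starts: the extremes of all-parameters-zero and
all-parameters-at-maximum plus Latin-hypercube draws (default 16) inside
the bounds; the lowest χ² wins, first-found on ties. Bounds are
non-negativity everywhere, p_Q ≤ 1, and generous caps (n̄_Q ≤ 5, rates
≤ 10 h⁻¹, n̄_b, n̄_s ≤ 5, p̄_Q ≤ 5) that exist to make the start sampling
and trust region finite, all configurable.

With four qualities and five time points plus the five-point sham series,
the default fit has 25 points and 13 free parameters (n̄_b, n̄_s, β0, β1,
β2 and per quality n̄_Q, p_Q), f = 12. Independent fits model the
irradiated-minus-sham difference series (sd propagated root-sum-square; the
induced correlation with the sham series is knowingly not modelled) with
the radiation term alone: 5 points, 4 free parameters, f = 1, or f = 2 with
β2 ≡ 0.

Standard errors come from the linearised problem at the optimum,
SE_i = √([(JᵀWJ)⁻¹]_ii · χ²/f); both the χ²/f-scaled and the unscaled
versions are reported, because the scaling is material in both directions:
real foci data are overdispersed (χ²/f ≈ 5), while data simulated with
exact Poisson structure give χ²/f ≈ 1/3 — the between-dish SD used as the
weight estimates the dish-level scatter, which overstates the sampling
error of the three-dish mean by √3, and the χ²/f scaling restores the
average magnitude. Scaled SEs are the adopted default. They are, however,
not perfectly calibrated at this design: with weights estimated from only
three dishes (two degrees of freedom) the weight noise inflates the true
estimator scatter beyond the linearised formula, and the recovery study in
the acceptance suite measures z-scores (estimate − truth)/SE with SD ≈ 1.3
instead of 1, i.e. 2·SE intervals cover the true per-track yields in
roughly 86–89% of replications rather than the nominal ≈ 95%. This is a
property of weighting by a 2-df SD estimate, not of the optimiser; it is
reported rather than patched.
A parameter ending on a bound is flagged (its SE is boundary-constrained);
a rank-deficient information matrix falls back to the pseudo-inverse with a
flag rather than failing the fit. In the mean-number parameterization the
optimiser may transiently explore p̄_Q > n̄_Q, which box bounds cannot
forbid; the model evaluation used inside the optimiser therefore skips that
check, the public API enforces it, and a violating optimum is reported with
a warning message.

## Synthetic data generator

The generator realises the study design: per radiation quality and time
point, 3 replicate dishes × 1000 nuclei (plus sham and control conditions),
aggregated to the mean of dish means and the between-dish SD — the exact
quantities the regression consumes. Per nucleus: background ~
Poisson(n̄_b); sham component ~ Poisson(n̄_s e^(−β0 Δ)); cluster counts
per size ~ Poisson(k̄(n)) (or an explicit geometry simulation); per
cluster, initial foci ~ Poisson(n·n̄_Q), persistence assigned per focus at
creation (Bernoulli p_Q — a per-cluster assignment would not reproduce the
mixture survival function and is rejected), survival thinning per class;
the cluster scores 1 while any focus survives. Because this is the model's
exact probabilistic inverse, the closed-form mean is the exact expectation
of the generated counts — the acceptance suite verifies agreement within
3 Monte Carlo standard errors on the full quality × time grid at 10⁵
nuclei per point.

Generator truth defaults are the fitted values of the modelled four-beam
HUVEC study (n̄_Q = 0.37/0.63/1.08/1.66 foci per track, p_Q =
0.17/0.10/0.11/0.11, β1 = 0.27 h⁻¹, β2 = 0.01 h⁻¹, n̄_b = 0.24, n̄_s =
0.26, β0 = 0.27 h⁻¹; the background matches the observed control mean of
0.24 foci/nucleus and n̄_b + n̄_s the sham mean of 0.50). What the
generator does *not* emulate: the overdispersion of real per-nucleus counts
(an optional negative-binomial background hook exists, default off),
dish-to-dish systematic effects, cell-cycle structure, and focus
morphology. Passing recovery tests therefore demonstrate correctness of
the estimation machinery under the model's own assumptions, not robustness
to the model violations present in real data.

## Robustness protocol

Three sweeps: (i) start-value sweeps re-run the fit from each start
separately and report the spread of optimum and parameters (zero on convex
or noise-free problems; wide, and deliberately exposed, for unidentifiable
configurations such as zero track yield); (ii) spectrum-batch sweeps refit
with k̄(n) re-estimated in independent 1000-nucleus batches, warm-started
from the reference optimum, and compare the across-batch parameter SD with
the fit SEs; (iii) constraint-variant sweeps refit under
{fraction, mean-number} × {β0 free, β0 = β1} × {β2 free, β2 = 0} plus
per-quality β1 and the independent difference fits, and trace the min/max
envelope of fitted curves on a log-spaced 0.5–24 h grid (100 points). The
envelope always brackets the default-variant curve and can only widen as
variants are added.

On Poisson-clean synthetic data at these conditions the batch spread is
well below the fit SEs for 12 of 13 parameters (ratios 0.02–0.65) but
essentially *equal* to the SE for the 10 MeV-alpha track yield (ratio
≈ 1.01): with calibrated SEs at ~1.2% relative precision, the ~1.3% Monte
Carlo scatter of k̄(n) at 1000-nucleus batches is no longer negligible.
The corresponding acceptance assertion (every ratio < 1) is kept strict and
documents this boundary case rather than hiding it; with the several-fold
larger uncertainties of overdispersed real data the spread is far below the
SEs, which is the regime the protocol was designed for.

## Problem sizes and numerical choices

Cluster spectra used as fixed fit inputs are estimated with 2×10⁴ nuclei;
batch sweeps use 100 batches × 1000 nuclei; the parameter-recovery study
uses 100 replications of the full design with a reduced multi-start
(extremes + 2 Latin-hypercube starts — the recovery landscape is unimodal
and the full 16-start default changes nothing but runtime). Random-number
streams are NumPy `Generator`s seeded explicitly everywhere; batch and
pipeline sub-seeds are derived from the master seed, and every spectrum and
output artifact records its seed. Ties between multi-start optima are
broken first-found; boundary detection uses an absolute tolerance of 1e-8.
Degenerate inputs fail loudly: empty point sets cluster to an empty list,
single-dish designs produce NaN SDs that the regression refuses, truncation
bounds inconsistent with the half-axis means are a configuration error.

## Known limitations

* Between-dish correlation induced by sham subtraction is not modelled in
  the independent fits (matching the published analysis).
* The control series is generated and reported but never fitted; the
  simultaneous fit uses irradiated + sham data only.
* β2 is weakly identified at this design (its fitted value is compatible
  with zero); its recovery coverage is reported but not asserted.
* LET values are metadata only; no track-structure or energy-deposition
  physics is simulated.
* The exponential-survival description of focus disappearance is a
  phenomenological first-order model; mechanistic alternatives (sequential
  repair, repair-time distributions) are out of scope.
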