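"""Weighted simultaneous nonlinear regression of the foci-kinetics model.

All datasets — one per radiation quality, plus the sham-irradiated series —
are fitted at once.  The repair rates β1 and β2 and the sham/background
parameters n̄_b, n̄_s, β0 are shared across datasets; each quality
contributes its own pair (n̄_Q, p_Q) or (n̄_Q, p̄_Q).  The minimised
quantity is the weighted residual sum of squares

    χ² = Σ_j ((observed_j − model_j) / sd_j)²,

the classic "ratios of residuals to uncertainties" objective.  Parameters
are bound-constrained to be non-negative (p_Q additionally ≤ 1); the
optimiser is a trust-region-reflective least-squares solver run from
multiple start points (the all-zero and all-maximum extremes plus a Latin
hypercube) with the best objective winning.

Standard errors come from the linearised problem at the optimum:
SE_i = sqrt([(JᵀJ)⁻¹]_ii · χ²/f), where J is the Jacobian of the weighted
residuals and f the degrees of freedom; both χ²/f-scaled and unscaled SEs
are reported because overdispersed foci data make the choice material.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .geometry import ClusterSpectrum
from .kinetics import (
    KineticsParams,
    ModelOptions,
    ParameterError,
    TrackParams,
    radiation_mean,
    sham_mean,
    total_mean,
)

__all__ = [
    "FociDataset",
    "FitBounds",
    "FitResult",
    "FitError",
    "objective",
    "simultaneous_fit",
    "independent_fit",
    "difference_dataset",
    "standard_errors",
    "covariance_from_jacobian",
]

SHAM = "sham"
CONTROL = "control"


class FitError(RuntimeError):
    """All optimisation starts failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list[str]):
        super().__init__(message + "\n" + "\n".join(diagnostics))
        self.diagnostics = diagnostics


@dataclass
class FociDataset:
    """Mean foci per nucleus ± SD over post-irradiation time for one condition.

    ``mean`` is the mean of the replicate-dish means and ``sd`` the square
    root of the sample variance between those means.  ``quality`` is a
    radiation-quality label, ``"sham"`` or ``"control"``.
    """

    quality: str
    t: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_replicates: int = 3

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.t) == len(self.mean) == len(self.sd)):
            raise ValueError("t, mean and sd must have equal length")
        order = np.argsort(self.t)
        self.t = self.t[order]
        self.mean = self.mean[order]
        self.sd = self.sd[order]

    def __len__(self) -> int:
        return len(self.t)


def difference_dataset(irradiated: FociDataset, sham: FociDataset) -> FociDataset:
    """Irradiated-minus-sham series with root-sum-square sd propagation.

    The subtraction correlates the resulting points with the sham series;
    that correlation is knowingly not modelled in the independent fits.
    """
    if not np.allclose(irradiated.t, sham.t):
        raise ValueError("irradiated and sham datasets must share time points")
    return FociDataset(
        quality=irradiated.quality,
        t=irradiated.t.copy(),
        mean=irradiated.mean - sham.mean,
        sd=np.sqrt(irradiated.sd**2 + sham.sd**2),
        n_replicates=irradiated.n_replicates,
    )


@dataclass(frozen=True)
class FitBounds:
    """Box bounds for the optimiser and for multi-start sampling.

    Lower bounds are all 0 (non-negativity).  The persistent fraction is
    intrinsically ≤ 1; the remaining upper bounds are generous caps used
    for Latin-hypercube start sampling and to keep the trust region finite.
    """

    n_background_max: float = 5.0
    n_sham_max: float = 5.0
    rate_max: float = 10.0
    n_track_max: float = 5.0
    persistent_mean_max: float = 5.0


class _Problem:
    """Free-parameter layout for one fit variant."""

    def __init__(
        self,
        names: list[str],
        lower: np.ndarray,
        upper: np.ndarray,
        unpack,
        residual,
    ):
        self.names = names
        self.lower = lower
        self.upper = upper
        self.unpack = unpack
        self.residual = residual

    @property
    def n_free(self) -> int:
        return len(self.names)


def _dataset_residuals(
    dataset: FociDataset,
    spectra: dict[str, ClusterSpectrum],
    params: KineticsParams,
    options: ModelOptions,
    check: bool,
) -> np.ndarray:
    sd = dataset.sd
    if np.any(~np.isfinite(sd)) or np.any(sd <= 0):
        raise ValueError(
            f"dataset {dataset.quality!r} has non-positive or missing sd; "
            "apply a weight floor or exclude those points before fitting"
        )
    if dataset.quality == SHAM:
        model = sham_mean(dataset.t, params)
    elif dataset.quality == CONTROL:
        model = np.full_like(dataset.t, params.n_background)
    else:
        try:
            spectrum = spectra[dataset.quality]
        except KeyError:
            raise ValueError(
                f"no cluster spectrum provided for quality {dataset.quality!r}"
            )
        model = total_mean(
            dataset.t, dataset.quality, spectrum, params, options, check=check
        )
    return (dataset.mean - np.asarray(model)) / sd


def objective(
    params: KineticsParams,
    datasets: list[FociDataset],
    spectra: dict[str, ClusterSpectrum],
    options: ModelOptions = ModelOptions(),
    check: bool = True,
) -> np.ndarray:
    """Vector of weighted residuals (observed − model)/sd over all datasets.

    The fit minimises the sum of squares of this vector.  Sham datasets are
    modelled by the sham term alone, control datasets by the constant
    background, irradiated datasets by the full cluster-aware model.
    """
    return np.concatenate(
        [_dataset_residuals(d, spectra, params, options, check) for d in datasets]
    )


def _build_simultaneous_problem(
    datasets: list[FociDataset],
    spectra: dict[str, ClusterSpectrum],
    options: ModelOptions,
    bounds: FitBounds,
    t_ref: float,
) -> _Problem:
    if options.per_quality_beta1 and options.beta0_equals_beta1:
        raise ParameterError(
            "beta0_equals_beta1 is ambiguous when beta1 varies per quality"
        )
    qualities = [d.quality for d in datasets if d.quality not in (SHAM, CONTROL)]
    if not qualities:
        raise ValueError("need at least one irradiated dataset")
    if not any(d.quality == SHAM for d in datasets):
        raise ValueError("need a sham dataset for the simultaneous fit")

    names: list[str] = ["n_b", "n_s"]
    lower: list[float] = [0.0, 0.0]
    upper: list[float] = [bounds.n_background_max, bounds.n_sham_max]
    if not options.beta0_equals_beta1:
        names.append("beta0")
        lower.append(0.0)
        upper.append(bounds.rate_max)
    if options.per_quality_beta1:
        for q in qualities:
            names.append(f"beta1[{q}]")
            lower.append(0.0)
            upper.append(bounds.rate_max)
    else:
        names.append("beta1")
        lower.append(0.0)
        upper.append(bounds.rate_max)
    if not options.beta2_zero:
        names.append("beta2")
        lower.append(0.0)
        upper.append(bounds.rate_max)
    fraction = options.parameterization == "fraction"
    for q in qualities:
        names.append(f"n[{q}]")
        lower.append(0.0)
        upper.append(bounds.n_track_max)
        names.append(f"p[{q}]" if fraction else f"pbar[{q}]")
        lower.append(0.0)
        upper.append(1.0 if fraction else bounds.persistent_mean_max)

    index = {name: i for i, name in enumerate(names)}

    def unpack(x: np.ndarray) -> KineticsParams:
        beta1_shared = (
            float(np.mean([x[index[f"beta1[{q}]"]] for q in qualities]))
            if options.per_quality_beta1
            else float(x[index["beta1"]])
        )
        beta0 = beta1_shared if options.beta0_equals_beta1 else float(x[index["beta0"]])
        beta2 = 0.0 if options.beta2_zero else float(x[index["beta2"]])
        tracks = {}
        for q in qualities:
            n_track = float(x[index[f"n[{q}]"]])
            b1q = (
                float(x[index[f"beta1[{q}]"]]) if options.per_quality_beta1 else None
            )
            if fraction:
                tracks[q] = TrackParams(n_track, p_persistent=float(x[index[f"p[{q}]"]]), beta1=b1q)
            else:
                tracks[q] = TrackParams(
                    n_track, persistent_mean=float(x[index[f"pbar[{q}]"]]), beta1=b1q
                )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return KineticsParams(
                n_background=float(x[index["n_b"]]),
                n_sham=float(x[index["n_s"]]),
                beta0=beta0,
                beta1=beta1_shared,
                beta2=beta2,
                tracks=tracks,
                t_ref=t_ref,
            )

    def residual(x: np.ndarray) -> np.ndarray:
        return objective(unpack(x), datasets, spectra, options, check=False)

    return _Problem(names, np.array(lower), np.array(upper), unpack, residual)


def _multistart_points(
    problem: _Problem,
    starts: list[np.ndarray] | None,
    n_random_starts: int,
    seed: int | None,
) -> list[np.ndarray]:
    pts: list[np.ndarray] = []
    if starts is not None:
        pts.extend(np.asarray(s, dtype=float) for s in starts)
    else:
        # the two extremes: everything at zero, everything at the maximum
        pts.append(problem.lower.copy())
        pts.append(problem.upper.copy())
    if n_random_starts > 0:
        sampler = qmc.LatinHypercube(d=problem.n_free, seed=seed)
        unit = sampler.random(n_random_starts)
        pts.extend(problem.lower + unit * (problem.upper - problem.lower))
    return pts


@dataclass
class FitResult:
    """Outcome of one bound-constrained weighted least-squares fit."""

    kind: str
    options: ModelOptions
    free_names: list[str]
    x: np.ndarray
    params: KineticsParams
    chi2: float
    dof: int
    n_points: int
    jac: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    cov_unscaled: np.ndarray | None
    cov_scaled: np.ndarray | None
    rank_deficient: bool
    at_bound: dict[str, bool]
    n_starts: int
    start_index: int
    start_costs: list[float]
    messages: list[str] = field(default_factory=list)

    @property
    def chi2_per_dof(self) -> float:
        return self.chi2 / self.dof if self.dof > 0 else float("nan")

    @property
    def estimates(self) -> dict[str, float]:
        return dict(zip(self.free_names, (float(v) for v in self.x)))

    def _se(self, cov: np.ndarray | None) -> dict[str, float]:
        if cov is None:
            return {n: float("nan") for n in self.free_names}
        d = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        return dict(zip(self.free_names, (float(v) for v in d)))

    @property
    def se_scaled(self) -> dict[str, float]:
        """SEs scaled by χ²/f (accounts for over/under-dispersion)."""
        return self._se(self.cov_scaled)

    @property
    def se_unscaled(self) -> dict[str, float]:
        return self._se(self.cov_unscaled)


def covariance_from_jacobian(
    jac: np.ndarray, chi2: float, dof: int
) -> tuple[np.ndarray | None, np.ndarray | None, bool]:
    """(unscaled, χ²/f-scaled) parameter covariance from the weighted Jacobian.

    The unscaled covariance is (JᵀJ)⁻¹ — J already incorporates the 1/sd
    weights.  A rank-deficient JᵀJ falls back to the pseudo-inverse and is
    flagged.  The scaled covariance multiplies by χ²/f (None when f ≤ 0).
    """
    jtj = jac.T @ jac
    rank = np.linalg.matrix_rank(jtj)
    deficient = rank < jtj.shape[0]
    if deficient:
        cov = np.linalg.pinv(jtj)
    else:
        cov = np.linalg.inv(jtj)
    scaled = cov * (chi2 / dof) if dof > 0 else None
    return cov, scaled, deficient


def _finish_fit(
    kind: str,
    problem: _Problem,
    options: ModelOptions,
    best,
    n_points: int,
    n_starts: int,
    start_index: int,
    start_costs: list[float],
) -> FitResult:
    x = best.x
    chi2 = float(2.0 * best.cost)
    dof = n_points - problem.n_free
    cov_u, cov_s, deficient = covariance_from_jacobian(best.jac, chi2, dof)
    atol = 1e-8
    at_bound = {
        name: bool(
            abs(x[i] - problem.lower[i]) <= atol * max(1.0, abs(problem.lower[i]))
            or abs(x[i] - problem.upper[i]) <= atol * max(1.0, abs(problem.upper[i]))
        )
        for i, name in enumerate(problem.names)
    }
    messages: list[str] = []
    if deficient:
        messages.append(
            "information matrix is rank deficient; SEs use the pseudo-inverse"
        )
    for name, hit in at_bound.items():
        if hit:
            messages.append(
                f"parameter {name} sits at a bound; its SE is boundary-constrained"
            )
    params = problem.unpack(x)
    if params.beta2 > params.beta1:
        messages.append("beta2 > beta1 at the optimum (class labels swapped)")
    for q, tp in params.tracks.items():
        if tp.persistent_mean is not None and tp.persistent_mean > tp.n_track + 1e-9:
            messages.append(
                f"persistent_mean exceeds n_track for {q}; the mean-number "
                "parameterization wandered outside the fraction-form domain"
            )
    return FitResult(
        kind=kind,
        options=options,
        free_names=problem.names,
        x=x,
        params=params,
        chi2=chi2,
        dof=dof,
        n_points=n_points,
        jac=best.jac,
        lower=problem.lower,
        upper=problem.upper,
        cov_unscaled=cov_u,
        cov_scaled=cov_s,
        rank_deficient=deficient,
        at_bound=at_bound,
        n_starts=n_starts,
        start_index=start_index,
        start_costs=start_costs,
        messages=messages,
    )


def _canonical_label_swap(
    problem: _Problem, options: ModelOptions, x: np.ndarray
) -> np.ndarray | None:
    """Mirror an optimum with β2 > β1 into the conventional labelling.

    The two repair classes are exchangeable: swapping β1 ↔ β2 together with
    p_Q → 1 − p_Q (or p̄_Q → n̄_Q − p̄_Q) for every quality leaves the model
    unchanged, so each optimum has an equal-χ² mirror.  The convention that
    "persistent" means the slower class picks one of the two.  Returns the
    mirrored vector, or None when the swap is not an exact symmetry (β0 tied
    to β1, per-quality β1, β2 fixed) or would leave the bounds.
    """
    if options.beta0_equals_beta1 or options.beta2_zero or options.per_quality_beta1:
        return None
    idx = {n: i for i, n in enumerate(problem.names)}
    if "beta1" not in idx or "beta2" not in idx:
        return None
    if x[idx["beta2"]] <= x[idx["beta1"]]:
        return None
    y = x.copy()
    y[idx["beta1"]], y[idx["beta2"]] = x[idx["beta2"]], x[idx["beta1"]]
    for name, i in idx.items():
        if name.startswith("p["):
            y[i] = 1.0 - x[i]
        elif name.startswith("pbar["):
            q = name[5:-1]
            n_val = x[idx[f"n[{q}]"]]
            mirrored = n_val - x[i]
            if mirrored < 0:
                return None
            y[i] = mirrored
    if np.any(y < problem.lower - 1e-12) or np.any(y > problem.upper + 1e-12):
        return None
    return np.clip(y, problem.lower, problem.upper)


def _run_multistart(
    kind: str,
    problem: _Problem,
    options: ModelOptions,
    n_points: int,
    starts: list[np.ndarray] | None,
    n_random_starts: int,
    seed: int | None,
) -> FitResult:
    pts = _multistart_points(problem, starts, n_random_starts, seed)
    best = None
    best_i = -1
    costs: list[float] = []
    diagnostics: list[str] = []
    for i, x0 in enumerate(pts):
        x0 = np.clip(x0, problem.lower, problem.upper)
        try:
            res = least_squares(
                problem.residual,
                x0,
                bounds=(problem.lower, problem.upper),
                method="trf",
                ftol=1e-12,
                xtol=1e-12,
                gtol=1e-12,
            )
        except Exception as exc:  # keep going; report per-start failures
            diagnostics.append(f"start {i}: raised {exc!r}")
            costs.append(float("nan"))
            continue
        if res.status <= 0:
            diagnostics.append(f"start {i}: did not converge ({res.message})")
            costs.append(float("nan"))
            continue
        costs.append(float(2.0 * res.cost))
        if best is None or res.cost < best.cost:
            best = res
            best_i = i
    if best is None:
        raise FitError(
            f"all {len(pts)} optimisation starts failed for the {kind} fit",
            diagnostics,
        )
    mirrored = _canonical_label_swap(problem, options, best.x)
    if mirrored is not None:
        # polish from the mirrored point so Jacobian and estimates agree
        res = least_squares(
            problem.residual,
            mirrored,
            bounds=(problem.lower, problem.upper),
            method="trf",
            ftol=1e-12,
            xtol=1e-12,
            gtol=1e-12,
        )
        if res.status > 0 and res.cost <= best.cost * (1 + 1e-9) + 1e-12:
            best = res
    return _finish_fit(kind, problem, options, best, n_points, len(pts), best_i, costs)


def simultaneous_fit(
    datasets: list[FociDataset],
    spectra: dict[str, ClusterSpectrum],
    options: ModelOptions = ModelOptions(),
    starts: list[np.ndarray] | None = None,
    n_random_starts: int = 16,
    seed: int | None = 0,
    bounds: FitBounds = FitBounds(),
    t_ref: float = 0.5,
) -> FitResult:
    """Fit all datasets at once with shared kinetics and per-quality track terms.

    The default free parameters are n̄_b, n̄_s, β0, β1, β2 and (n̄_Q, p_Q)
    per quality — 13 parameters for four qualities, hence f = 12 with the
    standard 4 × 5 + 5 design.  ``options`` selects the constraint variant
    and the parameterization.  ``starts`` overrides the default multi-start
    extremes; ``n_random_starts`` Latin-hypercube starts are added either
    way.  Raises :class:`FitError` with per-start diagnostics if nothing
    converges.
    """
    problem = _build_simultaneous_problem(datasets, spectra, options, bounds, t_ref)
    n_points = sum(len(d) for d in datasets)
    # validate weights up front so a bad sd fails fast with a clear message
    for d in datasets:
        if np.any(~np.isfinite(d.sd)) or np.any(d.sd <= 0):
            raise ValueError(
                f"dataset {d.quality!r} has non-positive or missing sd; "
                "apply a weight floor or exclude those points before fitting"
            )
    return _run_multistart(
        "simultaneous", problem, options, n_points, starts, n_random_starts, seed
    )


def _build_independent_problem(
    dataset: FociDataset,
    spectrum: ClusterSpectrum,
    options: ModelOptions,
    bounds: FitBounds,
    t_ref: float,
) -> _Problem:
    q = dataset.quality
    fraction = options.parameterization == "fraction"
    names = [f"n[{q}]", f"p[{q}]" if fraction else f"pbar[{q}]", "beta1"]
    lower = [0.0, 0.0, 0.0]
    upper = [
        bounds.n_track_max,
        1.0 if fraction else bounds.persistent_mean_max,
        bounds.rate_max,
    ]
    if not options.beta2_zero:
        names.append("beta2")
        lower.append(0.0)
        upper.append(bounds.rate_max)

    def unpack(x: np.ndarray) -> KineticsParams:
        if fraction:
            tp = TrackParams(float(x[0]), p_persistent=float(x[1]))
        else:
            tp = TrackParams(float(x[0]), persistent_mean=float(x[1]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return KineticsParams(
                n_background=0.0,
                n_sham=0.0,
                beta0=0.0,
                beta1=float(x[2]),
                beta2=0.0 if options.beta2_zero else float(x[3]),
                tracks={q: tp},
                t_ref=t_ref,
            )

    def residual(x: np.ndarray) -> np.ndarray:
        params = unpack(x)
        model = radiation_mean(dataset.t, spectrum, params, options, check=False)
        return (dataset.mean - np.asarray(model)) / dataset.sd

    return _Problem(names, np.array(lower), np.array(upper), unpack, residual)


def independent_fit(
    dataset: FociDataset,
    spectrum: ClusterSpectrum,
    options: ModelOptions = ModelOptions(),
    starts: list[np.ndarray] | None = None,
    n_random_starts: int = 16,
    seed: int | None = 0,
    bounds: FitBounds = FitBounds(),
    t_ref: float = 0.5,
) -> FitResult:
    """Fit one irradiated-minus-sham difference series with the radiation term only.

    ``dataset`` should come from :func:`difference_dataset`.  Free parameters
    are (n̄_Q, p_Q, β1, β2): with five time points that leaves a single
    degree of freedom, and two when β2 is fixed to zero — which is why
    these fits are reported but the simultaneous fit carries the analysis.
    """
    if dataset.quality in (SHAM, CONTROL):
        raise ValueError("independent fits apply to irradiated difference series")
    if spectrum.quality != dataset.quality:
        raise ValueError("spectrum/dataset quality mismatch")
    if np.any(~np.isfinite(dataset.sd)) or np.any(dataset.sd <= 0):
        raise ValueError(
            f"dataset {dataset.quality!r} has non-positive or missing sd; "
            "apply a weight floor or exclude those points before fitting"
        )
    problem = _build_independent_problem(dataset, spectrum, options, bounds, t_ref)
    return _run_multistart(
        "independent", problem, options, len(dataset), starts, n_random_starts, seed
    )


def standard_errors(fit: FitResult, scaled: bool = True) -> dict[str, float]:
    """Per-parameter standard errors of a converged fit.

    With ``scaled=True`` the covariance is multiplied by χ²/f.  Parameters
    flagged in ``fit.at_bound`` sit on a constraint and their SEs should be
    read as boundary-constrained; a rank-deficient fit reports
    pseudo-inverse SEs (see ``fit.messages``).
    """
    return fit.se_scaled if scaled else fit.se_unscaled
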