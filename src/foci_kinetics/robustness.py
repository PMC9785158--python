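"""Robustness protocol for the simultaneous regression.

Three sweeps probe how stable the fitted kinetics are:

* **start-value sweep** — re-run the fit from a grid of start points,
  including the extremes of everything-at-zero and everything-at-maximum,
  and report the spread of objective and parameters;
* **spectrum-batch sweep** — re-estimate the geometric input k̄(n) in many
  independent Monte Carlo batches, refit per batch, and compare the
  across-batch parameter spread with the regression standard errors
  (simulation scatter should be well below statistical uncertainty);
* **constraint-variant sweep** — refit under every combination of
  parameterization (fraction / mean-number), β0 free vs β0 = β1 and β2 free
  vs β2 = 0, plus the per-quality-β1 variant and independent difference
  fits, and trace the min/max envelope of the fitted curves over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ClusterSpectrum
from .kinetics import ModelOptions, radiation_mean, sham_mean, total_mean
from .regression import (
    SHAM,
    FitError,
    FitResult,
    FociDataset,
    difference_dataset,
    independent_fit,
    simultaneous_fit,
)

__all__ = [
    "RobustnessReport",
    "start_value_sweep",
    "spectrum_batch_sweep",
    "variant_sweep",
    "default_time_grid",
]

DEFAULT_VARIANT = "fraction|beta0-free|beta2-free"


def default_time_grid(n: int = 100) -> np.ndarray:
    """Log-spaced evaluation times spanning the observed 0.5–24 h window."""
    return np.logspace(np.log10(0.5), np.log10(24.0), n)


@dataclass
class RobustnessReport:
    """Collected fits of one sweep plus summary spreads.

    ``parameter_ranges`` span converged fits only; ``n_failed`` counts the
    rest.  ``parameter_spread`` (batch sweep) is the SD of each parameter
    across batch fits and ``spread_to_se`` its ratio to the reference fit's
    scaled SE.  ``envelope`` (variant sweep) holds per (quality, t) the
    min/max of the fitted mean-foci curves and the default-variant curve.
    """

    fits: dict[str, FitResult]
    failures: dict[str, str] = field(default_factory=dict)
    parameter_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    objective_range: tuple[float, float] | None = None
    parameter_spread: dict[str, float] | None = None
    spread_to_se: dict[str, float] | None = None
    envelope: pd.DataFrame | None = None

    @property
    def n_converged(self) -> int:
        return len(self.fits)

    @property
    def n_failed(self) -> int:
        return len(self.failures)


def _ranges(fits: dict[str, FitResult]) -> dict[str, tuple[float, float]]:
    names = sorted({n for f in fits.values() for n in f.free_names})
    out = {}
    for name in names:
        vals = [f.estimates[name] for f in fits.values() if name in f.estimates]
        if vals:
            out[name] = (min(vals), max(vals))
    return out


def start_value_sweep(
    datasets: list[FociDataset],
    spectra: dict[str, ClusterSpectrum],
    options: ModelOptions = ModelOptions(),
    start_grid: list[np.ndarray] | None = None,
    n_random_starts: int = 16,
    seed: int | None = 0,
) -> RobustnessReport:
    """One single-start fit per start point; spread of optimum across starts.

    With ``start_grid=None`` the grid is the two extremes plus
    ``n_random_starts`` Latin-hypercube points (materialised by running each
    as its own fit so per-start outcomes are visible, unlike the pooled
    multi-start of :func:`simultaneous_fit`).
    """
    if start_grid is None:
        probe = simultaneous_fit(
            datasets, spectra, options, n_random_starts=0, seed=seed
        )
        from .regression import _build_simultaneous_problem, _multistart_points, FitBounds

        problem = _build_simultaneous_problem(
            datasets, spectra, options, FitBounds(), probe.params.t_ref
        )
        start_grid = _multistart_points(problem, None, n_random_starts, seed)
    fits: dict[str, FitResult] = {}
    failures: dict[str, str] = {}
    for i, x0 in enumerate(start_grid):
        key = f"start[{i}]"
        try:
            fits[key] = simultaneous_fit(
                datasets, spectra, options, starts=[x0], n_random_starts=0
            )
        except FitError as exc:
            failures[key] = str(exc)
    report = RobustnessReport(fits=fits, failures=failures)
    report.parameter_ranges = _ranges(fits)
    if fits:
        costs = [f.chi2 for f in fits.values()]
        report.objective_range = (min(costs), max(costs))
    return report


def spectrum_batch_sweep(
    datasets: list[FociDataset],
    batch_spectra: list[dict[str, ClusterSpectrum]],
    options: ModelOptions = ModelOptions(),
    base_fit: FitResult | None = None,
    n_random_starts: int = 4,
    seed: int | None = 0,
) -> RobustnessReport:
    """Refit once per spectrum batch; parameter spread across batches.

    Each batch is an independent Monte Carlo estimate of the cluster spectra
    for all qualities.  When ``base_fit`` is given, each batch fit is
    warm-started from its optimum (the batches perturb the fixed geometric
    input only slightly, so the optimum moves little); otherwise each batch
    runs its own reduced multi-start.  ``spread_to_se`` compares the
    across-batch SD with the reference fit's scaled SEs.
    """
    if len(batch_spectra) < 2:
        raise ValueError("need at least 2 spectrum batches")
    fits: dict[str, FitResult] = {}
    failures: dict[str, str] = {}
    starts = [base_fit.x] if base_fit is not None else None
    nrs = 0 if base_fit is not None else n_random_starts
    for i, spectra in enumerate(batch_spectra):
        key = f"batch[{i}]"
        try:
            fits[key] = simultaneous_fit(
                datasets, spectra, options, starts=starts, n_random_starts=nrs,
                seed=seed,
            )
        except FitError as exc:
            failures[key] = str(exc)
    report = RobustnessReport(fits=fits, failures=failures)
    report.parameter_ranges = _ranges(fits)
    if fits:
        names = next(iter(fits.values())).free_names
        spread = {}
        for name in names:
            vals = np.array([f.estimates[name] for f in fits.values()])
            spread[name] = float(vals.std(ddof=1))
        report.parameter_spread = spread
        if base_fit is not None:
            se = base_fit.se_scaled
            report.spread_to_se = {
                n: (spread[n] / se[n] if se.get(n, 0) > 0 else float("nan"))
                for n in names
            }
    return report


def _variant_options() -> dict[str, ModelOptions]:
    out: dict[str, ModelOptions] = {}
    for par in ("fraction", "mean-number"):
        for b0 in (False, True):
            for b2 in (False, True):
                key = (
                    f"{par}|beta0-{'tied' if b0 else 'free'}"
                    f"|beta2-{'zero' if b2 else 'free'}"
                )
                out[key] = ModelOptions(
                    parameterization=par,
                    beta0_equals_beta1=b0,
                    beta2_zero=b2,
                )
    out["fraction|per-quality-beta1"] = ModelOptions(per_quality_beta1=True)
    return out


def variant_sweep(
    datasets: list[FociDataset],
    spectra: dict[str, ClusterSpectrum],
    n_random_starts: int = 8,
    seed: int | None = 0,
    time_grid: np.ndarray | None = None,
    include_independent: bool = True,
    variants: dict[str, ModelOptions] | None = None,
) -> RobustnessReport:
    """Fit every constraint/parameterization variant and trace the curve envelope.

    Simultaneous variants: {fraction, mean-number} × {β0 free, β0 = β1} ×
    {β2 free, β2 = 0}, plus per-quality β1 (or an explicit ``variants``
    mapping to restrict/extend the set; the envelope needs the default
    variant to be present).  With
    ``include_independent=True``, per-quality difference fits (β2 free and
    β2 = 0) are added; their curves enter the envelope after adding back the
    default variant's sham term, since they model the irradiated-minus-sham
    series.
    """
    if time_grid is None:
        time_grid = default_time_grid()
    sham_ds = next((d for d in datasets if d.quality == SHAM), None)
    qualities = [d.quality for d in datasets if d.quality not in (SHAM, "control")]

    fits: dict[str, FitResult] = {}
    failures: dict[str, str] = {}
    if variants is None:
        variants = _variant_options()
    for key, options in variants.items():
        try:
            fits[key] = simultaneous_fit(
                datasets, spectra, options, n_random_starts=n_random_starts, seed=seed
            )
        except FitError as exc:
            failures[key] = str(exc)

    if include_independent and sham_ds is not None:
        for q in qualities:
            irr = next(d for d in datasets if d.quality == q)
            diff = difference_dataset(irr, sham_ds)
            for b2, tag in ((False, "beta2-free"), (True, "beta2-zero")):
                key = f"independent[{q}]|{tag}"
                try:
                    fits[key] = independent_fit(
                        diff,
                        spectra[q],
                        ModelOptions(beta2_zero=b2),
                        n_random_starts=n_random_starts,
                        seed=seed,
                    )
                except FitError as exc:
                    failures[key] = str(exc)

    report = RobustnessReport(fits=fits, failures=failures)
    report.parameter_ranges = _ranges(fits)

    default_fit = fits.get(DEFAULT_VARIANT)
    if default_fit is not None:
        rows = []
        for q in qualities:
            spectrum = spectra[q]
            default_curve = np.asarray(
                total_mean(time_grid, q, spectrum, default_fit.params,
                           default_fit.options)
            )
            curves = [default_curve]
            for key, fit in fits.items():
                if key == DEFAULT_VARIANT:
                    continue
                if fit.kind == "independent":
                    if fit.params.tracks.get(q) is None:
                        continue
                    curve = np.asarray(
                        radiation_mean(time_grid, spectrum, fit.params, fit.options,
                                       check=False)
                    ) + np.asarray(sham_mean(time_grid, default_fit.params))
                else:
                    curve = np.asarray(
                        total_mean(time_grid, q, spectrum, fit.params, fit.options,
                                   check=False)
                    )
                curves.append(curve)
            stack = np.vstack(curves)
            rows.append(
                pd.DataFrame(
                    {
                        "quality": q,
                        "t_h": time_grid,
                        "lo": stack.min(axis=0),
                        "hi": stack.max(axis=0),
                        "default": default_curve,
                    }
                )
            )
        report.envelope = pd.concat(rows, ignore_index=True)
    return report
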