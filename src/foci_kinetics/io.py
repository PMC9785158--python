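"""File schemas, validated configuration, report rendering and the pipeline.

All tabular artifacts are plain CSV with explicit units in the column names
(``t_h`` for hours, ``rate_per_h`` for h⁻¹), because the kinetic model mixes
hours and inverse hours and implicit units invite silent errors.  The
pipeline stamps every output with the seed and a hash of the configuration
so a run can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .geometry import (
    BeamProfile,
    ClusterSpectrum,
    IonDeliveryModel,
    NucleusPopulationModel,
    TargetPattern,
    batch_spectra,
    estimate_cluster_spectrum,
)
from .kinetics import KineticsParams, ModelOptions, TrackParams
from .radiation import DEFAULT_QUALITIES
from .regression import (
    CONTROL,
    SHAM,
    FitResult,
    FociDataset,
    simultaneous_fit,
)
from .robustness import spectrum_batch_sweep, variant_sweep
from .synthetic import ExperimentDesign, generate_observations, generate_tables

__all__ = [
    "GeometryConfig",
    "TrackConfig",
    "KineticsConfig",
    "DesignConfig",
    "FitOptionsConfig",
    "RobustnessConfig",
    "PipelineConfig",
    "load_config",
    "read_datasets_csv",
    "write_datasets_csv",
    "read_spectra_csv",
    "write_spectra_csv",
    "render_report",
    "format_report",
    "run_pipeline",
]

log = logging.getLogger("foci_kinetics")

_forbid = ConfigDict(extra="forbid")


class GeometryConfig(BaseModel):
    """Irradiation-geometry block: pattern, beam, miscounting, nuclei, clustering."""

    model_config = _forbid

    pattern_side_um: float = 4.0
    beam_fwhm_um: float = 4.0
    p0: float = 0.05
    p1: float = 0.90
    p2: float = 0.05
    mean_a_um: float = 8.0
    mean_b_um: float = 5.0
    pc_sd_major_um: float = 2.0
    pc_sd_minor_um: float = 1.0
    pc_angle_rad: float = 0.0
    min_half_axis_um: float = 0.5
    proximity_radius_um: float = 2.0
    n_nuclei: int = 1000

    def pattern(self) -> TargetPattern:
        return TargetPattern.square_with_center(self.pattern_side_um)

    def beam(self) -> BeamProfile:
        return BeamProfile(self.beam_fwhm_um)

    def delivery(self) -> IonDeliveryModel:
        return IonDeliveryModel(self.p0, self.p1, self.p2)

    def pop_model(self) -> NucleusPopulationModel:
        return NucleusPopulationModel(
            mean_a=self.mean_a_um,
            mean_b=self.mean_b_um,
            pc_sd_major=self.pc_sd_major_um,
            pc_sd_minor=self.pc_sd_minor_um,
            pc_angle=self.pc_angle_rad,
            min_half_axis=self.min_half_axis_um,
        )


class TrackConfig(BaseModel):
    model_config = _forbid

    n_track: float
    p_persistent: float | None = None
    persistent_mean: float | None = None


class KineticsConfig(BaseModel):
    """Generator-truth kinetic parameters (units: foci, h⁻¹, hours)."""

    model_config = _forbid

    n_background: float = 0.24
    n_sham: float = 0.26
    beta0_per_h: float = 0.27
    beta1_per_h: float = 0.27
    beta2_per_h: float = 0.01
    t_ref_h: float = 0.5
    tracks: dict[str, TrackConfig] = Field(default_factory=dict)

    def params(self) -> KineticsParams:
        return KineticsParams(
            n_background=self.n_background,
            n_sham=self.n_sham,
            beta0=self.beta0_per_h,
            beta1=self.beta1_per_h,
            beta2=self.beta2_per_h,
            t_ref=self.t_ref_h,
            tracks={
                q: TrackParams(c.n_track, c.p_persistent, c.persistent_mean)
                for q, c in self.tracks.items()
            },
        )


class DesignConfig(BaseModel):
    model_config = _forbid

    times_h: list[float] = Field(default_factory=lambda: [0.5, 2.0, 4.0, 8.0, 24.0])
    n_replicates: int = 3
    n_nuclei: int = 1000
    background_dispersion: float | None = None

    def design(self, qualities: tuple[str, ...]) -> ExperimentDesign:
        return ExperimentDesign(
            qualities=qualities,
            times=tuple(self.times_h),
            n_replicates=self.n_replicates,
            n_nuclei=self.n_nuclei,
            background_dispersion=self.background_dispersion,
        )


class FitOptionsConfig(BaseModel):
    model_config = _forbid

    parameterization: str = "fraction"
    beta0_equals_beta1: bool = False
    beta2_zero: bool = False
    per_quality_beta1: bool = False
    n_random_starts: int = 16

    def options(self) -> ModelOptions:
        return ModelOptions(
            parameterization=self.parameterization,
            beta0_equals_beta1=self.beta0_equals_beta1,
            beta2_zero=self.beta2_zero,
            per_quality_beta1=self.per_quality_beta1,
        )


class RobustnessConfig(BaseModel):
    model_config = _forbid

    enabled: bool = False
    n_batches: int = 20
    n_nuclei_per_batch: int = 1000
    n_random_starts: int = 8


class PipelineConfig(BaseModel):
    """Validated end-to-end pipeline configuration (unknown keys rejected)."""

    model_config = _forbid

    seed: int = 0
    outdir: str = "results"
    datasets_csv: str | None = None
    spectra_csv: str | None = None
    geometry: GeometryConfig | None = None
    kinetics: KineticsConfig | None = None
    design: DesignConfig | None = None
    fit: FitOptionsConfig = Field(default_factory=FitOptionsConfig)
    robustness: RobustnessConfig = Field(default_factory=RobustnessConfig)

    @model_validator(mode="after")
    def _check_sources(self) -> "PipelineConfig":
        if self.spectra_csv is None and self.geometry is None:
            raise ValueError(
                "config needs 'spectra_csv' or a 'geometry' simulation block"
            )
        if self.datasets_csv is None:
            if self.kinetics is None or not self.kinetics.tracks:
                raise ValueError(
                    "config needs 'datasets_csv' or a 'kinetics' block with "
                    "per-quality tracks to simulate data"
                )
            if self.design is None:
                raise ValueError(
                    "config needs 'datasets_csv' or a 'design' block to simulate data"
                )
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


# ---------------------------------------------------------------------------
# CSV schemas


def write_datasets_csv(datasets: dict[str, FociDataset], path: str | Path) -> None:
    rows = []
    for q, d in datasets.items():
        for t, m, s in zip(d.t, d.mean, d.sd):
            rows.append(
                {"quality": q, "t_h": t, "mean": m, "sd": s, "n_rep": d.n_replicates}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_datasets_csv(path: str | Path) -> dict[str, FociDataset]:
    df = pd.read_csv(path)
    required = {"quality", "t_h", "mean", "sd", "n_rep"}
    if not required.issubset(df.columns):
        raise ValueError(f"datasets CSV must have columns {sorted(required)}")
    out = {}
    for q, grp in df.groupby("quality", sort=False):
        out[str(q)] = FociDataset(
            quality=str(q),
            t=grp["t_h"].to_numpy(),
            mean=grp["mean"].to_numpy(),
            sd=grp["sd"].to_numpy(),
            n_replicates=int(grp["n_rep"].iloc[0]),
        )
    return out


def write_spectra_csv(spectra: dict[str, ClusterSpectrum], path: str | Path) -> None:
    rows = []
    for q, s in spectra.items():
        for n, k in sorted(s.k_bar.items()):
            rows.append(
                {
                    "quality": q,
                    "n": n,
                    "k_bar": k,
                    "n_nuclei": s.n_nuclei,
                    "seed": s.seed if s.seed is not None else "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_spectra_csv(path: str | Path) -> dict[str, ClusterSpectrum]:
    df = pd.read_csv(path)
    required = {"quality", "n", "k_bar", "n_nuclei"}
    if not required.issubset(df.columns):
        raise ValueError(f"spectra CSV must have columns {sorted(required)}")
    out = {}
    for q, grp in df.groupby("quality", sort=False):
        seed = None
        if "seed" in grp.columns and pd.notna(grp["seed"].iloc[0]):
            try:
                seed = int(grp["seed"].iloc[0])
            except (TypeError, ValueError):
                seed = None
        out[str(q)] = ClusterSpectrum(
            quality=str(q),
            k_bar={int(n): float(k) for n, k in zip(grp["n"], grp["k_bar"])},
            n_nuclei=int(grp["n_nuclei"].iloc[0]),
            seed=seed,
        )
    return out


# ---------------------------------------------------------------------------
# Report rendering


def _let_for(quality: str) -> float | None:
    for q in DEFAULT_QUALITIES:
        if q.label == quality:
            return q.let_kev_um
    return None


def _delta_se_product(n, p, var_n, var_p, cov_np) -> float:
    # var(n·p) by the delta method
    return float(np.sqrt(max(p * p * var_n + n * n * var_p + 2 * n * p * cov_np, 0.0)))


def _delta_se_ratio(pbar, n, var_pbar, var_n, cov) -> float:
    # var(p̄/n) by the delta method
    if n == 0:
        return float("nan")
    g = np.array([1.0 / n, -pbar / n**2])
    v = g @ np.array([[var_pbar, cov], [cov, var_n]]) @ g
    return float(np.sqrt(max(v, 0.0)))


def render_report(fit: FitResult, scaled_se: bool = True) -> pd.DataFrame:
    """One row per radiation quality, in the layout of the published tables.

    Both parameterizations are shown; the one that was not fitted is
    computed via the reparameterization identity (its column is flagged
    with ``*_derived = True``, and its SE propagated by the delta method
    from the fitted covariance).  Shared rates and χ²/f (with f printed
    explicitly) repeat on every row.
    """
    se = fit.se_scaled if scaled_se else fit.se_unscaled
    cov = fit.cov_scaled if scaled_se else fit.cov_unscaled
    idx = {n: i for i, n in enumerate(fit.free_names)}
    fraction_fitted = fit.options.parameterization == "fraction"
    rows = []
    for q, tp in fit.params.tracks.items():
        n_name = f"n[{q}]"
        other_name = f"p[{q}]" if fraction_fitted else f"pbar[{q}]"
        n_val = tp.n_track
        n_se = se.get(n_name, float("nan"))
        if fraction_fitted:
            p_val = tp.fraction()
            p_se = se.get(other_name, float("nan"))
            pbar_val = tp.mean_persistent()
            if cov is not None and n_name in idx and other_name in idx:
                i, j = idx[n_name], idx[other_name]
                pbar_se = _delta_se_product(
                    n_val, p_val, cov[i, i], cov[j, j], cov[i, j]
                )
            else:
                pbar_se = float("nan")
            p_derived, pbar_derived = False, True
        else:
            pbar_val = tp.mean_persistent(check=False)
            pbar_se = se.get(other_name, float("nan"))
            p_val = tp.fraction(check=False)
            if cov is not None and n_name in idx and other_name in idx:
                i, j = idx[n_name], idx[other_name]
                p_se = _delta_se_ratio(pbar_val, n_val, cov[j, j], cov[i, i], cov[i, j])
            else:
                p_se = float("nan")
            p_derived, pbar_derived = True, False
        b1_name = f"beta1[{q}]" if fit.options.per_quality_beta1 else "beta1"
        rows.append(
            {
                "quality": q,
                "let_kev_um": _let_for(q),
                "n_track": n_val,
                "n_track_se": n_se,
                "p_persistent": p_val,
                "p_persistent_se": p_se,
                "p_persistent_derived": p_derived,
                "persistent_mean": pbar_val,
                "persistent_mean_se": pbar_se,
                "persistent_mean_derived": pbar_derived,
                "beta1_rate_per_h": fit.params.beta1_for(q),
                "beta1_se": se.get(b1_name, float("nan")),
                "beta2_rate_per_h": fit.params.beta2,
                "beta2_se": se.get("beta2", float("nan")),
                "chi2": fit.chi2,
                "dof": fit.dof,
                "chi2_per_dof": fit.chi2_per_dof,
            }
        )
    return pd.DataFrame(rows)


def format_report(fit: FitResult, scaled_se: bool = True) -> str:
    """Human-readable fit report (derived columns marked with an asterisk)."""
    df = render_report(fit, scaled_se)
    lines = [
        f"{fit.kind} fit — parameterization: {fit.options.parameterization}; "
        f"chi2 = {fit.chi2:.2f}, f = {fit.dof}, chi2/f = {fit.chi2_per_dof:.2f}",
        f"{'quality':<10}{'LET':>6}  {'n_Q':>12}  {'p_Q':>14}  {'pbar_Q':>14}"
        f"  {'beta1/h':>12}  {'beta2/h':>12}",
    ]
    for _, r in df.iterrows():
        p_mark = "*" if r.p_persistent_derived else " "
        pb_mark = "*" if r.persistent_mean_derived else " "
        let = f"{r.let_kev_um:.0f}" if pd.notna(r.let_kev_um) else "-"
        lines.append(
            f"{r.quality:<10}{let:>6}  "
            f"{r.n_track:.2f} ± {r.n_track_se:.2f}  "
            f"{p_mark}{r.p_persistent:.2f} ± {r.p_persistent_se:.2f}  "
            f"{pb_mark}{r.persistent_mean:.2f} ± {r.persistent_mean_se:.2f}  "
            f"{r.beta1_rate_per_h:.2f} ± {r.beta1_se:.2f}  "
            f"{r.beta2_rate_per_h:.2f} ± {r.beta2_se:.2f}"
        )
    lines.append("(* derived from the fitted column via p̄_Q = n̄_Q · p_Q)")
    others = {
        n: v
        for n, v in fit.estimates.items()
        if not n.startswith(("n[", "p[", "pbar[", "beta1["))
        and n not in ("beta1", "beta2")
    }
    if others:
        se = fit.se_scaled if scaled_se else fit.se_unscaled
        lines.append(
            "shared: "
            + ", ".join(f"{n} = {v:.3f} ± {se[n]:.3f}" for n, v in others.items())
        )
    for msg in fit.messages:
        lines.append(f"note: {msg}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Pipeline


def _stage(name: str, seed: int, n: int, started: float) -> None:
    log.info(
        "stage=%s seed=%d n=%d runtime_s=%.2f", name, seed, n, time.time() - started
    )


def run_pipeline(config: PipelineConfig, base_dir: str | Path = ".") -> dict[str, Path]:
    """Execute simulate-spectra → (simulate-data) → fit → (robustness) → render.

    Returns the paths of everything written.  Every JSON artifact carries
    the seed and the configuration hash.  Any stage failure surfaces as an
    exception labelled with the stage name.
    """
    base = Path(base_dir)
    outdir = base / config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config.config_hash()}
    paths: dict[str, Path] = {}

    # --- spectra
    t0 = time.time()
    try:
        if config.spectra_csv is not None:
            spectra = read_spectra_csv(base / config.spectra_csv)
        else:
            qualities = (
                tuple(config.kinetics.tracks) if config.kinetics else
                tuple(q.label for q in DEFAULT_QUALITIES)
            )
            g = config.geometry
            spectra = {
                q: estimate_cluster_spectrum(
                    q,
                    g.pop_model(),
                    g.pattern(),
                    g.beam(),
                    g.delivery(),
                    g.proximity_radius_um,
                    g.n_nuclei,
                    seed=config.seed + i,
                )
                for i, q in enumerate(qualities)
            }
        paths["spectra"] = outdir / "spectra.csv"
        write_spectra_csv(spectra, paths["spectra"])
    except Exception as exc:
        raise RuntimeError(f"stage 'spectra' failed: {exc}") from exc
    _stage("spectra", config.seed, sum(s.n_nuclei for s in spectra.values()), t0)

    # --- data
    t0 = time.time()
    try:
        if config.datasets_csv is not None:
            datasets = read_datasets_csv(base / config.datasets_csv)
        else:
            params = config.kinetics.params()
            design = config.design.design(tuple(config.kinetics.tracks))
            datasets = generate_tables(design, params, spectra, seed=config.seed)
            obs = generate_observations(design, params, spectra, seed=config.seed + 1)
            paths["per_nucleus"] = outdir / "per_nucleus.csv"
            obs.to_csv(paths["per_nucleus"], index=False)
        paths["datasets"] = outdir / "datasets.csv"
        write_datasets_csv(datasets, paths["datasets"])
    except Exception as exc:
        raise RuntimeError(f"stage 'data' failed: {exc}") from exc
    _stage("data", config.seed, sum(len(d) for d in datasets.values()), t0)

    # --- fit
    t0 = time.time()
    try:
        fit_inputs = [
            d for q, d in datasets.items() if q not in (CONTROL,)
        ]
        fit = simultaneous_fit(
            fit_inputs,
            spectra,
            config.fit.options(),
            n_random_starts=config.fit.n_random_starts,
            seed=config.seed,
        )
        report_df = render_report(fit)
        paths["report_csv"] = outdir / "fit_report.csv"
        report_df.to_csv(paths["report_csv"], index=False)
        payload = {
            **stamp,
            "estimates": fit.estimates,
            "se_scaled": fit.se_scaled,
            "se_unscaled": fit.se_unscaled,
            "chi2": fit.chi2,
            "dof": fit.dof,
            "chi2_per_dof": fit.chi2_per_dof,
            "options": vars(fit.options),
            "messages": fit.messages,
        }
        paths["report_json"] = outdir / "fit_report.json"
        paths["report_json"].write_text(json.dumps(payload, indent=2))
        paths["report_txt"] = outdir / "fit_report.txt"
        paths["report_txt"].write_text(format_report(fit) + "\n")
    except Exception as exc:
        raise RuntimeError(f"stage 'fit' failed: {exc}") from exc
    _stage("fit", config.seed, fit.n_points, t0)

    # --- robustness
    if config.robustness.enabled:
        t0 = time.time()
        try:
            fit_datasets = [d for q, d in datasets.items() if q != CONTROL]
            variants = variant_sweep(
                fit_datasets,
                spectra,
                n_random_starts=config.robustness.n_random_starts,
                seed=config.seed,
            )
            g = config.geometry or GeometryConfig()
            batches = [
                {
                    q: estimate_cluster_spectrum(
                        q,
                        g.pop_model(),
                        g.pattern(),
                        g.beam(),
                        g.delivery(),
                        g.proximity_radius_um,
                        config.robustness.n_nuclei_per_batch,
                        seed=config.seed + 1000 + b * len(spectra) + i,
                    )
                    for i, q in enumerate(spectra)
                }
                for b in range(config.robustness.n_batches)
            ]
            batch_rep = spectrum_batch_sweep(
                fit_datasets, batches, config.fit.options(), base_fit=fit
            )
            payload = {
                **stamp,
                "variant_ranges": {
                    k: list(v) for k, v in variants.parameter_ranges.items()
                },
                "variant_failures": variants.failures,
                "batch_spread": batch_rep.parameter_spread,
                "batch_spread_to_se": batch_rep.spread_to_se,
            }
            paths["robustness_json"] = outdir / "robustness.json"
            paths["robustness_json"].write_text(json.dumps(payload, indent=2))
            if variants.envelope is not None:
                paths["envelope_csv"] = outdir / "envelope.csv"
                variants.envelope.to_csv(paths["envelope_csv"], index=False)
        except Exception as exc:
            raise RuntimeError(f"stage 'robustness' failed: {exc}") from exc
        _stage("robustness", config.seed, len(batches), t0)

    paths["run_json"] = outdir / "run.json"
    paths["run_json"].write_text(json.dumps(stamp, indent=2))
    return paths
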