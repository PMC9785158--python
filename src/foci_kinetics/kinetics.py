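"""Two-class first-order repair kinetics of radiation-induced foci.

The mean number of 53BP1 foci per nucleus observed at time t after
irradiation with quality Q is modelled as

    m_Q(t) = m_s(t) + m_r,Q(t)

with a sham/background term

    m_s(t) = n̄_b + n̄_s · exp(−β0 (t − t_M))

and a radiation term summed over track-cluster sizes

    m_r,Q(t) = Σ_n  k̄_Q(n) · P_Q(t | n).

P_Q(t|n) is the probability that the location of an n-track cluster still
shows at least one focus at time t.  Foci per track are Poisson with mean
n̄_Q at the reference time t_M = 0.5 h (the post-irradiation maximum); a
fraction p_Q of them is persistent and is repaired at rate β2, the rest at
rate β1, so a focus created at t_M survives to t with probability
s(t) = (1−p_Q) e^{−β1 Δ} + p_Q e^{−β2 Δ}, Δ = t − t_M.  By Poisson thinning
the surviving foci in an n-track cluster are Poisson(n·n̄_Q·s(t)) and

    P_Q(t|n) = 1 − exp(−n · n̄_Q · [(1−p_Q) e^{−β1 Δ} + p_Q e^{−β2 Δ}])     (fraction form)
             = 1 − exp(−n · [(n̄_Q − p̄_Q) e^{−β1 Δ} + p̄_Q e^{−β2 Δ}])      (mean-number form)

where p̄_Q = n̄_Q p_Q is the mean number of persistent foci per track.  The
two forms are algebraically identical; they differ only as fitting
parameterizations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import ClusterSpectrum

__all__ = [
    "TrackParams",
    "KineticsParams",
    "ModelOptions",
    "ParameterError",
    "sham_mean",
    "cluster_focus_prob",
    "radiation_mean",
    "total_mean",
    "reparameterize",
    "persistent_mean_from_fraction",
    "persistent_fraction_from_mean",
]

T_REF_DEFAULT = 0.5  # hours; time of the post-irradiation focus maximum


class ParameterError(ValueError):
    """Kinetic parameters outside their admissible domain."""


@dataclass(frozen=True)
class ModelOptions:
    """Model-variant switches used throughout fitting and robustness sweeps.

    parameterization
        ``"fraction"`` fits (n̄_Q, p_Q); ``"mean-number"`` fits (n̄_Q, p̄_Q).
    beta0_equals_beta1
        Tie the sham repair rate to the normal-RIF repair rate.
    beta2_zero
        Fix the persistent-focus repair rate to 0 (truly persistent foci).
    per_quality_beta1
        Let the normal-RIF repair rate differ between radiation qualities.
    """

    parameterization: str = "fraction"
    beta0_equals_beta1: bool = False
    beta2_zero: bool = False
    per_quality_beta1: bool = False

    def __post_init__(self) -> None:
        if self.parameterization not in ("fraction", "mean-number"):
            raise ParameterError(
                "parameterization must be 'fraction' or 'mean-number'"
            )


@dataclass(frozen=True)
class TrackParams:
    """Per-quality track parameters at the reference time.

    ``n_track`` is n̄_Q, the mean number of foci formed along one ion track
    inside the nucleus at t_M.  Exactly one of ``p_persistent`` (p_Q) or
    ``persistent_mean`` (p̄_Q) may be given; the other is derived on demand.
    ``beta1`` optionally overrides the shared normal-repair rate for this
    quality (per-quality-β1 fit variant).
    """

    n_track: float
    p_persistent: float | None = None
    persistent_mean: float | None = None
    beta1: float | None = None

    def __post_init__(self) -> None:
        if self.n_track < 0:
            raise ParameterError("n_track must be >= 0")
        if self.p_persistent is None and self.persistent_mean is None:
            object.__setattr__(self, "p_persistent", 0.0)
        if self.p_persistent is not None and not (0.0 <= self.p_persistent <= 1.0):
            raise ParameterError("p_persistent must lie in [0, 1]")
        if self.persistent_mean is not None and self.persistent_mean < 0:
            raise ParameterError("persistent_mean must be >= 0")

    def fraction(self, check: bool = True) -> float:
        """p_Q, deriving it from p̄_Q if needed."""
        if self.p_persistent is not None:
            return self.p_persistent
        pbar = self.persistent_mean
        if self.n_track == 0:
            if pbar > 0:
                raise ParameterError(
                    "persistent_mean > 0 with n_track = 0 has no fraction form"
                )
            return 0.0
        p = pbar / self.n_track
        if check and p > 1.0 + 1e-12:
            raise ParameterError("persistent_mean exceeds n_track")
        return p

    def mean_persistent(self, check: bool = True) -> float:
        """p̄_Q, deriving it from p_Q if needed."""
        if self.persistent_mean is not None:
            if check and self.persistent_mean > self.n_track + 1e-12:
                raise ParameterError("persistent_mean exceeds n_track")
            return self.persistent_mean
        return self.n_track * self.p_persistent


@dataclass(frozen=True)
class KineticsParams:
    """Full parameter set of the kinetic model.

    Units: focus counts are per nucleus (n̄_b, n̄_s) or per track (n̄_Q,
    p̄_Q); repair rates β0, β1, β2 are in h⁻¹; t_ref is in hours.
    """

    n_background: float
    n_sham: float
    beta0: float
    beta1: float
    beta2: float
    tracks: dict[str, TrackParams] = field(default_factory=dict)
    t_ref: float = T_REF_DEFAULT

    def __post_init__(self) -> None:
        for name in ("n_background", "n_sham", "beta0", "beta1", "beta2"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.beta2 > self.beta1:
            warnings.warn(
                "beta2 > beta1: the 'persistent' class repairs faster than the "
                "normal class; parameters are admissible but the class labels "
                "are swapped",
                stacklevel=2,
            )

    def track(self, quality: str) -> TrackParams:
        try:
            return self.tracks[quality]
        except KeyError:
            raise ParameterError(f"no track parameters for quality {quality!r}")

    def beta1_for(self, quality: str) -> float:
        tp = self.track(quality)
        return tp.beta1 if tp.beta1 is not None else self.beta1


def _delta(t, t_ref: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < t_ref - 1e-12):
        raise ParameterError(
            f"model is defined for t >= t_ref = {t_ref} h (the focus maximum); "
            f"got t = {t}"
        )
    return t - t_ref


def sham_mean(t, params: KineticsParams):
    """Mean foci per nucleus in sham-irradiated cells at time t (hours).

    n̄_b + n̄_s exp(−β0 (t − t_ref)): a constant background plus an
    exponentially repaired component induced by the staining/illumination of
    the nucleus-recognition step.
    """
    d = _delta(t, params.t_ref)
    out = params.n_background + params.n_sham * np.exp(-params.beta0 * d)
    return out if out.ndim else float(out)


def cluster_focus_prob(
    t,
    n_i: int,
    params: KineticsParams,
    quality: str,
    options: ModelOptions = ModelOptions(),
    check: bool = True,
):
    """Probability that an n_i-track cluster still shows a focus at time t.

    Evaluates the fraction or mean-number form according to
    ``options.parameterization``; the forms coincide when p̄_Q = n̄_Q p_Q.
    With ``check=False`` the mean-number form is evaluated even when
    p̄_Q > n̄_Q (needed transiently inside box-bounded optimisation).
    """
    if n_i < 1 or int(n_i) != n_i:
        raise ParameterError("cluster size n_i must be a positive integer")
    tp = params.track(quality)
    b1 = params.beta1_for(quality)
    b2 = params.beta2
    d = _delta(t, params.t_ref)
    e1 = np.exp(-b1 * d)
    e2 = np.exp(-b2 * d)
    if options.parameterization == "fraction":
        p = tp.fraction(check=check)
        expo = n_i * tp.n_track * ((1.0 - p) * e1 + p * e2)
    else:
        pbar = tp.mean_persistent(check=check)
        expo = n_i * ((tp.n_track - pbar) * e1 + pbar * e2)
    out = 1.0 - np.exp(-expo)
    return out if np.ndim(out) else float(out)


def radiation_mean(
    t,
    spectrum: ClusterSpectrum,
    params: KineticsParams,
    options: ModelOptions = ModelOptions(),
    check: bool = True,
):
    """Mean radiation-induced foci per nucleus: Σₙ k̄_Q(n) P_Q(t|n)."""
    q = spectrum.quality
    total = np.zeros_like(_delta(t, params.t_ref))
    for n, k in spectrum.k_bar.items():
        if k == 0.0:
            continue
        total = total + k * cluster_focus_prob(t, n, params, q, options, check=check)
    return total if total.ndim else float(total)


def total_mean(
    t,
    quality: str,
    spectrum: ClusterSpectrum,
    params: KineticsParams,
    options: ModelOptions = ModelOptions(),
    check: bool = True,
):
    """Mean observed foci per nucleus at time t: sham term plus radiation term.

    Additivity reflects the assumption that radiation-induced foci and foci
    of non-radiation origin occur statistically independently.
    """
    if spectrum.quality != quality:
        raise ParameterError(
            f"spectrum is for quality {spectrum.quality!r}, not {quality!r}"
        )
    return sham_mean(t, params) + radiation_mean(t, spectrum, params, options, check)


def persistent_mean_from_fraction(n_track: float, p_persistent: float) -> float:
    """p̄_Q = n̄_Q · p_Q."""
    if n_track < 0 or not (0.0 <= p_persistent <= 1.0):
        raise ParameterError("require n_track >= 0 and 0 <= p_persistent <= 1")
    return n_track * p_persistent


def persistent_fraction_from_mean(n_track: float, persistent_mean: float) -> float:
    """p_Q = p̄_Q / n̄_Q (error when n̄_Q = 0 with p̄_Q > 0)."""
    if persistent_mean < 0:
        raise ParameterError("persistent_mean must be >= 0")
    if n_track == 0:
        if persistent_mean > 0:
            raise ParameterError("cannot form a fraction with n_track = 0")
        return 0.0
    return persistent_mean / n_track


def reparameterize(params: KineticsParams, direction: str) -> KineticsParams:
    """Convert every quality between the (n̄_Q, p_Q) and (n̄_Q, p̄_Q) forms.

    ``direction`` is ``"to-mean"`` (fill p̄_Q = n̄_Q p_Q) or ``"to-fraction"``
    (fill p_Q = p̄_Q / n̄_Q).  The round trip is the identity.
    """
    if direction not in ("to-mean", "to-fraction"):
        raise ParameterError("direction must be 'to-mean' or 'to-fraction'")
    new_tracks = {}
    for q, tp in params.tracks.items():
        if direction == "to-mean":
            pbar = tp.mean_persistent()
            new_tracks[q] = replace(
                tp, persistent_mean=pbar, p_persistent=None
            )
        else:
            p = tp.fraction()
            new_tracks[q] = replace(tp, p_persistent=p, persistent_mean=None)
    return replace(params, tracks=new_tracks)
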