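"""Monte Carlo model of the targeted microbeam irradiation geometry.

Each cell nucleus is targeted with five single ions aimed at the corners and
the centre of a 4 µm square whose orientation is fixed in the lab frame.  The
actual traversal points scatter about the targets with the beam's Gaussian
spread (4 µm FWHM), and the single-ion counter can miscount: a registered ion
occasionally corresponds to zero or two real ions.  Nuclei are modelled as
ellipses with randomly sampled half-axes and orientation.  Tracks that cross
the nucleus close together produce foci that cannot be resolved as separate;
such tracks are grouped into "clusters" by single-linkage on planar distance.

The quantity this module estimates is the cluster spectrum k̄(n): the mean
number, per nucleus, of clusters made of n tracks.  The spectrum is the fixed
geometric input of the kinetic model; everything downstream (the probability
that a cluster still shows a focus at time t) is in :mod:`.kinetics`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.random import Generator, default_rng

__all__ = [
    "TargetPattern",
    "BeamProfile",
    "IonDeliveryModel",
    "NucleusGeometry",
    "NucleusPopulationModel",
    "ClusterSpectrum",
    "sample_nucleus",
    "sample_ion_positions",
    "cluster_tracks",
    "estimate_cluster_spectrum",
    "batch_spectra",
    "spectra_cv",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class ConfigurationError(ValueError):
    """Invalid geometry/beam/population configuration."""


def _as_rng(rng: Generator | int | None) -> Generator:
    if isinstance(rng, Generator):
        return rng
    return default_rng(rng)


@dataclass(frozen=True)
class TargetPattern:
    """Aim points of the microbeam within one nucleus (µm, lab frame)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ConfigurationError("pattern points must be an (k, 2) array")
        object.__setattr__(self, "points", pts)

    @classmethod
    def square_with_center(cls, side: float = 4.0) -> "TargetPattern":
        """Four corners plus centre of a square of the given side (default 4 µm)."""
        if side <= 0:
            raise ConfigurationError("pattern side must be positive")
        h = side / 2.0
        pts = [(-h, -h), (-h, h), (h, -h), (h, h), (0.0, 0.0)]
        return cls(np.array(pts))

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class BeamProfile:
    """Isotropic 2-D Gaussian scatter of the traversal about the aim point.

    ``fwhm`` is in µm; ``sigma = fwhm / (2 sqrt(2 ln 2))``.  ``fwhm = 0`` is
    an ideal beam (useful for analytic limits).
    """

    fwhm: float = 4.0

    def __post_init__(self) -> None:
        if self.fwhm < 0:
            raise ConfigurationError("beam fwhm must be >= 0")

    @property
    def sigma(self) -> float:
        return self.fwhm * _FWHM_TO_SIGMA


@dataclass(frozen=True)
class IonDeliveryModel:
    """Miscounting of the single-ion detector.

    A registered ion corresponds to 0, 1 or 2 actual ions with
    probabilities ``p0``, ``p1``, ``p2`` (summing to 1).
    """

    p0: float = 0.05
    p1: float = 0.90
    p2: float = 0.05

    def __post_init__(self) -> None:
        probs = (self.p0, self.p1, self.p2)
        if any(p < 0 for p in probs):
            raise ConfigurationError("delivery probabilities must be >= 0")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigurationError("delivery probabilities must sum to 1")

    @property
    def mean_ions(self) -> float:
        """Expected actual ions per registered ion."""
        return self.p1 + 2.0 * self.p2

    def sample(self, rng: Generator, size) -> np.ndarray:
        """Draw ion multiplicities in {0, 1, 2}."""
        cum = np.array([self.p0, self.p0 + self.p1])
        return np.searchsorted(cum, rng.random(size), side="right")


@dataclass(frozen=True)
class NucleusGeometry:
    """Elliptical nucleus cross-section: half-axes a >= b (µm), orientation (rad)."""

    a: float
    b: float
    orientation: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ConfigurationError("require a >= b > 0 for nucleus half-axes")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points (k, 2) inside the ellipse (boundary included)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        dx = pts[:, 0] - self.center[0]
        dy = pts[:, 1] - self.center[1]
        ct, st = math.cos(self.orientation), math.sin(self.orientation)
        u = ct * dx + st * dy
        v = -st * dx + ct * dy
        return (u / self.a) ** 2 + (v / self.b) ** 2 <= 1.0


@dataclass(frozen=True)
class NucleusPopulationModel:
    """Bivariate-normal population of nucleus half-axes.

    The long/short half-axes ``(a, b)`` are drawn from a bivariate normal
    specified in principal-component form: independent normal deviates with
    standard deviations ``pc_sd_major`` and ``pc_sd_minor`` are rotated by
    ``pc_angle`` (which induces the a–b correlation) and shifted by the
    means.  Samples are rejected until ``a >= b > min_half_axis``; nucleus
    orientation is uniform on [0, π).
    """

    mean_a: float = 8.0
    mean_b: float = 5.0
    pc_sd_major: float = 2.0
    pc_sd_minor: float = 1.0
    pc_angle: float = 0.0
    min_half_axis: float = 0.5

    def __post_init__(self) -> None:
        if self.pc_sd_major < 0 or self.pc_sd_minor < 0:
            raise ConfigurationError("principal-component SDs must be >= 0")
        if self.min_half_axis <= 0:
            raise ConfigurationError("min_half_axis must be > 0")
        if not (self.mean_a >= self.mean_b):
            raise ConfigurationError("require mean_a >= mean_b")
        if self.mean_b <= self.min_half_axis:
            raise ConfigurationError(
                "mean short half-axis lies at or below the truncation bound"
            )

    def sample_axes(self, rng: Generator, size: int) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``size`` accepted (a, b) pairs by rejection."""
        ct, st = math.cos(self.pc_angle), math.sin(self.pc_angle)
        rot = np.array([[ct, -st], [st, ct]])
        sds = np.array([self.pc_sd_major, self.pc_sd_minor])
        out_a = np.empty(size)
        out_b = np.empty(size)
        filled = 0
        for _ in range(1000):
            need = size - filled
            if need == 0:
                break
            z = rng.standard_normal((max(need * 2, 16), 2)) * sds
            ab = z @ rot.T + np.array([self.mean_a, self.mean_b])
            ok = (ab[:, 0] >= ab[:, 1]) & (ab[:, 1] > self.min_half_axis)
            acc = ab[ok][:need]
            out_a[filled : filled + len(acc)] = acc[:, 0]
            out_b[filled : filled + len(acc)] = acc[:, 1]
            filled += len(acc)
        else:
            raise ConfigurationError(
                "rejection sampling of nucleus half-axes did not converge; "
                "check the population-model parameters against the truncation bound"
            )
        return out_a, out_b


def sample_nucleus(
    pop_model: NucleusPopulationModel, rng: Generator | int | None = None
) -> NucleusGeometry:
    """Draw one nucleus geometry, centred on the targeting pattern centroid.

    The microbeam targets recognised nuclei, so the pattern centroid and the
    nucleus centre coincide; only the half-axes and the in-plane orientation
    are random.
    """
    rng = _as_rng(rng)
    a, b = pop_model.sample_axes(rng, 1)
    theta = rng.uniform(0.0, math.pi)
    return NucleusGeometry(a=float(a[0]), b=float(b[0]), orientation=float(theta))


def sample_ion_positions(
    pattern: TargetPattern,
    beam: BeamProfile,
    delivery: IonDeliveryModel,
    rng: Generator | int | None = None,
) -> np.ndarray:
    """Actual ion traversal points (k, 2) for one irradiated nucleus.

    For every aim point the counter delivers 0, 1 or 2 ions; each delivered
    ion lands at the aim point plus isotropic Gaussian scatter of the beam's
    sigma.
    """
    rng = _as_rng(rng)
    mult = delivery.sample(rng, len(pattern))
    targets = np.repeat(pattern.points, mult, axis=0)
    if len(targets) == 0:
        return targets
    return targets + rng.normal(scale=beam.sigma, size=targets.shape)


def cluster_tracks(points: np.ndarray, proximity_radius: float) -> list[int]:
    """Single-linkage clustering of traversal points into unresolvable groups.

    Two tracks are connected when their planar distance is <= the proximity
    radius; clusters are the connected components of that graph.  Returns the
    cluster sizes (a partition of the input count), in no particular order.
    """
    if proximity_radius <= 0:
        raise ConfigurationError("proximity_radius must be > 0")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = 0 if pts.size == 0 else len(pts)
    if n == 0:
        return []
    # union-find over the <= radius adjacency; n is at most ~10 here
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    r2 = proximity_radius * proximity_radius
    for i in range(n):
        for j in range(i + 1, n):
            if d2[i, j] <= r2:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    sizes: dict[int, int] = {}
    for i in range(n):
        r = find(i)
        sizes[r] = sizes.get(r, 0) + 1
    return list(sizes.values())


@dataclass
class ClusterSpectrum:
    """Mean per-nucleus counts of n-track clusters for one radiation quality.

    ``k_bar[n]`` is the mean number of clusters of exactly n tracks per
    nucleus; ``mean_tracks`` is the independently tallied mean number of
    in-nucleus tracks, kept for the conservation check
    Σₙ n·k̄(n) == mean_tracks.
    """

    quality: str
    k_bar: dict[int, float]
    n_nuclei: int
    seed: int | None = None
    mean_tracks: float | None = None

    def __post_init__(self) -> None:
        if any(k < 0 for k in self.k_bar.values()):
            raise ConfigurationError("cluster frequencies must be >= 0")

    @property
    def sizes(self) -> list[int]:
        return sorted(self.k_bar)

    @property
    def track_weighted_sum(self) -> float:
        """Σₙ n·k̄(n): mean in-nucleus tracks implied by the spectrum."""
        return float(sum(n * k for n, k in self.k_bar.items()))


def _simulate_cluster_counts(
    pop_model: NucleusPopulationModel,
    pattern: TargetPattern,
    beam: BeamProfile,
    delivery: IonDeliveryModel,
    proximity_radius: float,
    n_nuclei: int,
    rng: Generator,
) -> tuple[dict[int, int], int]:
    """Tally cluster sizes over ``n_nuclei`` simulated irradiations.

    Returns (counts per size, total in-nucleus tracks) where the track total
    is tallied independently of the clustering.
    """
    k = len(pattern)
    a, b = pop_model.sample_axes(rng, n_nuclei)
    theta = rng.uniform(0.0, math.pi, size=n_nuclei)
    mult = delivery.sample(rng, (n_nuclei, k))
    per_nucleus = mult.sum(axis=1)
    targets = np.repeat(
        np.tile(pattern.points, (n_nuclei, 1)), mult.reshape(-1), axis=0
    )
    if beam.sigma > 0 and len(targets):
        pts = targets + rng.normal(scale=beam.sigma, size=targets.shape)
    else:
        pts = targets
    idx = np.repeat(np.arange(n_nuclei), per_nucleus)
    ct, st = np.cos(theta[idx]), np.sin(theta[idx])
    u = ct * pts[:, 0] + st * pts[:, 1]
    v = -st * pts[:, 0] + ct * pts[:, 1]
    inside = (u / a[idx]) ** 2 + (v / b[idx]) ** 2 <= 1.0

    tally: dict[int, int] = {}
    total_tracks = int(np.count_nonzero(inside))
    bounds = np.concatenate([[0], np.cumsum(per_nucleus)])
    for i in range(n_nuclei):
        sl = slice(bounds[i], bounds[i + 1])
        sub = pts[sl][inside[sl]]
        if len(sub) == 0:
            continue
        for size in cluster_tracks(sub, proximity_radius):
            tally[size] = tally.get(size, 0) + 1
    return tally, total_tracks


def estimate_cluster_spectrum(
    quality: str,
    pop_model: NucleusPopulationModel | None = None,
    pattern: TargetPattern | None = None,
    beam: BeamProfile | None = None,
    delivery: IonDeliveryModel | None = None,
    proximity_radius: float = 2.0,
    n_nuclei: int = 1000,
    seed: int | None = None,
    rng: Generator | None = None,
) -> ClusterSpectrum:
    """Estimate the cluster spectrum k̄(n) by simulating ``n_nuclei`` irradiations.

    Per nucleus: sample the elliptical geometry, deliver the (possibly
    miscounted) ions with beam scatter, keep traversals inside the ellipse,
    and single-linkage cluster them; k̄(n) is the total count of n-track
    clusters divided by the number of nuclei.
    """
    if n_nuclei < 1:
        raise ConfigurationError("n_nuclei must be >= 1")
    pop_model = pop_model or NucleusPopulationModel()
    pattern = pattern or TargetPattern.square_with_center()
    beam = beam or BeamProfile()
    delivery = delivery or IonDeliveryModel()
    if rng is None:
        rng = default_rng(seed)
    tally, total_tracks = _simulate_cluster_counts(
        pop_model, pattern, beam, delivery, proximity_radius, n_nuclei, rng
    )
    k_bar = {n: c / n_nuclei for n, c in sorted(tally.items())}
    return ClusterSpectrum(
        quality=quality,
        k_bar=k_bar,
        n_nuclei=n_nuclei,
        seed=seed,
        mean_tracks=total_tracks / n_nuclei,
    )


def batch_spectra(
    quality: str,
    pop_model: NucleusPopulationModel | None = None,
    pattern: TargetPattern | None = None,
    beam: BeamProfile | None = None,
    delivery: IonDeliveryModel | None = None,
    proximity_radius: float = 2.0,
    n_batches: int = 100,
    n_nuclei_per_batch: int = 1000,
    seed: int | None = None,
) -> list[ClusterSpectrum]:
    """Independent spectrum estimates for propagating simulation scatter.

    Each batch re-simulates ``n_nuclei_per_batch`` nuclei with its own
    sub-seed derived from ``seed``; the spread of k̄(n) across batches (see
    :func:`spectra_cv`) measures how much the fixed geometric input of the
    regression fluctuates.
    """
    if n_batches < 1:
        raise ConfigurationError("n_batches must be >= 1")
    master = default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n_batches)
    return [
        estimate_cluster_spectrum(
            quality,
            pop_model,
            pattern,
            beam,
            delivery,
            proximity_radius,
            n_nuclei_per_batch,
            seed=int(s),
        )
        for s in child_seeds
    ]


def spectra_cv(spectra: list[ClusterSpectrum]) -> dict[int, float]:
    """Coefficient of variation of k̄(n) across batch spectra, per size n."""
    sizes = sorted({n for s in spectra for n in s.k_bar})
    out: dict[int, float] = {}
    for n in sizes:
        vals = np.array([s.k_bar.get(n, 0.0) for s in spectra])
        mean = vals.mean()
        out[n] = float(vals.std(ddof=1) / mean) if mean > 0 else float("nan")
    return out
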