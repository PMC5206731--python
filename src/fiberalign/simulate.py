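"""In-silico fiber configurations for validating the alignment analysis.

Two generators:

- :func:`simulate_uniform` — straight fibers scattered uniformly over a
  square box, all sharing a base orientation perturbed by Gaussian angular
  noise.  The closed-form expectation of the alignment length for noise
  std σ (radians) is exp(−2σ²), which the generator is tested against.
- :func:`simulate_radial` — straight fibers radially aligned (normal) to a
  circular tumor boundary occupying a quarter disk at a box corner.  Fiber
  midpoints are uniform over the quarter annulus between the tumor radius
  and an outer radius (default: the box size, i.e. the largest quarter
  circle the box holds), with both endpoints kept inside the box and the
  annulus.  On this geometry the *global* alignment at zero noise is
  ≈ 2/π ≈ 0.64 pointing along the 45° diagonal, while small local circles
  see near-perfect order — the heterogeneity the local method resolves.

All randomness flows from ``numpy.random.default_rng(seed)``; identical
configs produce bit-identical fiber lists.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .circular import alignment_vector, axial_mean, axial_std
from .errors import ConfigError, DomainError
from .field import CircularBoundary
from .geometry import FiberPath, quantize_all

_MAX_BATCHES = 1000  # rejection-sampling safety valve

DEFAULT_FILTER_LENGTH = 5.0


@dataclass(frozen=True)
class UniformSimConfig:
    """Uniformly placed fibers with Gaussian angular perturbation.

    Defaults are the reference validation conditions: 100 fibers of length
    40 px in a 512×512 box, vertical (90°) base orientation.
    """

    box_size: float = 512.0
    n_fibers: int = 100
    fiber_length: float = 40.0
    base_angle: float = 90.0
    noise_std: float = 0.0  # degrees
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fibers < 1:
            raise ConfigError("n_fibers must be >= 1")
        if not (0 < self.fiber_length <= self.box_size):
            raise ConfigError("need 0 < fiber_length <= box_size")
        if self.noise_std < 0:
            raise ConfigError("noise_std must be >= 0")
        if not (0 <= self.base_angle < 180):
            raise DomainError("base_angle must lie in [0, 180)")


@dataclass(frozen=True)
class RadialSimConfig:
    """Fibers radially aligned to a quarter-disk tumor boundary at a corner.

    ``boundary`` defaults to a quarter disk of radius 150 px anchored at the
    bottom-left box corner (0, box_size) in image coordinates, so radial
    directions span 0°–90°.  ``outer_radius`` (default: box_size) caps fiber
    midpoints and endpoints at the largest quarter circle the box contains.
    Defaults follow the reference validation conditions: 500 fibers of
    length 40 px in a 512×512 box.
    """

    box_size: float = 512.0
    n_fibers: int = 500
    fiber_length: float = 40.0
    boundary: Optional[CircularBoundary] = None
    outer_radius: Optional[float] = None
    noise_std: float = 0.0  # degrees
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary is None:
            object.__setattr__(
                self, "boundary", CircularBoundary((0.0, self.box_size), 150.0)
            )
        if self.outer_radius is None:
            object.__setattr__(self, "outer_radius", float(self.box_size))
        if self.n_fibers < 1:
            raise ConfigError("n_fibers must be >= 1")
        if not (0 < self.fiber_length <= self.box_size):
            raise ConfigError("need 0 < fiber_length <= box_size")
        if self.noise_std < 0:
            raise ConfigError("noise_std must be >= 0")
        cx, cy = self.boundary.center
        corners = {(0.0, 0.0), (0.0, self.box_size), (self.box_size, 0.0),
                   (self.box_size, self.box_size)}
        if (float(cx), float(cy)) not in corners:
            raise ConfigError("radial boundary center must sit at a box corner")
        if self.outer_radius - self.boundary.radius <= self.fiber_length:
            raise ConfigError("annulus too thin for the fiber length")


def _fiber_endpoints(mid: np.ndarray, angles_deg: np.ndarray, length: float):
    """Endpoints of straight fibers with given midpoints and axial angles."""
    rad = np.radians(angles_deg)
    # image convention: y axis points down, so a +angle tilts dy negative
    d = 0.5 * length * np.column_stack([np.cos(rad), -np.sin(rad)])
    return mid - d, mid + d


def _inside_box(p: np.ndarray, box: float) -> np.ndarray:
    return (p >= 0.0).all(axis=1) & (p <= box).all(axis=1)


def _make_fibers(e1: np.ndarray, e2: np.ndarray) -> List[FiberPath]:
    return [
        FiberPath(i, np.array([e1[i], e2[i]]))
        for i in range(len(e1))
    ]


def simulate_uniform(config: UniformSimConfig) -> List[FiberPath]:
    """Generate straight fibers with uniform midpoints and noisy orientation.

    Each fiber's axial angle is ``base_angle + ε`` with ε ~ N(0, noise_std),
    wrapped into [0, 180); midpoints are uniform over the box and candidates
    are rejected until both endpoints lie inside the box.
    """
    rng = np.random.default_rng(config.seed)
    acc_e1, acc_e2 = [], []
    need = config.n_fibers
    for _ in range(_MAX_BATCHES):
        m = rng.uniform(0.0, config.box_size, size=(max(2 * need, 64), 2))
        ang = (config.base_angle + rng.normal(0.0, config.noise_std, len(m))) % 180.0
        e1, e2 = _fiber_endpoints(m, ang, config.fiber_length)
        ok = _inside_box(e1, config.box_size) & _inside_box(e2, config.box_size)
        acc_e1.append(e1[ok])
        acc_e2.append(e2[ok])
        need = config.n_fibers - sum(len(a) for a in acc_e1)
        if need <= 0:
            break
    else:
        raise ConfigError("uniform simulation: rejection sampling did not converge")
    e1 = np.concatenate(acc_e1)[: config.n_fibers]
    e2 = np.concatenate(acc_e2)[: config.n_fibers]
    return _make_fibers(e1, e2)


def simulate_radial(config: RadialSimConfig) -> List[FiberPath]:
    """Generate straight fibers normal to a quarter-circle tumor boundary.

    Midpoints are uniform over the quarter annulus between the tumor radius
    and ``outer_radius``; each fiber's axial angle is the radial direction
    from the boundary center to its midpoint plus Gaussian noise, wrapped
    into [0, 180).  Candidates are rejected until both endpoints lie inside
    the box and the annulus (outside the tumor disk, inside the outer
    circle), so every fiber sits in the fiber-bearing region.
    """
    rng = np.random.default_rng(config.seed)
    cx, cy = config.boundary.center
    rt, ro = config.boundary.radius, config.outer_radius
    acc_e1, acc_e2 = [], []
    need = config.n_fibers
    for _ in range(_MAX_BATCHES):
        m = rng.uniform(0.0, config.box_size, size=(max(4 * need, 64), 2))
        r_mid = np.hypot(m[:, 0] - cx, m[:, 1] - cy)
        in_ann = (r_mid > rt) & (r_mid <= ro)
        m = m[in_ann]
        radial = np.degrees(np.arctan2(-(m[:, 1] - cy), m[:, 0] - cx)) % 180.0
        ang = (radial + rng.normal(0.0, config.noise_std, len(m))) % 180.0
        e1, e2 = _fiber_endpoints(m, ang, config.fiber_length)
        ok = _inside_box(e1, config.box_size) & _inside_box(e2, config.box_size)
        for e in (e1, e2):
            re = np.hypot(e[:, 0] - cx, e[:, 1] - cy)
            ok &= (re >= rt) & (re <= ro)
        acc_e1.append(e1[ok])
        acc_e2.append(e2[ok])
        need = config.n_fibers - sum(len(a) for a in acc_e1)
        if need <= 0:
            break
    else:
        raise ConfigError("radial simulation: rejection sampling did not converge")
    e1 = np.concatenate(acc_e1)[: config.n_fibers]
    e2 = np.concatenate(acc_e2)[: config.n_fibers]
    return _make_fibers(e1, e2)


def radial_demo_circles(
    boundary: CircularBoundary,
    radius: float = 50.0,
    offsets: Sequence[float] = (60.0, 160.0),
    azimuths: Sequence[float] = (11.25, 33.75, 56.25, 78.75),
) -> List[Tuple[Tuple[float, float], float]]:
    """Local sampling circles for the radial demonstration geometry.

    Circle centers sit on concentric arcs around the tumor center at
    distances ``boundary.radius + offset`` and the given azimuths (degrees,
    measured in the axial convention).  Returns [(center, radius), ...].
    """
    cx, cy = boundary.center
    out = []
    for off in offsets:
        d = boundary.radius + off
        for az in azimuths:
            a = np.radians(az)
            out.append(((cx + d * np.cos(a), cy - d * np.sin(a)), radius))
    return out


SimConfig = Union[UniformSimConfig, RadialSimConfig]


def _simulate(config: SimConfig) -> List[FiberPath]:
    if isinstance(config, UniformSimConfig):
        return simulate_uniform(config)
    if isinstance(config, RadialSimConfig):
        return simulate_radial(config)
    raise ConfigError(f"unknown simulation config type {type(config).__name__}")


def _stat_alignment_length(fibers: List[FiberPath]) -> float:
    segs = quantize_all(fibers, DEFAULT_FILTER_LENGTH)
    return alignment_vector([s.angle for s in segs]).length


def _stat_alignment_angle(fibers: List[FiberPath]) -> float:
    segs = quantize_all(fibers, DEFAULT_FILTER_LENGTH)
    vec = alignment_vector([s.angle for s in segs])
    if vec.axial_angle is None:
        raise DomainError("alignment angle undefined (zero-length vector)")
    return vec.axial_angle


STATISTICS: dict = {
    "alignment_length": _stat_alignment_length,
    "alignment_angle": _stat_alignment_angle,
}


@dataclass(frozen=True)
class ReplicaResult:
    """Per-replica statistic values with their mean and standard deviation."""

    statistic: str
    values: np.ndarray
    mean: float
    std: float

    @property
    def stderr(self) -> float:
        """Standard error of the replica mean: std / sqrt(n_replicas)."""
        return float(self.std / np.sqrt(len(self.values)))


def replicate(
    config: SimConfig,
    n_replicas: int,
    statistic: Union[str, Callable[[List[FiberPath]], float]],
) -> ReplicaResult:
    """Run independent simulation replicas and summarize one statistic.

    Replica ``i`` uses ``seed = config.seed + i``.  ``statistic`` is a name
    from :data:`STATISTICS` (``"alignment_length"``, ``"alignment_angle"``)
    or any callable mapping a fiber list to a float.  Angle statistics are
    averaged with the axial circular mean (double, average vectors, halve)
    and spread with the corresponding circular standard deviation, since
    arithmetic means fail near the 0°/180° wrap.
    """
    if n_replicas < 1:
        raise ConfigError("n_replicas must be >= 1")
    if callable(statistic):
        fn, name, angular = statistic, getattr(statistic, "__name__", "custom"), False
    else:
        if statistic not in STATISTICS:
            raise ConfigError(
                f"unknown statistic {statistic!r}; known: {sorted(STATISTICS)}"
            )
        fn, name = STATISTICS[statistic], statistic
        angular = statistic == "alignment_angle"
    values = np.array(
        [fn(_simulate(replace(config, seed=config.seed + i))) for i in range(n_replicas)]
    )
    if angular:
        mean, _ = axial_mean(values)
        std = axial_std(values)
        if std == float("inf") or mean is None:
            raise DomainError("replica angles have no defined circular mean")
    else:
        mean = float(values.mean())
        std = float(values.std(ddof=1)) if n_replicas > 1 else 0.0
    return ReplicaResult(name, values, float(mean), float(std))
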