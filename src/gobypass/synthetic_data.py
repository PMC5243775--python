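"""Synthetic cohorts, assay recordings and flow profiles.

Because the study system's individual-level data were never deposited,
every downstream stage is exercised on generated data with the same
statistical structure: total lengths from a truncated normal on the
observed 7.3-15.3 cm range with mean 9.9 cm; the three personality
indices from a correlated trivariate normal on the index scale (the
indices are already log-type transforms and their distributions were
checked to be roughly symmetric), truncated at zero where an index is
nonnegative by construction; invasion-front trait means sit at the
published thresholds (boldness 1.13, activity 1.17, asociability 0.95)
and invasion-center means one effect-size unit lower.  Trait
intracorrelations default to the published Spearman intracorrelations
(bolder fish are more active).

Assay recordings are lazy random walks sampled at one frame per 6 s
inside a pixel-calibrated arena; flow profiles are stations at regular
spacing with the near_shore <= near_bottom <= center velocity ordering
enforced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .barrier_profile import FlowProfile
from .behavior_assays import AssayRecording
from .decision_matrix import FishRecord

__all__ = [
    "FRONT_TRAIT_MEANS",
    "DEFAULT_TRAIT_SDS",
    "DEFAULT_TRAIT_CORR",
    "CohortConfig",
    "RecordingConfig",
    "generate_cohort",
    "generate_recording",
    "generate_flow_profile",
    "front_cohort_config",
    "center_cohort_config",
    "child_seeds",
]

#: Published invasion-front means, order (boldness, activity, asociability).
FRONT_TRAIT_MEANS = (1.13, 1.17, 0.95)
#: Default index-scale spreads; chosen so the printed index ranges
#: (boldness up to ~1.76, asociability down to ~0.47) are ~2 sd excursions.
DEFAULT_TRAIT_SDS = (0.30, 0.30, 0.25)
#: Default intracorrelations, from the published rank-correlation table:
#: r(bold, act) = 0.366, r(bold, asoc) = -0.093, r(act, asoc) = 0.261.
DEFAULT_TRAIT_CORR = (
    (1.0, 0.366, -0.093),
    (0.366, 1.0, 0.261),
    (-0.093, 0.261, 1.0),
)


def child_seeds(seed: int, n: int) -> list[int]:
    """Fan one global seed out into *n* independent substreams.

    Uses ``numpy.random.SeedSequence`` spawning so adding a generator to a
    pipeline does not perturb the streams of the existing ones.
    """
    return [int(s.generate_state(1)[0] % (2**31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


@dataclass(frozen=True)
class CohortConfig:
    """Distributional targets for one generated population."""

    n_individuals: int
    length_mean: float = 9.9
    length_sd: float = 1.5
    length_min: float = 7.3
    length_max: float = 15.3
    trait_means: tuple[float, float, float] = FRONT_TRAIT_MEANS
    trait_sds: tuple[float, float, float] = DEFAULT_TRAIT_SDS
    trait_correlations: tuple = DEFAULT_TRAIT_CORR
    population_label: str = "front"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not self.length_min < self.length_max:
            raise ValueError("length_min must be below length_max")
        if any(s < 0 for s in self.trait_sds):
            raise ValueError("trait_sds must be nonnegative")
        if self.population_label not in ("front", "center"):
            raise ValueError("population_label must be 'front' or 'center'")
        r = np.asarray(self.trait_correlations, dtype=float)
        if r.shape != (3, 3):
            raise ValueError("trait_correlations must be 3x3")
        if not np.allclose(r, r.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(r).min() < -1e-10:
            raise ValueError("correlation matrix must be positive semi-definite")


@dataclass(frozen=True)
class RecordingConfig:
    """Parameters of one synthetic behavioural recording.

    ``movement_rate`` is the per-frame probability that the fish moves
    between consecutive frames; ``latency_distribution`` is a spec dict,
    either ``{"kind": "uniform", "low": .., "high": ..}`` or
    ``{"kind": "lognormal", "mean_log": .., "sd_log": ..}``, truncated to
    ``(0, duration]``.
    """

    duration: float = 3600.0
    frame_interval: float = 6.0
    arena_width_cm: float = 80.0
    arena_length_cm: float = 26.5
    px_per_cm: float = 8.0
    movement_rate: float = 0.5
    step_scale_cm: float = 3.0
    latency_distribution: dict = field(
        default_factory=lambda: {"kind": "lognormal",
                                 "mean_log": 4.0, "sd_log": 1.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.duration < self.frame_interval:
            raise ValueError("duration must cover at least one frame interval")
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        if not 0 <= self.movement_rate <= 1:
            raise ValueError("movement_rate must lie in [0, 1]")


def front_cohort_config(n: int, seed: int = 0, **overrides) -> CohortConfig:
    """Invasion-front cohort: trait means at the published thresholds."""
    return replace(CohortConfig(n_individuals=n, seed=seed,
                                population_label="front"), **overrides)


def center_cohort_config(n: int, seed: int = 0, effect_size: float = 1.0,
                         **overrides) -> CohortConfig:
    """Invasion-center cohort: means *effect_size* sd units below the front.

    The source publications show center fish to be shyer, less active and
    more social, but print no numeric center means; one standardized unit
    is the assumed default gap.
    """
    means = tuple(m - effect_size * s
                  for m, s in zip(FRONT_TRAIT_MEANS, DEFAULT_TRAIT_SDS))
    return replace(CohortConfig(n_individuals=n, seed=seed,
                                trait_means=means, population_label="center"),
                   **overrides)


def _truncated_lengths(rng: np.random.Generator, cfg: CohortConfig) -> np.ndarray:
    if cfg.length_sd == 0:
        return np.full(cfg.n_individuals, cfg.length_mean)
    a = (cfg.length_min - cfg.length_mean) / cfg.length_sd
    b = (cfg.length_max - cfg.length_mean) / cfg.length_sd
    return stats.truncnorm.rvs(a, b, loc=cfg.length_mean, scale=cfg.length_sd,
                               size=cfg.n_individuals, random_state=rng)


def _correlated_traits(rng: np.random.Generator, cfg: CohortConfig) -> np.ndarray:
    mu = np.asarray(cfg.trait_means, dtype=float)
    sd = np.asarray(cfg.trait_sds, dtype=float)
    corr = np.asarray(cfg.trait_correlations, dtype=float)
    cov = np.outer(sd, sd) * corr
    out = rng.multivariate_normal(mu, cov, size=cfg.n_individuals,
                                  method="svd")
    # indices are nonnegative by construction: resample the rare negative rows
    for _ in range(1000):
        bad = np.any(out < 0, axis=1)
        if not bad.any():
            break
        out[bad] = rng.multivariate_normal(mu, cov, size=int(bad.sum()),
                                           method="svd")
    else:
        raise RuntimeError("trait truncation at 0 failed to converge; "
                           "means are too close to zero for the given sds")
    return out


def generate_cohort(config: CohortConfig) -> list[FishRecord]:
    """Draw a reproducible cohort of individuals from the configured model."""
    rng = np.random.default_rng(config.seed)
    lengths = _truncated_lengths(rng, config)
    traits = _correlated_traits(rng, config)
    prefix = config.population_label
    return [
        FishRecord(fish_id=f"{prefix}-{i:05d}", tl_cm=float(lengths[i]),
                   boldness=float(traits[i, 0]), activity=float(traits[i, 1]),
                   asociability=float(traits[i, 2]),
                   population=config.population_label)
        for i in range(config.n_individuals)
    ]


def _draw_latency(rng: np.random.Generator, spec: dict, t_max: float) -> float:
    kind = spec.get("kind", "lognormal")
    if kind == "uniform":
        hi = min(spec.get("high", t_max), t_max)
        lo = min(spec.get("low", 1.0), hi)
        val = rng.uniform(lo, hi)
    elif kind == "lognormal":
        val = rng.lognormal(spec.get("mean_log", 4.0), spec.get("sd_log", 1.0))
    else:
        raise ValueError(f"unknown latency distribution kind {kind!r}")
    return float(min(max(val, 1e-6), t_max))


def generate_recording(config: RecordingConfig,
                       fish_id: str = "synthetic") -> AssayRecording:
    """Simulate one frame-sampled recording as a lazy random walk.

    The fish starts at a uniform position; at each frame it moves with
    probability ``movement_rate`` by an exponentially distributed step of
    mean ``step_scale_cm`` in a uniform direction, reflected back into the
    arena.  The stimulus point is the midpoint of one short arena wall.
    """
    rng = np.random.default_rng(config.seed)
    n_frames = int(math.floor(config.duration / config.frame_interval))
    w_px = config.arena_width_cm * config.px_per_cm
    l_px = config.arena_length_cm * config.px_per_cm
    pos = np.array([rng.uniform(0, w_px), rng.uniform(0, l_px)])
    times = config.frame_interval * np.arange(1, n_frames + 1)
    frames = np.empty((n_frames, 3))

    def _reflect(val: float, hi: float) -> float:
        val = abs(val) % (2 * hi)
        return 2 * hi - val if val > hi else val

    for i in range(n_frames):
        if rng.uniform() < config.movement_rate:
            step_px = rng.exponential(config.step_scale_cm) * config.px_per_cm
            angle = rng.uniform(0, 2 * math.pi)
            pos = pos + step_px * np.array([math.cos(angle), math.sin(angle)])
            pos = np.array([_reflect(pos[0], w_px), _reflect(pos[1], l_px)])
        frames[i] = (times[i], pos[0], pos[1])
    latency = _draw_latency(rng, config.latency_distribution, config.duration)
    return AssayRecording(
        fish_id=fish_id, latency_s=latency, frames=frames,
        px_per_cm=config.px_per_cm, stimuli_point=(0.0, l_px / 2.0),
        t_max=config.duration,
    )


def generate_flow_profile(n_stations: int, spacing: float,
                          bottom_velocity_range: tuple[float, float],
                          center_velocity_range: tuple[float, float],
                          seed: int = 0,
                          pool_spacing_range: tuple[float, float] = (1.0, 4.54),
                          ) -> FlowProfile:
    """Stations at regular spacing with ordered per-position velocities.

    ``near_shore <= near_bottom <= center`` is enforced at every station:
    the bottom velocity is drawn from its range, the center velocity from
    its range but floored at the bottom value, and the near-shore velocity
    uniformly below the bottom value.
    """
    if n_stations < 2:
        raise ValueError("need at least two stations")
    for name, (lo, hi) in (("bottom", bottom_velocity_range),
                           ("center", center_velocity_range),
                           ("pool spacing", pool_spacing_range)):
        if lo > hi:
            raise ValueError(f"inverted {name} range ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    stations = tuple((i, spacing * i) for i in range(n_stations))
    measurements = []
    for i in range(n_stations):
        vb = rng.uniform(*bottom_velocity_range)
        vc = max(rng.uniform(*center_velocity_range), vb)
        vs = rng.uniform(0, vb) if vb > 0 else 0.0
        measurements += [(i, "near_bottom", float(vb)),
                         (i, "center", float(vc)),
                         (i, "near_shore", float(vs))]
    n_pools = 3 * (n_stations - 1) + 1
    spacings = tuple(float(s) for s in
                     rng.uniform(*pool_spacing_range, size=max(n_pools - 1, 1)))
    return FlowProfile(stations=stations, measurements=tuple(measurements),
                       pool_spacings_m=spacings,
                       length_m=spacing * (n_stations - 1))
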