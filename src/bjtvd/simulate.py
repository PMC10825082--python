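"""Synthetic break-junction conductance traces.

A break-junction (BJ) pull produces a conductance-versus-stretch trace: a
metal-contact region near the conductance quantum G0, one or more molecular
plateaus at much lower conductance, and finally the open tunneling gap.  This
module emulates that sequence for three validation trace classes:

* Class 1 — two molecular plateaus (high state at log10(G/G0) = -2.5, low
  state at -3.0), 50 points each on average;
* Class 2 — a single high-state plateau (-2.5), 100 points on average;
* Class 3 — a single low-state plateau (-3.0), 100 points on average.

Ground-truth traces are piecewise constant; each plateau draws its level and
its length once from normal distributions.  Gaussian noise is then added
pointwise, with a small standard deviation (0.1) where the true conductance
exceeds G0 (metal contact) and a large one (0.5) everywhere else.  Stretch
distance advances 0.01 nm per point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

DISTANCE_STEP_NM = 0.01
#: truth level of the open-gap tail after the last molecular plateau,
#: below any histogram window used downstream
BASELINE_LEVEL = -6.0
BASELINE_POINTS = 50

STATE_METAL = "metal"
STATE_BASELINE = "baseline"


def plateau_state(k: int) -> str:
    """Label for the k-th molecular plateau (1-based), e.g. ``plateau_1``."""
    return f"plateau_{k}"


@dataclass(frozen=True)
class PlateauSpec:
    """One molecular plateau: level ~ N(g, sigma_g), length ~ N(length, sigma_length)."""

    g: float                # mean level, log10(G/G0)
    sigma_g: float          # sd of the level
    length: float           # mean length, points
    sigma_length: float     # sd of the length, points

    def __post_init__(self) -> None:
        if self.sigma_g < 0 or self.sigma_length < 0:
            raise ValueError("plateau sigmas must be >= 0")
        if self.length <= 0:
            raise ValueError("plateau mean length must be > 0")
        if self.g >= 0:
            raise ValueError("molecular plateau level must be < 0 (below G0)")


@dataclass(frozen=True)
class ClassSpec:
    """Molecular-region recipe for one trace class."""

    class_id: int
    plateaus: tuple[PlateauSpec, ...]

    def __post_init__(self) -> None:
        if self.class_id not in (1, 2, 3):
            raise ValueError(f"class_id must be 1, 2 or 3, got {self.class_id}")
        expected = 2 if self.class_id == 1 else 1
        if len(self.plateaus) != expected:
            raise ValueError(
                f"class {self.class_id} requires {expected} plateau(s), "
                f"got {len(self.plateaus)}"
            )


#: validation classes: level means, sds and lengths of the three trace types
CLASS_SPECS: dict[int, ClassSpec] = {
    1: ClassSpec(1, (PlateauSpec(-2.5, 0.1, 50, 10), PlateauSpec(-3.0, 0.1, 50, 10))),
    2: ClassSpec(2, (PlateauSpec(-2.5, 0.1, 100, 20),)),
    3: ClassSpec(3, (PlateauSpec(-3.0, 0.1, 100, 20),)),
}


@dataclass(frozen=True)
class MetalRegionSpec:
    """Metal-contact mixture before the molecular plateaus.

    A single-atom contact plateau at log10(G/G0) ~ N(0, 0.01) is always
    present (the 0.7-probability branch); with probability 0.3 it is preceded
    by a two-atom plateau at N(0.3, 0.02).  Segment lengths are
    round(N(50, 10)) points, clamped to at least ``min_points``.
    """

    extra_prob: float = 0.3
    extra_mean: float = 0.3
    extra_sd: float = 0.02
    contact_mean: float = 0.0
    contact_sd: float = 0.01
    length_mean: float = 50.0
    length_sd: float = 10.0
    min_points: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.extra_prob <= 1.0:
            raise ValueError("extra_prob must lie in [0, 1]")
        if min(self.extra_sd, self.contact_sd, self.length_sd) < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise on the log scale, keyed on the true level.

    Points whose ground truth exceeds 0 (G > G0, i.e. inside the metal
    contact) receive sd ``sd_metal``; all other points receive ``sd_other``.
    """

    sd_metal: float = 0.1
    sd_other: float = 0.5

    def __post_init__(self) -> None:
        if self.sd_metal < 0 or self.sd_other < 0:
            raise ValueError("noise sds must be >= 0")


@dataclass
class LabeledTrace:
    """A stretch-distance / log-conductance series with optional ground truth.

    ``distance`` is in nm with a uniform 0.01 nm step; ``log_g`` is
    log10(G/G0) per point.  Simulated traces carry the noise-free
    ``truth_log_g`` and a per-point ``truth_state`` label in
    {metal, plateau_k, baseline}.
    """

    distance: np.ndarray
    log_g: np.ndarray
    truth_log_g: np.ndarray | None = None
    truth_state: np.ndarray | None = None
    class_id: int | None = None
    trace_id: int | None = None
    reconstructed: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.distance = np.asarray(self.distance, dtype=float)
        self.log_g = np.asarray(self.log_g, dtype=float)
        if self.distance.shape != self.log_g.shape or self.distance.ndim != 1:
            raise ValueError("distance and log_g must be equal-length 1-D arrays")
        if len(self.distance) > 1:
            steps = np.diff(self.distance)
            if not np.allclose(steps, DISTANCE_STEP_NM, rtol=0, atol=1e-9):
                raise ValueError("distance must advance 0.01 nm per point")
        for name in ("truth_log_g", "truth_state"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val)
                if val.shape != self.log_g.shape:
                    raise ValueError(f"{name} must match log_g in length")
                setattr(self, name, val)

    def __len__(self) -> int:
        return len(self.log_g)

    def with_reconstructed(self, rec: np.ndarray) -> "LabeledTrace":
        rec = np.asarray(rec, dtype=float)
        if rec.shape != self.log_g.shape:
            raise ValueError("reconstructed series must match log_g in length")
        return replace(self, reconstructed=rec)


def _sample_length(rng: np.random.Generator, mean: float, sd: float,
                   min_points: int = 1) -> int:
    return max(min_points, round(rng.normal(mean, sd)))


def generate_ground_truth(
    spec: ClassSpec,
    metal: MetalRegionSpec | None = None,
    rng_seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> LabeledTrace:
    """Generate one noise-free trace for a class.

    The trace is: metal-contact segment(s), the class's molecular plateaus in
    decreasing-conductance order, then a fixed 50-point baseline tail at
    log10(G/G0) = -6 representing the open gap.  Each plateau's level is drawn
    once; lengths are rounded normal draws clamped to >= 1 point.
    """
    if metal is None:
        metal = MetalRegionSpec()
    rng = np.random.default_rng(rng_seed)

    levels: list[float] = []
    lengths: list[int] = []
    states: list[str] = []

    if rng.random() < metal.extra_prob:
        levels.append(rng.normal(metal.extra_mean, metal.extra_sd))
        lengths.append(_sample_length(rng, metal.length_mean, metal.length_sd,
                                      metal.min_points))
        states.append(STATE_METAL)
    levels.append(rng.normal(metal.contact_mean, metal.contact_sd))
    lengths.append(_sample_length(rng, metal.length_mean, metal.length_sd,
                                  metal.min_points))
    states.append(STATE_METAL)

    # conductance decreases monotonically with stretching: high state first
    ordered = sorted(spec.plateaus, key=lambda p: p.g, reverse=True)
    for k, p in enumerate(ordered, start=1):
        levels.append(rng.normal(p.g, p.sigma_g))
        lengths.append(_sample_length(rng, p.length, p.sigma_length))
        states.append(plateau_state(k))

    levels.append(BASELINE_LEVEL)
    lengths.append(BASELINE_POINTS)
    states.append(STATE_BASELINE)

    truth = np.repeat(np.asarray(levels, dtype=float), lengths)
    state = np.repeat(np.asarray(states, dtype=object), lengths)
    n = len(truth)
    distance = np.arange(n, dtype=float) * DISTANCE_STEP_NM
    return LabeledTrace(
        distance=distance,
        log_g=truth.copy(),
        truth_log_g=truth,
        truth_state=state,
        class_id=spec.class_id,
    )


def add_noise(
    trace: LabeledTrace,
    noise: NoiseSpec | None = None,
    rng_seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> LabeledTrace:
    """Add pointwise Gaussian noise to a ground-truth trace.

    The sd is chosen per point: ``sd_metal`` where truth_log_g > 0 (inside
    the metal contact, G > G0) and ``sd_other`` elsewhere.  Truth fields are
    preserved.
    """
    if trace.truth_log_g is None:
        raise ValueError("add_noise requires a trace with truth_log_g")
    if noise is None:
        noise = NoiseSpec()
    rng = np.random.default_rng(rng_seed)
    truth = trace.truth_log_g
    sd = np.where(truth > 0, noise.sd_metal, noise.sd_other)
    noisy = truth + rng.standard_normal(truth.shape) * sd
    return replace(trace, log_g=noisy)


def generate_trace(
    class_id: int,
    rng_seed: int | np.random.SeedSequence = 0,
    metal: MetalRegionSpec | None = None,
    noise: NoiseSpec | None = None,
) -> LabeledTrace:
    """Ground truth plus noise for one trace of the given class."""
    ss = (rng_seed if isinstance(rng_seed, np.random.SeedSequence)
          else np.random.SeedSequence(rng_seed))
    truth_seed, noise_seed = ss.spawn(2)
    trace = generate_ground_truth(CLASS_SPECS[class_id], metal, truth_seed)
    return add_noise(trace, noise, noise_seed)


def generate_dataset(
    n_per_class: int,
    rng_seed: int | np.random.SeedSequence = 0,
    class_ids: Sequence[int] = (1, 2, 3),
    metal: MetalRegionSpec | None = None,
    noise: NoiseSpec | None = None,
) -> list[LabeledTrace]:
    """Generate ``n_per_class`` noisy traces for each class.

    Every trace receives an independent child seed spawned deterministically
    from ``rng_seed``, so the dataset is reproducible trace-by-trace.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    for cid in class_ids:
        if cid not in CLASS_SPECS:
            raise ValueError(f"unknown class id {cid}")
    ss = (rng_seed if isinstance(rng_seed, np.random.SeedSequence)
          else np.random.SeedSequence(rng_seed))
    children = ss.spawn(len(class_ids) * n_per_class)
    traces: list[LabeledTrace] = []
    tid = 0
    for cid in class_ids:
        for _ in range(n_per_class):
            trace = generate_trace(cid, children[tid], metal, noise)
            trace.trace_id = tid
            traces.append(trace)
            tid += 1
    return traces
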