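"""End-to-end orchestration: simulate -> denoise -> plateaus / histograms /
classification, with a machine-readable summary.

A single master seed deterministically spawns per-stage seeds, so a run is
reproducible bit-for-bit from its configuration alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .classify import train_and_evaluate
from .denoise import DEFAULT_LAMBDA, TVDConfig, tvd_admm
from .histogram import conductance_histogram, peak_count
from .io import write_traces
from .plateau import (DEFAULT_MAX_DIST, DEFAULT_MIN_POINTS, DEFAULT_REGION,
                      DEFAULT_STATE_LEVELS, detection_summary)
from .simulate import generate_dataset

__all__ = ["RunConfig", "run_pipeline", "stage_seeds"]

STAGES = ("simulate", "split", "classifier")


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage integer seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    states = [int(child.generate_state(1)[0] % (2 ** 31)) for child in
              ss.spawn(len(STAGES))]
    return dict(zip(STAGES, states))


@dataclass(frozen=True)
class RunConfig:
    """Settings for a full validation run."""

    seed: int = 0
    n_per_class: int = 1000
    lam: float = DEFAULT_LAMBDA
    rho: float = 1.0
    max_iter: int = 5000
    tol: float = 1e-7
    min_points: int = DEFAULT_MIN_POINTS
    region: tuple[float, float] = DEFAULT_REGION
    state_levels: tuple[float, ...] = DEFAULT_STATE_LEVELS
    max_dist: float = DEFAULT_MAX_DIST
    out_dir: str | None = None
    write_dataset: bool = False
    peak_prominence: float = 0.1

    def tvd_config(self) -> TVDConfig:
        return TVDConfig(lam=self.lam, rho=self.rho,
                         max_iter=self.max_iter, tol=self.tol)

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load settings from a flat ``key = value`` text file.

        Lines starting with ``#`` and blank lines are ignored; keyword
        ``overrides`` (e.g. from CLI flags) win over file values.
        """
        fields = {f.name: f.type for f in
                  cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        values: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key == "lambda":  # friendlier alias for the TV weight
                    key = "lam"
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                default = getattr(cls, key, None)
                if key in ("region", "state_levels"):
                    values[key] = tuple(float(v) for v in raw.split(","))
                elif isinstance(default, bool):
                    values[key] = raw.lower() in ("1", "true", "yes")
                elif isinstance(default, int):
                    values[key] = int(raw)
                elif isinstance(default, float):
                    values[key] = float(raw)
                else:
                    values[key] = raw
        values.update(overrides)
        return cls(**values)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full validation flow and return a summary dict.

    The summary carries the both-state detection rate and per-state plateau
    statistics on Class 1, molecular-window peak counts of the pooled raw
    and denoised histograms, and the raw- and TVD-feature classification
    reports, plus every seed used.
    """
    seeds = stage_seeds(config.seed)
    cfg = config.tvd_config()

    dataset = generate_dataset(config.n_per_class, seeds["simulate"])
    for t in dataset:
        t.reconstructed = tvd_admm(t.log_g, cfg).reconstructed

    class1 = [t for t in dataset if t.class_id == 1]
    det = detection_summary(class1, cfg, min_points=config.min_points,
                            region=config.region,
                            state_levels=config.state_levels,
                            max_dist=config.max_dist)

    lo, hi = config.region
    window = np.round(np.arange(lo, hi + 1e-9, 0.05), 10)
    raw_hist = conductance_histogram(dataset, window)
    tvd_hist = conductance_histogram(dataset, window, use_reconstructed=True)

    reports = {}
    for key, use_rec in (("raw", False), ("tvd", True)):
        rep = train_and_evaluate(dataset, use_reconstructed=use_rec,
                                 lam=config.lam,
                                 split_seed=seeds["split"],
                                 clf_seed=seeds["classifier"])
        reports[key] = {
            "macro_f": rep.macro_f,
            "confusion": rep.confusion.tolist(),
            "per_class": {str(c): asdict(p) for c, p in rep.per_class.items()},
        }

    summary = {
        "version": __version__,
        "seeds": {"master": config.seed, **seeds},
        "n_per_class": config.n_per_class,
        "lambda": config.lam,
        "detection": {
            "n_traces": det.n_traces,
            "n_both_detected": det.n_both_detected,
            "rate": det.rate,
            "per_state": {
                s: {"n_plateaus": st.n_plateaus,
                    "mean_level": st.mean_level,
                    "mean_length_nm": st.mean_length_nm}
                for s, st in det.per_state.items()
            },
        },
        "histogram_peaks": {
            "raw": peak_count(raw_hist, config.peak_prominence),
            "tvd": peak_count(tvd_hist, config.peak_prominence),
        },
        "classification": reports,
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if config.write_dataset:
            write_traces(dataset, out / "dataset.tsv")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    return summary
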