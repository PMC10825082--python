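"""Reading and writing trace datasets as long-format TSV.

One row per point, columns: trace_id, class_id, point_index, distance_nm,
log_g, truth_log_g, truth_state.  Truth columns are empty for traces
without ground truth.  The reader validates point ordering and the uniform
0.01 nm distance step and round-trips the writer's output bit-exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import LabeledTrace

__all__ = ["write_traces", "read_traces"]

COLUMNS = ["trace_id", "class_id", "point_index", "distance_nm",
           "log_g", "truth_log_g", "truth_state"]


def write_traces(traces: Sequence[LabeledTrace], path: str | Path) -> None:
    """Write a dataset to tab-delimited long format."""
    frames = []
    for i, t in enumerate(traces):
        n = len(t)
        tid = t.trace_id if t.trace_id is not None else i
        frames.append(pd.DataFrame({
            "trace_id": np.full(n, tid, dtype=np.int64),
            "class_id": np.full(n, -1 if t.class_id is None else t.class_id,
                                dtype=np.int64),
            "point_index": np.arange(n, dtype=np.int64),
            "distance_nm": t.distance,
            "log_g": t.log_g,
            "truth_log_g": (t.truth_log_g if t.truth_log_g is not None
                            else np.full(n, np.nan)),
            "truth_state": (t.truth_state if t.truth_state is not None
                            else np.full(n, "", dtype=object)),
        }))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=COLUMNS)
    # %.17g round-trips float64 exactly
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_traces(path: str | Path) -> list[LabeledTrace]:
    """Read a long-format TSV dataset back into traces.

    Rows are grouped by trace_id and ordered by point_index; gaps or
    duplicates in point_index and non-uniform distance steps are rejected
    with the offending trace named.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    traces = []
    for tid, group in df.groupby("trace_id", sort=True):
        group = group.sort_values("point_index")
        pidx = group["point_index"].to_numpy()
        if np.any(np.diff(pidx) == 0):
            raise ValueError(f"trace {tid}: duplicate point_index")
        if not np.array_equal(pidx, np.arange(len(pidx))):
            raise ValueError(f"trace {tid}: point_index must run 0..n-1 "
                             "without gaps")
        truth = group["truth_log_g"].to_numpy()
        states = group["truth_state"].to_numpy(dtype=object)
        has_truth = not np.all(np.isnan(truth))
        class_id = int(group["class_id"].iloc[0])
        try:
            trace = LabeledTrace(
                distance=group["distance_nm"].to_numpy(),
                log_g=group["log_g"].to_numpy(),
                truth_log_g=truth if has_truth else None,
                truth_state=states if has_truth else None,
                class_id=None if class_id < 0 else class_id,
                trace_id=int(tid),
            )
        except ValueError as exc:
            raise ValueError(f"trace {tid}: {exc}") from exc
        traces.append(trace)
    return traces
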