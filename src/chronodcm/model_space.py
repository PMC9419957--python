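"""Timespan allocation and the 18-model time-of-day design space.

Subjects are binned into six two-hour timespans between 09:00 and 21:00 by
their mid-scan clock time.  Group-level (second-level) design matrices encode
competing hypotheses about how a parameter varies over those timespans:

* models 1-6   -- a deviation from the mean in one single timespan,
* models 7-11  -- a deviation over two adjacent timespans (4 h windows),
* models 12-17 -- phase-shifted sinusoids (one full period over the 12 h
                  window), an idealized circadian waveform,
* model 18     -- the null model: no time-of-day effect.

Each design has 12 rows, one per (timespan, session) cell in timespan-major
order (t1,LR), (t1,RL), ..., (t6,RL), and seven columns: the grand mean, the
mean-centred time-effect regressor, and five sum-to-zero effect codes for the
six-level timespan factor.  The two session rows of a timespan are identical,
so the sessions are averaged through the common design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_TIMESPANS = 6
N_SESSIONS = 2
N_MODELS = 18
SESSIONS = ("LR", "RL")

__all__ = [
    "TimespanScheme",
    "DesignMatrix",
    "ModelSpace",
    "default_scheme",
    "allocate_timespan",
    "time_effect_column",
    "build_design_matrix",
    "enumerate_model_space",
]


@dataclass(frozen=True)
class TimespanScheme:
    """Six contiguous clock-time intervals (hours) covering 09:00-21:00."""

    boundaries: tuple[tuple[float, float], ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.boundaries) != N_TIMESPANS or len(self.labels) != N_TIMESPANS:
            raise ValueError("a timespan scheme needs exactly six intervals and labels")
        starts = [b[0] for b in self.boundaries]
        ends = [b[1] for b in self.boundaries]
        if starts[0] != 9.0 or ends[-1] != 21.0:
            raise ValueError("timespan intervals must cover 09:00-21:00")
        for i in range(N_TIMESPANS):
            if ends[i] <= starts[i]:
                raise ValueError(f"interval {i + 1} is empty or reversed")
            if i and starts[i] != ends[i - 1]:
                raise ValueError("timespan intervals must be contiguous and ordered")

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([(a + b) / 2.0 for a, b in self.boundaries])


def default_scheme() -> TimespanScheme:
    """The six two-hour bins used throughout: 09-11, 11-13, ..., 19-21."""
    edges = [9.0 + 2.0 * k for k in range(N_TIMESPANS + 1)]
    bounds = tuple((edges[k], edges[k + 1]) for k in range(N_TIMESPANS))
    labels = tuple(
        f"{int(a):02d}:00–{int(b) - 1:02d}:59" for a, b in bounds
    )
    return TimespanScheme(boundaries=bounds, labels=labels)


def allocate_timespan(mid_scan_time: float, scheme: TimespanScheme | None = None) -> int:
    """Map a mid-scan clock time (fractional hours) to a timespan index 1..6.

    Intervals are half-open ``[start, end)`` except the last, which includes
    its right edge, so 21:00 itself is admissible and falls in timespan 6.
    """
    scheme = scheme or default_scheme()
    lo = scheme.boundaries[0][0]
    hi = scheme.boundaries[-1][1]
    if not (lo <= mid_scan_time <= hi):
        raise ValueError(
            f"mid-scan time {mid_scan_time:g} h outside the admissible window "
            f"[{lo:g}, {hi:g}] hours"
        )
    for t, (a, b) in enumerate(scheme.boundaries, start=1):
        if a <= mid_scan_time < b:
            return t
    return N_TIMESPANS  # mid_scan_time == 21.0, closed right edge


def time_effect_column(model_id: int) -> np.ndarray:
    """The mean-centred 6-vector of per-timespan predictions for one model."""
    if not 1 <= int(model_id) <= N_MODELS:
        raise ValueError(f"model_id must be in 1..{N_MODELS}, got {model_id}")
    model_id = int(model_id)
    if model_id <= 6:
        col = np.zeros(N_TIMESPANS)
        col[model_id - 1] = 1.0
    elif model_id <= 11:
        col = np.zeros(N_TIMESPANS)
        col[model_id - 7] = 1.0
        col[model_id - 6] = 1.0
    elif model_id <= 17:
        # one full period over the six timespans; model 12 peaks at timespan 2,
        # each successive model one timespan later (model 15 is -model 12)
        peak = model_id - 10
        t = np.arange(1, N_TIMESPANS + 1)
        col = np.cos(2.0 * np.pi * (t - peak) / N_TIMESPANS)
    else:
        col = np.zeros(N_TIMESPANS)
    return col - col.mean()


@dataclass(frozen=True)
class DesignMatrix:
    """A 12x7 second-level design for one time-of-day model."""

    model_id: int
    matrix: np.ndarray
    column_names: tuple[str, ...] = field(
        default=("mean", "time_effect", "ts1", "ts2", "ts3", "ts4", "ts5")
    )

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (N_TIMESPANS * N_SESSIONS, len(self.column_names)):
            raise ValueError(
                f"design matrix must be {N_TIMESPANS * N_SESSIONS}x{len(self.column_names)}"
            )
        object.__setattr__(self, "matrix", m)

    @property
    def row_labels(self) -> list[str]:
        return [f"t{t}:{s}" for t in range(1, N_TIMESPANS + 1) for s in SESSIONS]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.row_labels, columns=list(self.column_names))

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_id": self.model_id,
                "column_names": list(self.column_names),
                "matrix": self.matrix.tolist(),
            }
        )


def _session_factor_codes() -> np.ndarray:
    """Sum-to-zero effects coding of the six-level timespan factor (5 columns)."""
    codes = np.zeros((N_TIMESPANS, N_TIMESPANS - 1))
    for level in range(N_TIMESPANS - 1):
        codes[level, level] = 1.0
    codes[N_TIMESPANS - 1, :] = -1.0
    return codes


def build_design_matrix(model_id: int, scheme: TimespanScheme | None = None) -> DesignMatrix:
    """Assemble the 12x7 design for one model (rows timespan-major, LR then RL)."""
    col = time_effect_column(model_id)
    codes = _session_factor_codes()
    rows = []
    for t in range(N_TIMESPANS):
        row = np.concatenate(([1.0, col[t]], codes[t]))
        rows.append(row)  # LR
        rows.append(row.copy())  # RL -- identical, sessions averaged by design
    return DesignMatrix(model_id=int(model_id), matrix=np.vstack(rows))


@dataclass(frozen=True)
class ModelSpace:
    """All 18 designs sharing row ordering and column count."""

    designs: tuple[DesignMatrix, ...]
    scheme: TimespanScheme

    def __post_init__(self) -> None:
        if len(self.designs) != N_MODELS:
            raise ValueError(f"model space must hold exactly {N_MODELS} designs")
        ids = [d.model_id for d in self.designs]
        if ids != list(range(1, N_MODELS + 1)):
            raise ValueError("designs must carry model_ids 1..18 in order")
        ncols = {d.matrix.shape[1] for d in self.designs}
        if len(ncols) != 1:
            raise ValueError("all designs must share a column count")

    def __iter__(self):
        return iter(self.designs)

    def __getitem__(self, model_id: int) -> DesignMatrix:
        return self.designs[model_id - 1]


def enumerate_model_space(scheme: TimespanScheme | None = None) -> ModelSpace:
    scheme = scheme or default_scheme()
    designs = tuple(build_design_matrix(m, scheme) for m in range(1, N_MODELS + 1))
    space = ModelSpace(designs=designs, scheme=scheme)
    # structural invariants: centred time columns, null model empty, all distinct
    cols = np.array([time_effect_column(m) for m in range(1, N_MODELS + 1)])
    assert np.allclose(cols.sum(axis=1), 0.0, atol=1e-12)
    assert np.allclose(cols[N_MODELS - 1], 0.0)
    for i in range(N_MODELS):
        for j in range(i + 1, N_MODELS):
            if np.allclose(cols[i], cols[j], atol=1e-12):
                raise AssertionError(f"models {i + 1} and {j + 1} share a time-effect column")
    return space
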