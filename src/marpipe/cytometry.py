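"""Reporter-fluorescence event scoring.

Flow-cytometry event tables (one fluorescence value per cell, relative
fluorescence units) are gated into four categories — silent, low, medium,
high — with half-open gates ``[lower, upper)``: an event exactly on a gate
belongs to the upper category.  The silent gate defaults to 10 RFU, the
background fluorescence of non-transfected cells; the fraction of silent
cells quantifies transgene silencing and its reduction by a MAR element is
the anti-silencing effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError, ValidationError

CATEGORIES = ("silent", "low", "medium", "high")


@dataclass
class EventTable:
    """Per-cell fluorescence values (RFU, all ≥ 0)."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("event values must be one-dimensional")
        if len(self.values) and np.min(self.values) < 0:
            raise ValidationError("fluorescence values must be >= 0")

    @property
    def n_events(self) -> int:
        return int(len(self.values))


@dataclass(frozen=True)
class GateConfig:
    """Category gate boundaries in RFU; must be strictly increasing.

    Only the silent gate (10 RFU) is anchored to measured background; the
    low/medium boundaries are configuration placeholders that any
    four-category analysis must set explicitly.
    """

    silent_max: float = 10.0
    low_max: float = 100.0
    medium_max: float = 1000.0

    def __post_init__(self):
        if not (0 < self.silent_max < self.low_max < self.medium_max):
            raise ConfigurationError(
                f"gates must satisfy 0 < {self.silent_max} < {self.low_max} "
                f"< {self.medium_max}"
            )


@dataclass(frozen=True)
class CategoryFractions:
    """Integer category counts with exact rational fractions."""

    counts: dict[str, int]
    n_events: int

    @property
    def fractions(self) -> dict[str, Fraction]:
        return {k: Fraction(v, self.n_events) for k, v in self.counts.items()}

    def as_floats(self) -> dict[str, float]:
        return {k: v / self.n_events for k, v in self.counts.items()}

    def __getitem__(self, category: str) -> float:
        return self.counts[category] / self.n_events


def read_events(path, column: str | None = None, label: str = "") -> EventTable:
    """Read events from one-column (or labelled multi-column) delimited text."""
    from .qpcr import _read_table

    df = _read_table(path)
    if column is None:
        if df.shape[1] != 1:
            raise ValidationError(
                f"{path}: multiple columns {list(df.columns)}; specify one"
            )
        column = df.columns[0]
    if column not in df.columns:
        raise ValidationError(f"{path}: no column {column!r}")
    return EventTable(df[column].to_numpy(dtype=float), label=label or str(column))


def classify_events(events: EventTable, gates: GateConfig = GateConfig()) -> CategoryFractions:
    """Fraction of events per category under half-open gates.

    silent: RFU < silent_max; low: [silent_max, low_max);
    medium: [low_max, medium_max); high: ≥ medium_max.  Counts are integers,
    so the fractions sum to 1 exactly.
    """
    if events.n_events == 0:
        raise DegenerateInputError("event table is empty")
    v = events.values
    edges = np.array([gates.silent_max, gates.low_max, gates.medium_max])
    idx = np.searchsorted(edges, v, side="right")  # boundary -> upper category
    counts = np.bincount(idx, minlength=4)
    return CategoryFractions(
        counts={cat: int(n) for cat, n in zip(CATEGORIES, counts)},
        n_events=events.n_events,
    )


def mean_fluorescence(
    events: EventTable,
    exclude_silent: bool = False,
    gates: GateConfig = GateConfig(),
) -> float:
    """Arithmetic mean RFU, optionally over non-silent events only."""
    if events.n_events == 0:
        raise DegenerateInputError("event table is empty")
    v = events.values
    if exclude_silent:
        v = v[v >= gates.silent_max]
        if len(v) == 0:
            raise DegenerateInputError("no non-silent events to average")
    return float(np.mean(v))


def fold_change(sample_mean: float, control_mean: float) -> float:
    """Sample mean fluorescence relative to a control population (control = 1)."""
    if control_mean <= 0:
        raise DegenerateInputError("control mean must be positive")
    return sample_mean / control_mean


def summary_table(
    tables: dict[str, EventTable],
    gates: GateConfig = GateConfig(),
    control: str | None = None,
    exclude_silent_mean: bool = False,
) -> pd.DataFrame:
    """Per-population category fractions, mean RFU and fold vs control."""
    rows = []
    for name, events in tables.items():
        frac = classify_events(events, gates).as_floats()
        rows.append(
            {
                "population": name,
                "n_events": events.n_events,
                **{f"frac_{c}": frac[c] for c in CATEGORIES},
                "mean_rfu": mean_fluorescence(events, exclude_silent_mean, gates),
            }
        )
    df = pd.DataFrame(rows)
    if control is not None:
        if control not in tables:
            raise ValidationError(f"control population {control!r} not found")
        cmean = df.loc[df["population"] == control, "mean_rfu"].iloc[0]
        df["fold_vs_control"] = [fold_change(m, cmean) for m in df["mean_rfu"]]
    return df
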