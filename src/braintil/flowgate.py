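"""Flow-cytometry event processing: arcsinh transform, per-sample QC and
downsampling, threshold gating, and gate-fraction classification.

Events arrive as a table with one row per (already lineage-gated, e.g.
viable CD3+CD8+) event, a ``sample_id`` column, and one column per marker
with pre-compensation-corrected intensities. The pTRT readout is the
CD39+CCR7low gate fraction among CD8+ events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def arcsinh_transform(x, cofactor: float = 150.0):
    """asinh(x / cofactor), elementwise. The standard variance-stabilizing
    transform for cytometry intensities."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return np.arcsinh(np.asarray(x, dtype=float) / cofactor)


def transform_events(
    events: pd.DataFrame, markers: list[str], cofactor: float = 150.0
) -> pd.DataFrame:
    out = events.copy()
    out[markers] = arcsinh_transform(events[markers].to_numpy(), cofactor)
    return out


def qc_and_downsample(
    events: pd.DataFrame,
    min_events: int = 100,
    n_keep: int = 1500,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Drop samples with < min_events events; subsample larger samples to
    n_keep events without replacement (smaller samples kept whole)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kept = []
    for sid, grp in events.groupby("sample_id", observed=True, sort=True):
        if len(grp) < min_events:
            continue
        if len(grp) > n_keep:
            idx = rng.choice(len(grp), size=n_keep, replace=False)
            grp = grp.iloc[np.sort(idx)]
        kept.append(grp)
    if not kept:
        return events.iloc[0:0]
    return pd.concat(kept)


@dataclass(frozen=True)
class GatePredicate:
    marker: str
    op: str  # ">" or "<"
    threshold: float

    def evaluate(self, events: pd.DataFrame) -> np.ndarray:
        if self.marker not in events.columns:
            raise KeyError(f"unknown marker {self.marker!r}")
        x = events[self.marker].to_numpy()
        if self.op == ">":
            return x > self.threshold
        if self.op == "<":
            return x < self.threshold
        raise ValueError(f"unknown operator {self.op!r}")


def gate_mask(events: pd.DataFrame, gate: list[GatePredicate]) -> np.ndarray:
    """Conjunction of per-marker threshold predicates over transformed
    intensities."""
    mask = np.ones(len(events), dtype=bool)
    for pred in gate:
        mask &= pred.evaluate(events)
    return mask


def gate_fraction(
    events: pd.DataFrame,
    gate: list[GatePredicate],
    median_markers: list[str] | None = None,
) -> pd.DataFrame:
    """Per-sample fraction of events inside the gate.

    Also returns, for each requested marker, the median transformed
    intensity within the gate (NaN for empty gates).
    """
    rows = []
    for sid, grp in events.groupby("sample_id", observed=True, sort=True):
        m = gate_mask(grp, gate)
        frac = m.mean() if len(grp) else np.nan
        row = {"sample_id": sid, "n_events": len(grp), "fraction": frac}
        if median_markers:
            inside = grp.loc[m]
            for mk in median_markers:
                row[f"median_{mk}"] = inside[mk].median() if len(inside) else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def classify_by_gate_fraction(fraction: float, high_cut: float = 0.30) -> str:
    """"high" iff fraction > high_cut (strict), else "low"."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction outside [0, 1]")
    return "high" if fraction > high_cut else "low"
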