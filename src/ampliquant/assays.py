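"""Companion assay metrics: phospho-protein percentages, flow-orientation
fractions, curve AUC, and vessel-diameter summaries.

These are the small quantification formulas used downstream of the edited
cell line: electrochemiluminescence (multiplex) and western-blot
phospho-protein percentages, the fraction of cells whose long axis aligns
with a flow direction, trapezoidal area under migration/proliferation
curves, and per-explant vessel-diameter statistics from filament-tracing
segment tables.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "pct_phospho_multiplex",
    "pct_phospho_wb",
    "fold_angles",
    "orientation_fraction",
    "angle_histogram",
    "auc_trapezoid",
    "diameter_summary",
    "diameter_histogram",
]


def pct_phospho_multiplex(phospho_signal: float, total_signal: float) -> float:
    """Percent phospho-protein for multiplex phospho/total assays.

    ``%phospho = 100 * 2 * phospho / (phospho + total)``. The factor 2
    reflects that the "total" well of the multiplex kit also contains the
    phosphorylated species, so the value ranges over [0, 200].
    """
    if phospho_signal < 0 or total_signal < 0:
        raise ValueError("signals must be nonnegative")
    denom = phospho_signal + total_signal
    if denom == 0:
        raise ValueError("phospho + total signal is zero; %phospho undefined")
    return 100.0 * 2.0 * phospho_signal / denom


def pct_phospho_wb(phospho_signal: float, total_signal: float) -> float:
    """Percent phospho-protein for western-blot band densitometry.

    ``%phospho = 100 * phospho / total``.
    """
    if phospho_signal < 0 or total_signal < 0:
        raise ValueError("signals must be nonnegative")
    if total_signal == 0:
        raise ValueError("total signal is zero; %phospho undefined")
    return 100.0 * phospho_signal / total_signal


def fold_angles(angles_deg: Sequence[float] | np.ndarray) -> np.ndarray:
    """Fold orientation angles into (−90, 90].

    Cell long axes are undirected, so an angle and its 180° rotation are
    the same orientation; flow direction is 0°.
    """
    a = np.asarray(angles_deg, dtype=float) % 180.0
    a[a > 90.0] -= 180.0
    return a


def orientation_fraction(
    angles_deg: Sequence[float] | np.ndarray, tolerance: float = 5.0
) -> float:
    """Fraction of cells oriented within ±``tolerance`` degrees of the flow axis."""
    a = fold_angles(angles_deg)
    if a.size == 0:
        raise ValueError("no angles supplied")
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    return float(np.count_nonzero(np.abs(a) <= tolerance) / a.size)


def angle_histogram(
    angles_deg: Sequence[float] | np.ndarray, bin_width: float = 10.0
) -> pd.DataFrame:
    """Binned folded-angle distribution (fractions), for orientation curves."""
    a = fold_angles(angles_deg)
    edges = np.arange(-90.0, 90.0 + bin_width, bin_width)
    counts, _ = np.histogram(a, bins=edges)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "fraction": counts / a.size if a.size else counts.astype(float),
        }
    )


def auc_trapezoid(
    time: Sequence[float] | np.ndarray, value: Sequence[float] | np.ndarray
) -> float:
    """Trapezoidal area under a time–value curve (impedance, % area, ...)."""
    t = np.asarray(time, dtype=float)
    v = np.asarray(value, dtype=float)
    if t.size != v.size or t.size < 2:
        raise ValueError("time and value must have equal length >= 2")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    return float(np.trapezoid(v, t))


def diameter_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-explant vessel-diameter statistics from a segment table.

    ``table`` needs columns ``explant_id`` and ``mean_diameter`` (µm, one
    row per traced segment; ``segment_id`` is optional). The per-explant
    mean is the unit of analysis when explants are compared.
    """
    _require_columns(table, ("explant_id", "mean_diameter"))
    d = table["mean_diameter"].to_numpy(dtype=float)
    if np.any(d <= 0) or np.any(~np.isfinite(d)):
        raise ValueError("mean_diameter values must be positive and finite")
    out = (
        table.groupby("explant_id", sort=True)["mean_diameter"]
        .agg(n_segments="size", mean_diameter="mean", median_diameter="median")
        .reset_index()
    )
    return out


def diameter_histogram(table: pd.DataFrame, bin_width: float = 5.0) -> pd.DataFrame:
    """Pooled diameter distribution across all segments (fixed-width bins, µm)."""
    _require_columns(table, ("mean_diameter",))
    d = table["mean_diameter"].to_numpy(dtype=float)
    if d.size == 0:
        raise ValueError("empty segment table")
    hi = np.ceil(d.max() / bin_width) * bin_width
    edges = np.arange(0.0, hi + bin_width, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "fraction": counts / d.size,
        }
    )


def _require_columns(table: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing required columns: {missing}")
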