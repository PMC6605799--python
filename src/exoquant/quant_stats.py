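"""Colocalization, secreted-fraction, and two-group comparison statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import Image2D
from .detection import SpotSet

__all__ = [
    "ColocResult",
    "GroupComparison",
    "object_colocalization",
    "pearson_coefficient",
    "secreted_fraction",
    "secreted_fraction_table",
    "compare_groups",
]


@dataclass
class ColocResult:
    """Object-based colocalization: one-to-one centroid matches within a radius."""

    fraction_A_in_B: float
    n_A: int
    n_B: int
    matches: list[tuple[int, int, float]] = field(default_factory=list)


@dataclass
class GroupComparison:
    t_statistic: float
    p_value: float
    mean_A: float
    sem_A: float
    mean_B: float
    sem_B: float
    n_A: int
    n_B: int
    welch: bool


def object_colocalization(
    spots_A: SpotSet, spots_B: SpotSet, radius: float = 3.0
) -> ColocResult:
    """Fraction of A spots with a one-to-one B partner within ``radius`` px.

    Matching is greedy by increasing centroid distance and restricted to
    spots in the same frame; every match distance is <= radius.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(spots_A) == 0:
        raise ValueError("no reference objects")
    matches: list[tuple[int, int, float]] = []
    table_a = spots_A.table.reset_index(drop=True)
    table_b = spots_B.table.reset_index(drop=True)
    for f in np.unique(table_a["frame"].to_numpy()):
        idx_a = np.flatnonzero(table_a["frame"].to_numpy() == f)
        idx_b = np.flatnonzero(table_b["frame"].to_numpy() == f) if len(table_b) else np.array([], dtype=int)
        if len(idx_b) == 0:
            continue
        pa = table_a.loc[idx_a, ["row", "col"]].to_numpy(dtype=float)
        pb = table_b.loc[idx_b, ["row", "col"]].to_numpy(dtype=float)
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
        order = np.dstack(np.unravel_index(np.argsort(d, axis=None, kind="stable"), d.shape))[0]
        used_a: set[int] = set()
        used_b: set[int] = set()
        for i, j in order:
            if d[i, j] > radius:
                break
            if i in used_a or j in used_b:
                continue
            used_a.add(int(i))
            used_b.add(int(j))
            matches.append((int(idx_a[i]), int(idx_b[j]), float(d[i, j])))
    return ColocResult(
        fraction_A_in_B=len(matches) / len(table_a),
        n_A=len(table_a),
        n_B=len(table_b),
        matches=matches,
    )


def pearson_coefficient(
    img_A: Image2D, img_B: Image2D, roi_mask: np.ndarray | None = None
) -> float:
    """Pearson correlation of the two channels over ROI pixels."""
    if img_A.shape != img_B.shape:
        raise ValueError("channel shapes differ")
    if roi_mask is None:
        roi_mask = np.ones(img_A.shape, dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != img_A.shape:
        raise ValueError("ROI mask shape differs from images")
    a = img_A.intensity[roi_mask]
    b = img_B.intensity[roi_mask]
    if len(a) < 2:
        raise ValueError("ROI must contain at least 2 pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("undefined correlation")
    return float(np.corrcoef(a, b)[0, 1])


def secreted_fraction(supernatant: float, lysate: float) -> float:
    """Secreted fraction F = supernatant / (supernatant + lysate)."""
    if supernatant < 0 or lysate < 0:
        raise ValueError("intensities must be non-negative")
    total = supernatant + lysate
    if total == 0:
        raise ValueError("secreted fraction undefined: both intensities are zero")
    return supernatant / total


def secreted_fraction_table(lanes: pd.DataFrame) -> pd.DataFrame:
    """Per-timepoint secreted fraction from (time_h, supernatant, lysate) lanes."""
    required = {"time_h", "supernatant", "lysate"}
    missing = required - set(lanes.columns)
    if missing:
        raise ValueError(f"lane table missing columns {sorted(missing)}")
    out = lanes[["time_h", "supernatant", "lysate"]].copy()
    out["secreted_fraction"] = [
        secreted_fraction(s, l) for s, l in zip(out["supernatant"], out["lysate"])
    ]
    return out


def compare_groups(
    values_A, values_B, welch: bool = False
) -> GroupComparison:
    """Two-sided two-sample t test with mean +/- SEM summaries.

    Pooled-variance Student's t by default; Welch's correction on request.
    """
    a = np.asarray(values_A, dtype=float)
    b = np.asarray(values_B, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        t_statistic=float(t),
        p_value=float(p),
        mean_A=float(a.mean()),
        sem_A=float(stats.sem(a)),
        mean_B=float(b.mean()),
        sem_B=float(stats.sem(b)),
        n_A=len(a),
        n_B=len(b),
        welch=welch,
    )
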