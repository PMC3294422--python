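"""Per-cell marker expression (quotient method) and group statistics.

Marker fluorescence (e.g. IBA-1, CD68 immunostains) is quantified per cell
as the mean intensity within the cell mask divided by the mean intensity
of the local region excluding the mask.  The quotient, unlike background
subtraction, is invariant to multiplicative staining/illumination
variation, which is why it is preferred for tissues of varying staining
intensity.

Group-level plumbing follows the convention that the experimental unit is
the animal: per-cell ratios aggregate to per-animal means before
normalization to the control group or any significance test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError
from .segment import CellRecord
from .stacks import Projection


@dataclass
class ExpressionRecord:
    cell_id: int
    channel: str
    ratio: float


@dataclass
class GroupSummary:
    """Percent-of-control summary for one experimental group."""

    group: str
    per_animal_means: list[float]
    percent_of_control: list[float]
    mean_percent: float
    sd_percent: float
    p_value: float | None = None
    stars: str = ""
    low_n: bool = False


def quantify_expression(
    record: CellRecord, proj: Projection, channel: str
) -> ExpressionRecord:
    """Quotient-method expression ratio for one accepted cell.

    ratio = mean(channel over cell mask) / mean(channel over LR \\ mask).
    """
    if record.status != "accepted":
        raise ValueError(f"expression requires an accepted cell, got {record.status!r}")
    if channel not in proj.channels:
        raise KeyError(f"channel {channel!r} not in projection")
    lr = record.local_region
    patch = lr.patches.get(channel)
    if patch is None:
        r0, r1, c0, c1 = lr.bounds_rc
        patch = np.asarray(proj.channels[channel][r0:r1, c0:c1], dtype=float)
    mask = record.cell_mask.mask
    bg = ~mask
    if not bg.any():
        raise DegenerateInputError("cell mask fills the whole LR; no background")
    bg_mean = float(patch[bg].mean())
    if bg_mean <= 0:
        raise DegenerateInputError("zero mean background intensity")
    return ExpressionRecord(
        cell_id=record.cell_position.id,
        channel=channel,
        ratio=float(patch[mask].mean()) / bg_mean,
    )


def normalize_to_control(
    per_animal_means: dict[str, list[float]], control_group: str
) -> dict[str, GroupSummary]:
    """Express each animal's mean as percent of the control grand mean.

    The control group's own percent-of-control mean is 100 by construction.
    Single-animal groups are computed but flagged ``low_n``.
    """
    if control_group not in per_animal_means:
        raise KeyError(f"control group {control_group!r} missing")
    for g, vals in per_animal_means.items():
        if len(vals) == 0:
            raise ValueError(f"group {g!r} is empty")
    control_vals = per_animal_means[control_group]
    if len(control_vals) < 2:
        raise ValueError("control group needs at least 2 animals")
    grand = float(np.mean(control_vals))
    out = {}
    for g, vals in per_animal_means.items():
        pct = [100.0 * v / grand for v in vals]
        out[g] = GroupSummary(
            group=g,
            per_animal_means=list(vals),
            percent_of_control=pct,
            mean_percent=float(np.mean(pct)),
            sd_percent=float(np.std(pct, ddof=1)) if len(pct) > 1 else 0.0,
            low_n=len(vals) < 2,
        )
    return out


def star_code(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(
    a, b, equal_var: bool = True
) -> tuple[float, str]:
    """Two-sample two-tailed Student's t-test between per-animal values.

    Classical pooled-variance test by default; ``equal_var=False`` gives
    Welch's variant.  Returns (p_value, stars).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(p):  # both groups constant and identical
        p = 1.0
    return float(p), star_code(float(p))


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation of per-cell values."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need n >= 3 paired values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError("correlation undefined for constant input")
    r, _ = stats.pearsonr(x, y)
    return float(r**2)


def mean_r2_by_animal(df, x: str, y: str, animal: str = "animal_id") -> float:
    """Average per-animal R² — the convention used for group reporting."""
    vals = [
        pearson_r2(sub[x].to_numpy(), sub[y].to_numpy())
        for _, sub in df.groupby(animal)
        if len(sub) >= 3
    ]
    if not vals:
        raise ValueError("no animal with >= 3 cells")
    return float(np.mean(vals))
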