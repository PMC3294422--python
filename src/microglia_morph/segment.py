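"""Iterative local-threshold segmentation of individual cells.

Per candidate cell position (CP) a square local region (LR, default
120×120 µm) is cut from the projection.  Within the LR a threshold is
iterated from an Otsu start until the 8-connected suprathreshold component
containing the CP — the candidate cell mask (CCM) — has an area within a
tolerance of the prior target cell size (TCS, default 500 µm²).  Because
the threshold is local to the LR, slow illumination gradients across the
field do not bias the segmented shape.

The accepted mask is then tested: it must not touch the LR boundary
(otherwise the cell is cut off) and must contain exactly one soma mask — a
contiguous region at least ``min_soma_um2`` large whose pixels exceed the
final threshold by a relative increment ``soma_factor_x`` (default +50%).
Zero somata indicate a cell centered outside the imaged slab; two or more
indicate a dividing cell or an unresolved pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .detect import EIGHT, CellPosition, find_cell_positions
from .errors import ConfigurationError, DegenerateInputError
from .stacks import Projection


@dataclass
class SegmentationParams:
    """All segmentation tunables.

    tcs_um2
        Target cell size: the prior 2D footprint of one microglia (µm²).
    tol_um2
        Acceptance half-window around the TCS (µm²).
    lr_um
        Side of the square local region centered on each CP (µm).
    soma_factor_x
        Relative increment over the final threshold defining soma pixels
        (0.5 → pixels 50% above the last iterative threshold).
    min_soma_um2
        Minimum contiguous soma area (µm²).
    max_iter
        Hard cap on threshold iterations.
    stability_runs
        Number of consecutive iterations with identical area (and a settled
        threshold) that declares stagnation.
    step_gain
        Threshold-update gain, scaled by the patch intensity range.
    """

    tcs_um2: float = 500.0
    tol_um2: float = 100.0
    lr_um: float = 120.0
    soma_factor_x: float = 0.5
    min_soma_um2: float = 16.7
    max_iter: int = 100
    stability_runs: int = 3
    step_gain: float = 0.05
    min_object_area_um2: float = 50.0
    smooth_radius_px: int = 1
    dedupe_distance_um: float = 5.0

    def __post_init__(self) -> None:
        if not (self.tcs_um2 > self.tol_um2 > 0):
            raise ConfigurationError("require tcs_um2 > tol_um2 > 0")
        if self.soma_factor_x <= 0:
            raise ConfigurationError("soma_factor_x must be positive")
        if self.min_soma_um2 <= 0:
            raise ConfigurationError("min_soma_um2 must be positive")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be at least 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LocalRegion:
    """Square window of nominal side ``lr_um`` centered on a CP."""

    bounds_rc: tuple[int, int, int, int]  # half-open (r0, r1, c0, c1)
    patches: dict[str, np.ndarray]
    offset_rc: tuple[int, int]
    pixel_size_um: float
    clipped: bool
    channel: str

    @property
    def patch(self) -> np.ndarray:
        return self.patches[self.channel]

    @property
    def shape(self) -> tuple[int, int]:
        return self.patch.shape


@dataclass
class CellMask:
    """Final mask of one cell in LR coordinates, with iteration diagnostics."""

    mask: np.ndarray
    area_um2: float
    final_threshold: float
    n_iterations: int
    converged: bool
    iteration_log: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class SomaMask:
    mask: np.ndarray
    area_um2: float
    centroid_rc: tuple[float, float]  # LR coordinates


@dataclass
class CellRecord:
    """Everything known about one candidate cell after segmentation."""

    cell_position: CellPosition
    local_region: LocalRegion
    cell_mask: CellMask | None = None
    soma_masks: list[SomaMask] = field(default_factory=list)
    status: str = "accepted"

    @property
    def soma_mask(self) -> SomaMask | None:
        return self.soma_masks[0] if len(self.soma_masks) == 1 else None


def extract_local_region(
    proj: Projection, cp: CellPosition, params: SegmentationParams
) -> LocalRegion:
    """Cut the square LR around a CP, clipping at image edges."""
    nrow, ncol = proj.shape
    r, c = cp.centroid_rc
    if not (0 <= r < nrow and 0 <= c < ncol):
        raise ValueError(f"CP {cp.centroid_rc} outside image {proj.shape}")
    side = int(round(params.lr_um / proj.pixel_size_um))
    half = side // 2
    ri, ci = int(round(r)), int(round(c))
    r0, r1 = ri - half, ri - half + side
    c0, c1 = ci - half, ci - half + side
    clipped = r0 < 0 or c0 < 0 or r1 > nrow or c1 > ncol
    r0, r1 = max(r0, 0), min(r1, nrow)
    c0, c1 = max(c0, 0), min(c1, ncol)
    patches = {
        name: np.asarray(img[r0:r1, c0:c1], dtype=float)
        for name, img in proj.channels.items()
    }
    channel = "egfp" if "egfp" in patches else next(iter(patches))
    return LocalRegion(
        bounds_rc=(r0, r1, c0, c1),
        patches=patches,
        offset_rc=(r0, c0),
        pixel_size_um=proj.pixel_size_um,
        clipped=clipped,
        channel=channel,
    )


def otsu_threshold(patch: np.ndarray) -> float:
    """Otsu's threshold over a 256-bin histogram of the patch.

    Minimizes the within-class intensity variance of the two-class split.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.max() == patch.min():
        raise DegenerateInputError("constant patch has no Otsu threshold")
    return float(threshold_otsu(patch, nbins=256))


def candidate_mask(
    lr: LocalRegion,
    threshold: float,
    cp: CellPosition,
    search_radius_um: float = 10.0,
) -> np.ndarray:
    """Suprathreshold 8-connected component belonging to the CP.

    Binarizes the LR patch at ``> threshold`` and returns the component
    containing the CP's pixel.  If the CP pixel itself is below threshold,
    the nearest component within ``search_radius_um`` is returned; if none
    is that close, an all-false mask ("threshold too high").
    """
    patch = lr.patch
    binary = patch > threshold
    out = np.zeros(lr.shape, dtype=bool)
    if not binary.any():
        return out
    labels, _ = ndimage.label(binary, structure=EIGHT)
    r = int(round(cp.centroid_rc[0])) - lr.offset_rc[0]
    c = int(round(cp.centroid_rc[1])) - lr.offset_rc[1]
    r = np.clip(r, 0, lr.shape[0] - 1)
    c = np.clip(c, 0, lr.shape[1] - 1)
    lab = labels[r, c]
    if lab == 0:
        # nearest suprathreshold component within the search radius
        dist, idx = ndimage.distance_transform_edt(labels == 0, return_indices=True)
        if dist[r, c] * lr.pixel_size_um > search_radius_um:
            return out
        lab = labels[idx[0][r, c], idx[1][r, c]]
    out[labels == lab] = True
    return out


def iterate_threshold(
    lr: LocalRegion,
    cp: CellPosition,
    params: SegmentationParams,
    start_threshold: float | None = None,
) -> CellMask:
    """Iterate the local threshold until the CCM area is within
    ``tcs_um2 ± tol_um2``.

    Starting from the Otsu estimate (or an explicit ``start_threshold``),
    each iteration measures the CCM area A_k and, if outside tolerance,
    updates T by ``step_gain · ē_k · (patch range)`` where ē_k is the
    running mean of the bounded relative errors
    ``(A_i − TCS) / max(A_i, TCS)``.  Averaging over all past iterations
    damps oscillation; bounding the error keeps a worst-case start (a
    threshold in the noise floor, where the component spans the whole LR)
    from pinning the threshold at the patch maximum.  The threshold is
    clamped inside the open patch intensity range.

    Stops: converged (area within tolerance), stagnation (``stability_runs``
    consecutive identical areas with a settled threshold — the fixed point
    of the iteration on quantized patches), or ``max_iter``.
    """
    patch = lr.patch
    lo, hi = float(patch.min()), float(patch.max())
    if hi == lo:
        raise DegenerateInputError("constant LR patch cannot be segmented")
    rng = hi - lo
    eps = 1e-9 * rng
    px_area = lr.pixel_size_um**2

    t = otsu_threshold(patch) if start_threshold is None else float(start_threshold)
    t = float(np.clip(t, lo + eps, hi - eps))
    log: list[tuple[float, float]] = []
    errors: list[float] = []
    mask = np.zeros(lr.shape, dtype=bool)
    converged = False

    for _ in range(params.max_iter):
        mask = candidate_mask(lr, t, cp)
        area = float(mask.sum()) * px_area
        log.append((t, area))
        if abs(area - params.tcs_um2) <= params.tol_um2:
            converged = True
            break
        if _stagnated(log, params.stability_runs, eps):
            break
        errors.append(
            (area - params.tcs_um2) / max(area, params.tcs_um2)
        )
        t = t + params.step_gain * float(np.mean(errors)) * rng
        t = float(np.clip(t, lo + eps, hi - eps))

    return CellMask(
        mask=mask,
        area_um2=log[-1][1],
        final_threshold=log[-1][0],
        n_iterations=len(log),
        converged=converged,
        iteration_log=log,
    )


def _stagnated(log: list[tuple[float, float]], runs: int, eps: float) -> bool:
    """Same area for ``runs`` consecutive iterations and a settled threshold."""
    if len(log) < runs:
        return False
    tail = log[-runs:]
    areas = {a for _, a in tail}
    if len(areas) != 1:
        return False
    thresholds = [t for t, _ in tail]
    return max(thresholds) - min(thresholds) <= eps


def find_soma_masks(
    cm: CellMask, lr: LocalRegion, params: SegmentationParams
) -> list[SomaMask]:
    """Contiguous bright sub-regions of the cell mask: candidate somata.

    Soma pixels exceed the final iterative threshold by ``soma_factor_x``
    (T_s = T_final × (1 + x)); candidates below ``min_soma_um2`` are
    discarded.
    """
    if cm.area_um2 <= 0:
        return []
    t_soma = cm.final_threshold * (1.0 + params.soma_factor_x)
    bright = cm.mask & (lr.patch > t_soma)
    if not bright.any():
        return []
    labels, n = ndimage.label(bright, structure=EIGHT)
    px_area = lr.pixel_size_um**2
    out = []
    for lab in range(1, n + 1):
        m = labels == lab
        area = float(m.sum()) * px_area
        if area >= params.min_soma_um2:
            r, c = ndimage.center_of_mass(m)
            out.append(SomaMask(mask=m, area_um2=area, centroid_rc=(float(r), float(c))))
    return out


def validate_cell(
    cm: CellMask, somas: list[SomaMask], lr: LocalRegion
) -> str:
    """Post-segmentation tests: border contact, then soma count.

    border_touch — any mask pixel on the LR window's outermost pixel ring
    (the cell extends beyond the LR and its area is unreliable);
    multi_soma — two or more somata (likely a dividing cell or unresolved
    pair); no_soma — none (cell body above/below the imaged slab);
    accepted otherwise.
    """
    m = cm.mask
    if m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any():
        return "border_touch"
    if len(somas) >= 2:
        return "multi_soma"
    if len(somas) == 0:
        return "no_soma"
    return "accepted"


def segment_projection(
    proj: Projection,
    channel: str = "egfp",
    params: SegmentationParams | None = None,
) -> list[CellRecord]:
    """Run detect → local region → iterate → soma → validate per CP.

    Cells whose iteration ends outside TCS ± tol are kept in the output
    with status ``not_converged_discard`` and excluded from any further
    analysis.  Accepted cells whose mask centroids fall within 5 µm of an
    accepted cell with a larger seed object are dropped as duplicates.
    Deterministic given identical input and parameters.
    """
    params = params or SegmentationParams()
    cps = find_cell_positions(
        proj,
        channel=channel,
        min_object_area_um2=params.min_object_area_um2,
        smooth_radius_px=params.smooth_radius_px,
        merge_distance_um=params.dedupe_distance_um,
    )
    records: list[CellRecord] = []
    for cp in cps:
        lr = extract_local_region(proj, cp, params)
        lr.channel = channel
        try:
            cm = iterate_threshold(lr, cp, params)
        except DegenerateInputError:
            records.append(
                CellRecord(cp, lr, None, [], status="not_converged_discard")
            )
            continue
        if not cm.converged:
            records.append(
                CellRecord(cp, lr, cm, [], status="not_converged_discard")
            )
            continue
        somas = find_soma_masks(cm, lr, params)
        status = validate_cell(cm, somas, lr)
        records.append(CellRecord(cp, lr, cm, somas, status=status))

    _dedupe_accepted(records, params.dedupe_distance_um, proj.pixel_size_um)
    return records


def mask_centroid_full(rec: CellRecord) -> tuple[float, float]:
    """Cell-mask centroid in full-image coordinates."""
    r, c = ndimage.center_of_mass(rec.cell_mask.mask)
    return (r + rec.local_region.offset_rc[0], c + rec.local_region.offset_rc[1])


def _dedupe_accepted(
    records: list[CellRecord], min_dist_um: float, pixel_size_um: float
) -> None:
    """Demote accepted records whose mask centroids crowd a larger seed."""
    accepted = [r for r in records if r.status == "accepted"]
    accepted.sort(key=lambda r: -r.cell_position.seed_object_area_um2)
    kept: list[np.ndarray] = []
    for rec in accepted:
        rc = np.array(mask_centroid_full(rec)) * pixel_size_um
        if any(np.linalg.norm(rc - k) < min_dist_um for k in kept):
            rec.status = "duplicate"
        else:
            kept.append(rc)
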