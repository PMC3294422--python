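"""Candidate cell-position detection via regional maxima.

A microglia field contains bright somata and dimmer processes over a noisy
background with slowly varying illumination.  Global thresholding at a
fixed intensity fails under such inhomogeneity, so the detector works on
*local contrast*: the lightly smoothed image divided by a coarse local
background estimate (window much larger than one cell).  On that ratio
image the background sits near 1 everywhere regardless of illumination,
while labeled cells stand several-fold higher.  All regional maxima of the
ratio image are found; the detection level is the *median* of their
plateau values — noise maxima vastly outnumber cell maxima, so the level
sits just above the noise ceiling — and the connected objects above it
whose area exceeds a physical minimum (default 50 µm²) each contribute one
candidate cell position (CP): the object's unweighted centroid.

Detection is invariant to multiplying the image by a positive constant
(the ratio image is unchanged) and, by locality, insensitive to smooth
illumination gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import local_maxima

from .stacks import Projection

#: structuring element for 8-connectivity on a 2D grid
EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class CellPosition:
    """One candidate cell: centroid of a detected maxima object."""

    id: int
    centroid_rc: tuple[float, float]
    seed_object_area_um2: float


def find_cell_positions(
    proj: Projection,
    channel: str = "egfp",
    min_object_area_um2: float = 50.0,
    smooth_radius_px: int = 1,
    merge_distance_um: float = 5.0,
    background_window_um: float = 80.0,
) -> list[CellPosition]:
    """Detect candidate cell positions in one projection channel.

    Returns one :class:`CellPosition` per retained object, ordered by
    descending seed-object area with ids sequential from 0.  A blank
    (constant) image yields an empty list.  CPs closer than
    ``merge_distance_um`` are merged, keeping the larger seed object, so a
    soma split by noise is not segmented twice.  ``background_window_um``
    sets the scale of the local background estimate; it should comfortably
    exceed one cell's footprint.
    """
    if channel not in proj.channels:
        raise KeyError(f"channel {channel!r} not in projection {proj.channel_names}")
    if min_object_area_um2 <= 0:
        raise ValueError("min_object_area_um2 must be positive")
    img = np.asarray(proj.channels[channel], dtype=float)
    if img.max() == img.min():
        return []

    if smooth_radius_px > 0:
        size = 2 * smooth_radius_px + 1
        smoothed = ndimage.uniform_filter(img, size=size, mode="nearest")
    else:
        smoothed = img

    # flush the filters' numerical dust so dark regions are exactly zero
    tiny = 1e-9 * float(smoothed.max())
    smoothed = np.where(smoothed < tiny, 0.0, smoothed)

    bg_size = max(3, int(round(background_window_um / proj.pixel_size_um)))
    background = np.maximum(
        ndimage.uniform_filter(smoothed, size=bg_size, mode="nearest"),
        max(1e-12, 1e-3 * float(np.mean(np.abs(smoothed)))),
    )
    contrast_s = smoothed / background

    maxima = local_maxima(contrast_s, connectivity=2)
    if not maxima.any():
        return []
    # noise maxima vastly outnumber cell maxima, so a robust outlier rule
    # on peak heights separates the two; when the only maxima are real
    # objects (dark background), MAD = 0 and the level is their plateau
    peaks = contrast_s[maxima]
    med = float(np.median(peaks))
    mad = float(np.median(np.abs(peaks - med)))
    level = (med + 3.0 * mad) * (1.0 - 1e-9)

    # objects are cut from the unsmoothed contrast: smoothing erodes the
    # rim of small plateaus, which matters against the area filter
    contrast = np.where(img < tiny, 0.0, img) / background
    labels, n = ndimage.label(contrast >= level, structure=EIGHT)
    if n == 0:
        return []
    px_area = proj.pixel_size_um**2
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(areas * px_area > min_object_area_um2) + 1
    if keep.size == 0:
        return []
    centroids = ndimage.center_of_mass(np.ones_like(labels), labels, index=keep)

    cps = sorted(
        (
            CellPosition(0, (float(r), float(c)), float(areas[lab - 1] * px_area))
            for lab, (r, c) in zip(keep, centroids)
        ),
        key=lambda cp: -cp.seed_object_area_um2,
    )
    cps = _merge_close(cps, merge_distance_um / proj.pixel_size_um)
    for i, cp in enumerate(cps):
        cp.id = i
    return cps


def _merge_close(cps: list[CellPosition], min_dist_px: float) -> list[CellPosition]:
    """Drop CPs within ``min_dist_px`` of an already-kept (larger) CP."""
    kept: list[CellPosition] = []
    for cp in cps:  # already sorted by descending seed area
        rc = np.array(cp.centroid_rc)
        if all(np.linalg.norm(rc - np.array(k.centroid_rc)) >= min_dist_px for k in kept):
            kept.append(cp)
    return kept
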