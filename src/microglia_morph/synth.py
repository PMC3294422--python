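"""Seeded synthetic microglia fields with ground truth, and evaluation.

The generator emulates the features of fluorescence micrographs that the
segmentation method is designed to survive: a bright soma inside each
cell, dim textured processes (resting, ramified regime) or an amoeboid
body (activated regime), a smooth illumination gradient that
multiplicatively scales signal, autofluorescence background and
shot-like Gaussian noise together, and a co-registered marker channel
whose per-cell intensity scales with activation.  Somata reach the 8-bit
ceiling and clip at 255 — as saturated somata do in real acquisitions —
which the threshold-relative pipeline is expected to tolerate.

Both shape regimes target a total footprint near the 500 µm² prior cell
size: processes are grown pixel-by-pixel until the sampled area target is
reached, so every in-regime cell *can* converge within the TCS tolerance.
The radial extent of any cell is capped at 19 µm, so a 40 µm center
separation guarantees disjoint supports.

Ground truth is the pre-noise rendered support; evaluation therefore
measures segmentation quality, not denoising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import PackingError
from .segment import (
    CellRecord,
    SegmentationParams,
    iterate_threshold,
    mask_centroid_full,
    otsu_threshold,
    segment_projection,
)
from .stacks import Projection

#: radial extent cap (µm): half the default 40 µm separation, minus margin
EXTENT_CAP_UM = 19.0
#: placement margin from the field edge (µm)
EDGE_MARGIN_UM = 25.0


@dataclass
class SyntheticCellSpec:
    """Shape and intensity parameters of one rendered cell.

    ``activation`` is 0 for the resting (ramified) regime and 1 for the
    activated (amoeboid) regime; intermediate values interpolate the
    marker level only.
    """

    state: str = "resting"                # "resting" | "activated"
    activation: float = 0.0
    soma_radius_um: float = 3.0
    n_processes: int = 6
    process_length_um: float = 40.0       # cap on path length per process
    process_width_px: int = 3
    soma_intensity: float = 225.0         # + background -> 8-bit ceiling
    process_intensity: float = 30.0       # added over background: dim processes
    intensity_jitter: float = 2.0         # per-pixel uniform ± texture, sub-noise
    target_area_um2: float = 500.0
    body_axis_ratio: float = 1.2          # activated body ellipse a/b

    @classmethod
    def resting(cls, rng: np.random.Generator) -> "SyntheticCellSpec":
        return cls(
            state="resting",
            activation=0.0,
            soma_radius_um=float(rng.uniform(2.5, 3.5)),
            n_processes=int(rng.integers(6, 9)),
            process_length_um=float(rng.uniform(30.0, 40.0)),
            target_area_um2=float(rng.uniform(460.0, 540.0)),
        )

    @classmethod
    def activated(cls, rng: np.random.Generator) -> "SyntheticCellSpec":
        return cls(
            state="activated",
            activation=1.0,
            soma_radius_um=float(rng.uniform(4.5, 6.0)),
            n_processes=int(rng.integers(0, 3)),
            process_length_um=float(rng.uniform(4.0, 10.0)),
            target_area_um2=float(rng.uniform(440.0, 500.0)),
            body_axis_ratio=float(rng.uniform(1.05, 1.3)),
        )


@dataclass
class TruthCell:
    spec: SyntheticCellSpec
    position_um: tuple[float, float]      # (row, col) of soma center
    mask: np.ndarray                      # full-field pre-noise support
    soma_mask: np.ndarray                 # full-field soma plateau support
    soma_area_um2: float
    marker_level: float
    touching: bool = False


@dataclass
class SyntheticField:
    channels: dict[str, np.ndarray]
    pixel_size_um: float
    cells: list[TruthCell]
    illumination: np.ndarray
    noise_sigma: float
    seed: int

    def projection(self) -> Projection:
        return Projection(dict(self.channels), pixel_size_um=self.pixel_size_um)


def _disk(radius_px: float, shape: tuple[int, int], center: tuple[float, float]):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def _ellipse(a_px, b_px, theta, shape, center):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    u = dr * math.cos(theta) + dc * math.sin(theta)
    v = -dr * math.sin(theta) + dc * math.cos(theta)
    return (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0


def render_cell(
    spec: SyntheticCellSpec, seed: int, pixel_size_um: float = 0.76
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one cell on a local canvas.

    Returns ``(patch, mask, soma_mask)``: the pre-noise intensity patch,
    its support, and the soma plateau disk.  Deterministic per seed.
    Processes are random-walk polylines of the stated width, grown
    round-robin until the footprint reaches the spec's area target (or
    every process reaches its length cap); the walk is steered back inward
    at the radial extent cap.
    """
    rng = np.random.default_rng(seed)
    px = pixel_size_um
    half = int(math.ceil((EXTENT_CAP_UM + 2.0) / px))
    side = 2 * half + 1
    center = (float(half), float(half))
    shape = (side, side)

    target_px = spec.target_area_um2 / px**2
    soma = _disk(spec.soma_radius_um / px, shape, center)

    if spec.state == "activated":
        a_um = math.sqrt(spec.target_area_um2 * spec.body_axis_ratio / math.pi)
        b_um = a_um / spec.body_axis_ratio
        theta = rng.uniform(0, math.pi)
        mask = _ellipse(a_um / px, b_um / px, theta, shape, center)
        mask |= soma
        mask = _grow_processes(
            mask, soma, spec, rng, px, center,
            target_px=mask.sum() + spec.n_processes * spec.process_length_um / px * spec.process_width_px,
        )
    else:
        mask = soma.copy()
        mask = _grow_processes(mask, soma, spec, rng, px, center, target_px=target_px)

    if not mask.any():
        raise ValueError("spec produced an empty mask")

    patch = np.zeros(shape, dtype=float)
    jitter = rng.uniform(-spec.intensity_jitter, spec.intensity_jitter, size=shape)
    patch[mask] = spec.process_intensity + jitter[mask]
    patch[soma] = spec.soma_intensity
    return patch, mask, soma


def _grow_processes(mask, soma, spec, rng, px, center, target_px):
    """Grow ``n_processes`` wiggly radial arms until the area target."""
    if spec.n_processes == 0:
        return mask
    mask = mask.copy()
    shape = mask.shape
    half_w = spec.process_width_px // 2
    max_steps = int(spec.process_length_um / px)
    cap_px = EXTENT_CAP_UM / px
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    # stamped pixels never exceed the radial cap, so the footprint of a
    # cell is guaranteed inside a disk of radius EXTENT_CAP_UM
    within_cap = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= cap_px**2

    base = rng.uniform(0, 2 * math.pi)
    angles = [
        base + 2 * math.pi * i / spec.n_processes + rng.uniform(-0.25, 0.25)
        for i in range(spec.n_processes)
    ]
    # each arm starts at the soma boundary along its base direction
    r0 = spec.soma_radius_um / px
    pos = [
        np.array([center[0] + r0 * math.sin(a), center[1] + r0 * math.cos(a)])
        for a in angles
    ]
    heading = list(angles)
    alive = [True] * spec.n_processes
    steps = [0] * spec.n_processes

    while any(alive) and mask.sum() < target_px:
        for i in range(spec.n_processes):
            if not alive[i]:
                continue
            heading[i] += rng.uniform(-0.35, 0.35)
            # steer back toward the base direction near the extent cap
            nxt = pos[i] + np.array([math.sin(heading[i]), math.cos(heading[i])])
            if np.linalg.norm(nxt - np.array(center)) > cap_px:
                heading[i] = math.atan2(
                    center[0] - pos[i][0], center[1] - pos[i][1]
                ) + rng.uniform(-0.5, 0.5)
                nxt = pos[i] + np.array([math.sin(heading[i]), math.cos(heading[i])])
            pos[i] = nxt
            steps[i] += 1
            r = int(round(pos[i][0]))
            c = int(round(pos[i][1]))
            window = (
                slice(max(r - half_w, 0), r + half_w + 1),
                slice(max(c - half_w, 0), c + half_w + 1),
            )
            mask[window] |= within_cap[window]
            if steps[i] >= max_steps:
                alive[i] = False
            if mask.sum() >= target_px:
                break
    return mask


def generate_field(
    n_cells: int = 20,
    field_um: float = 300.0,
    mix: float = 0.5,
    illumination_amp: float = 0.3,
    noise_sigma: float = 5.0,
    pixel_size_um: float = 0.76,
    min_separation_um: float = 40.0,
    seed: int = 0,
    bg_level: float = 30.0,
    marker_bg: float = 40.0,
    marker_level: float = 60.0,
    marker_gain: float = 0.5,
) -> SyntheticField:
    """Render a multi-channel field of ``n_cells`` with ground truth.

    Cells are placed by seeded rejection sampling honoring
    ``min_separation_um`` between centers (0 allows touching cells, which
    are labeled as such in the truth).  The EGFP channel is the sum of
    rendered cells scaled by a left-to-right linear illumination gradient
    of amplitude ``illumination_amp``, over a constant background with
    additive Gaussian noise, clipped to [0, 255].  The marker channel is a
    constant background plus each cell's footprint at
    ``marker_level × (1 + marker_gain × activation)`` plus noise.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if min_separation_um < 0:
        raise ValueError("min_separation_um must be >= 0")
    rng = np.random.default_rng(seed)
    px = pixel_size_um
    side = int(round(field_um / px))
    shape = (side, side)

    # placement by dart throwing inside the edge margin
    margin = EDGE_MARGIN_UM
    lo, hi = margin, field_um - margin
    if hi <= lo:
        raise PackingError(f"field {field_um} µm too small for margin {margin} µm")
    positions: list[np.ndarray] = []
    attempts = 0
    max_attempts = 2000 * n_cells
    while len(positions) < n_cells:
        if attempts > max_attempts:
            raise PackingError(
                f"could not place {n_cells} cells at separation "
                f"{min_separation_um} µm in a {field_um} µm field"
            )
        attempts += 1
        p = rng.uniform(lo, hi, size=2)
        if all(np.linalg.norm(p - q) >= min_separation_um for q in positions):
            positions.append(p)

    n_act = int(round(mix * n_cells))
    states = np.array(["activated"] * n_act + ["resting"] * (n_cells - n_act))
    states = states[rng.permutation(n_cells)]

    egfp_cells = np.zeros(shape, dtype=float)
    marker_cells = np.zeros(shape, dtype=float)
    cells: list[TruthCell] = []
    for pos_um, state in zip(positions, states):
        spec = (
            SyntheticCellSpec.activated(rng)
            if state == "activated"
            else SyntheticCellSpec.resting(rng)
        )
        patch, mask, soma = render_cell(
            spec, seed=int(rng.integers(0, 2**31)), pixel_size_um=px
        )
        full_mask = np.zeros(shape, dtype=bool)
        full_soma = np.zeros(shape, dtype=bool)
        r0 = int(round(pos_um[0] / px)) - patch.shape[0] // 2
        c0 = int(round(pos_um[1] / px)) - patch.shape[1] // 2
        sl = (slice(r0, r0 + patch.shape[0]), slice(c0, c0 + patch.shape[1]))
        egfp_cells[sl] = np.maximum(egfp_cells[sl], patch)
        full_mask[sl] = mask
        full_soma[sl] = soma
        level = marker_level * (1.0 + marker_gain * spec.activation)
        marker_cells[sl][mask] = level
        cells.append(
            TruthCell(
                spec=spec,
                position_um=(float(pos_um[0]), float(pos_um[1])),
                mask=full_mask,
                soma_mask=full_soma,
                soma_area_um2=float(soma.sum()) * px**2,
                marker_level=level,
            )
        )

    _label_touching(cells)

    cols = np.linspace(-1.0, 1.0, side)
    illumination = 1.0 + illumination_amp * np.tile(cols, (side, 1))
    # illumination is multiplicative on everything the detector sees —
    # signal, autofluorescence background and shot-like noise — so every
    # local region is an intensity-scaled copy of the same imaging model
    egfp = (egfp_cells + bg_level + rng.normal(0.0, noise_sigma, size=shape))
    egfp = np.clip(egfp * illumination, 0.0, 255.0)

    marker = (marker_bg + marker_cells + rng.normal(0.0, noise_sigma, size=shape))
    marker = np.clip(marker * illumination, 0.0, 255.0)

    return SyntheticField(
        channels={"egfp": egfp, "marker": marker},
        pixel_size_um=px,
        cells=cells,
        illumination=illumination,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def _label_touching(cells: list[TruthCell]) -> None:
    """Mark cells whose supports touch (8-adjacency) another cell's."""
    struct = np.ones((3, 3), bool)
    dilated = [ndimage.binary_dilation(c.mask, structure=struct) for c in cells]
    for i, ci in enumerate(cells):
        for j in range(i + 1, len(cells)):
            if np.any(dilated[i] & cells[j].mask):
                ci.touching = True
                cells[j].touching = True


@dataclass
class MatchScores:
    detection_rate: float         # matched / n_truth × 100
    mean_area_accuracy: float     # 100 − mean |ΔA|/A_truth × 100
    mean_soma_error_pct: float    # mean |Δsoma|/soma_truth × 100
    n_truth: int
    n_matched: int
    matches: list[tuple[int, int]] = field(default_factory=list)  # (truth, record)


def match_and_score(
    field_truth: SyntheticField,
    records: list[CellRecord],
    match_radius_um: float = 10.0,
) -> MatchScores:
    """Greedy nearest-first one-to-one matching of accepted records to truth.

    Ground truth stands in for the manual rater: detection rate is the
    fraction of true cells matched by an accepted record within
    ``match_radius_um``; area accuracy compares segmented to true mask
    areas per matched cell.
    """
    px = field_truth.pixel_size_um
    accepted = [r for r in records if r.status == "accepted"]
    truth_pos = np.array([c.position_um for c in field_truth.cells])
    n_truth = len(field_truth.cells)
    if not accepted or n_truth == 0:
        return MatchScores(0.0, 0.0, 0.0, n_truth, 0)

    rec_pos = np.array([np.array(mask_centroid_full(r)) * px for r in accepted])
    d = np.linalg.norm(truth_pos[:, None, :] - rec_pos[None, :, :], axis=2)
    pairs = sorted(
        ((d[i, j], i, j) for i in range(n_truth) for j in range(len(accepted))
         if d[i, j] <= match_radius_um)
    )
    used_t: set[int] = set()
    used_r: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, i, j in pairs:
        if i in used_t or j in used_r:
            continue
        used_t.add(i)
        used_r.add(j)
        matches.append((i, j))

    if not matches:
        return MatchScores(0.0, 0.0, 0.0, n_truth, 0)

    area_errs, soma_errs = [], []
    for i, j in matches:
        truth = field_truth.cells[i]
        rec = accepted[j]
        a_truth = float(truth.mask.sum()) * px**2
        a_auto = rec.cell_mask.area_um2
        area_errs.append(abs(a_auto - a_truth) / a_truth * 100.0)
        if rec.soma_mask is not None and truth.soma_area_um2 > 0:
            soma_errs.append(
                abs(rec.soma_mask.area_um2 - truth.soma_area_um2)
                / truth.soma_area_um2 * 100.0
            )
    return MatchScores(
        detection_rate=100.0 * len(matches) / n_truth,
        mean_area_accuracy=100.0 - float(np.mean(area_errs)),
        mean_soma_error_pct=float(np.mean(soma_errs)) if soma_errs else float("nan"),
        n_truth=n_truth,
        n_matched=len(matches),
        matches=matches,
    )


def s1_robustness(
    fields: SyntheticField | list[SyntheticField],
    params: SegmentationParams | None = None,
    n_cells_min: int = 200,
) -> float:
    """Worst-case start-threshold convergence statistic (percent).

    For every cell accepted under the default pipeline, the threshold
    iteration is rerun from half and from double the Otsu estimate; the
    statistic is the mean over cells of |A₁ − A₂| / mean(A₁, A₂) × 100.
    It is symmetric in the two starts by construction.
    """
    if isinstance(fields, SyntheticField):
        fields = [fields]
    params = params or SegmentationParams()
    diffs = []
    for fld in fields:
        proj = fld.projection()
        records = segment_projection(proj, "egfp", params)
        for rec in records:
            if rec.status != "accepted":
                continue
            lr = rec.local_region
            t0 = otsu_threshold(lr.patch)
            a1 = iterate_threshold(lr, rec.cell_position, params, start_threshold=t0 / 2).area_um2
            a2 = iterate_threshold(lr, rec.cell_position, params, start_threshold=t0 * 2).area_um2
            mean_a = (a1 + a2) / 2.0
            diffs.append(0.0 if mean_a == 0 else abs(a1 - a2) / mean_a * 100.0)
    if len(diffs) < n_cells_min:
        raise ValueError(
            f"only {len(diffs)} accepted cells; enlarge the cohort to reach "
            f"{n_cells_min}"
        )
    return float(np.mean(diffs))
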