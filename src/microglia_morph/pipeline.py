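"""End-to-end runs: configuration, orchestration, tabular/label output.

A :class:`RunConfig` carries every tunable (segmentation parameters,
projection settings, channel layout, output paths) and serializes to JSON
losslessly, so a run is reproducible from its config alone.  No hidden
global state: two pipelines with different configs in one process do not
interfere.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from ._version import __version__
from .errors import ConfigurationError
from .expression import quantify_expression
from .morphometry import compute_morphometrics
from .segment import (
    CellRecord,
    SegmentationParams,
    mask_centroid_full,
    segment_projection,
)
from .stacks import Projection, load_stack, project_slabs
from .synth import SyntheticField, generate_field, match_and_score

log = logging.getLogger("microglia_morph")


@dataclass
class RunConfig:
    """Everything needed for a deterministic pipeline run."""

    input_path: str | None = None
    pixel_size_um: float = 0.76
    z_step_um: float = 1.0
    channel_map: dict | None = None
    channel: str = "egfp"
    marker_channels: list[str] = field(default_factory=list)
    slab_um: float = 10.0
    gap_um: float = 20.0
    projection_mode: str = "maximum"
    params: SegmentationParams = field(default_factory=SegmentationParams)
    synthetic: dict | None = None         # kwargs for generate_field
    seed: int = 0
    out_dir: str = "."
    quiet: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.params, dict):
            self.params = SegmentationParams(**self.params)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())


def records_to_dataframe(
    records: list[CellRecord], pixel_size_um: float
) -> pd.DataFrame:
    """One row per candidate cell: position, status, iteration diagnostics."""
    rows = []
    for rec in records:
        cm = rec.cell_mask
        r, c = rec.cell_position.centroid_rc
        rows.append(
            {
                "cell_id": rec.cell_position.id,
                "status": rec.status,
                "row": r,
                "col": c,
                "seed_area_um2": rec.cell_position.seed_object_area_um2,
                "area_um2": cm.area_um2 if cm else np.nan,
                "final_threshold": cm.final_threshold if cm else np.nan,
                "n_iterations": cm.n_iterations if cm else 0,
                "converged": bool(cm.converged) if cm else False,
                "n_somas": len(rec.soma_masks),
            }
        )
    return pd.DataFrame(rows)


def morphometrics_dataframe(records: list[CellRecord]) -> pd.DataFrame:
    """Five shape parameters per accepted cell."""
    rows = []
    for rec in records:
        if rec.status != "accepted":
            continue
        m = compute_morphometrics(rec)
        r, c = rec.cell_position.centroid_rc
        rows.append(
            {
                "cell_id": rec.cell_position.id,
                "status": rec.status,
                "perimeter_um": m.perimeter_um,
                "spread_um": m.spread_um,
                "eccentricity": m.eccentricity,
                "roundness": m.roundness,
                "soma_size_um2": m.soma_size_um2,
                "row": r,
                "col": c,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id", "status", "perimeter_um", "spread_um", "eccentricity",
            "roundness", "soma_size_um2", "row", "col",
        ],
    )


def expression_dataframe(
    records: list[CellRecord], proj: Projection, channels: list[str]
) -> pd.DataFrame:
    """Tidy quotient-method ratios: one row per accepted cell and channel."""
    rows = []
    for rec in records:
        if rec.status != "accepted":
            continue
        for ch in channels:
            e = quantify_expression(rec, proj, ch)
            rows.append({"cell_id": e.cell_id, "channel": ch, "ratio": e.ratio})
    return pd.DataFrame(rows, columns=["cell_id", "channel", "ratio"])


def label_image(records: list[CellRecord], shape: tuple[int, int]) -> np.ndarray:
    """16-bit label image: 0 background, cell_id + 1 for accepted masks."""
    out = np.zeros(shape, dtype=np.uint16)
    for rec in records:
        if rec.status != "accepted":
            continue
        r0, r1, c0, c1 = rec.local_region.bounds_rc
        region = out[r0:r1, c0:c1]
        region[rec.cell_mask.mask] = rec.cell_position.id + 1
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run detect → segment → morphometrics → expression and write outputs.

    Input is either a calibrated TIFF stack (``config.input_path``) or a
    synthetic field (``config.synthetic`` kwargs, seeded by
    ``config.seed``).  Writes ``cells.csv``, ``morphometrics.csv``,
    ``expression.csv``, ``labels.tif`` and ``run_config.json`` under
    ``config.out_dir`` and returns the in-memory results.
    """
    _setup_logging(config.quiet)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("microglia-morph %s", __version__)
    log.info("parameters: %s", config.params.to_dict())

    truth: SyntheticField | None = None
    if config.synthetic is not None:
        kwargs = dict(config.synthetic)
        kwargs.setdefault("seed", config.seed)
        kwargs.setdefault("pixel_size_um", config.pixel_size_um)
        truth = generate_field(**kwargs)
        projections = [truth.projection()]
        log.info("generated synthetic field: %d cells", len(truth.cells))
    elif config.input_path is not None:
        stack = load_stack(
            config.input_path, config.pixel_size_um, config.z_step_um,
            config.channel_map,
        )
        projections = project_slabs(
            stack, config.slab_um, config.gap_um, config.projection_mode
        )
        log.info("loaded %s: %d slab projection(s)", config.input_path,
                 len(projections))
    else:
        raise ConfigurationError("config needs input_path or synthetic settings")

    cells_frames, morph_frames, expr_frames = [], [], []
    all_scores = []
    for k, proj in enumerate(projections):
        records = segment_projection(proj, config.channel, config.params)
        for rec in records:
            if rec.status != "accepted":
                log.debug("slab %d cell %d rejected: %s", k,
                          rec.cell_position.id, rec.status)
        cells = records_to_dataframe(records, proj.pixel_size_um)
        cells.insert(0, "slab", k)
        cells_frames.append(cells)
        morph = morphometrics_dataframe(records)
        morph.insert(0, "slab", k)
        morph_frames.append(morph)
        marker_chs = [c for c in config.marker_channels if c in proj.channels]
        expr = expression_dataframe(records, proj, marker_chs)
        expr.insert(0, "slab", k)
        expr_frames.append(expr)
        tifffile.imwrite(out_dir / f"labels_{k:02d}.tif",
                         label_image(records, proj.shape))
        if truth is not None:
            all_scores.append(match_and_score(truth, records))
        n_acc = int((cells["status"] == "accepted").sum())
        log.info("slab %d: %d candidates, %d accepted", k, len(cells), n_acc)

    results = {
        "cells": pd.concat(cells_frames, ignore_index=True),
        "morphometrics": pd.concat(morph_frames, ignore_index=True),
        "expression": pd.concat(expr_frames, ignore_index=True),
    }
    results["cells"].to_csv(out_dir / "cells.csv", index=False)
    results["morphometrics"].to_csv(out_dir / "morphometrics.csv", index=False)
    results["expression"].to_csv(out_dir / "expression.csv", index=False)
    (out_dir / "run_config.json").write_text(config.to_json())
    if all_scores:
        results["scores"] = all_scores
        for s in all_scores:
            log.info(
                "evaluation: detection %.1f%%, area accuracy %.1f%% "
                "(%d/%d matched)",
                s.detection_rate, s.mean_area_accuracy, s.n_matched, s.n_truth,
            )
    return results


def tcs_sweep(
    field_truth: SyntheticField,
    tcs_values,
    base_params: SegmentationParams | None = None,
) -> pd.DataFrame:
    """Sweep the target cell size and report detection and cohort separation.

    For each TCS the full pipeline runs on the field; rows report the
    number of accepted cells, the detection rate against truth, and —
    where both activation cohorts are represented among matched cells —
    the separation of soma size between activated and resting cohorts
    (difference of means over pooled SD).
    """
    base = base_params or SegmentationParams()
    proj = field_truth.projection()
    rows = []
    for tcs in tcs_values:
        params = dataclasses.replace(base, tcs_um2=float(tcs))
        records = segment_projection(proj, "egfp", params)
        accepted = [r for r in records if r.status == "accepted"]
        score = match_and_score(field_truth, records)
        somas = {"resting": [], "activated": []}
        for i, j in score.matches:
            rec = [r for r in records if r.status == "accepted"][j]
            somas[field_truth.cells[i].spec.state].append(rec.soma_mask.area_um2)
        sep = np.nan
        if len(somas["resting"]) >= 2 and len(somas["activated"]) >= 2:
            a, r = np.array(somas["activated"]), np.array(somas["resting"])
            pooled = np.sqrt((a.var(ddof=1) + r.var(ddof=1)) / 2.0)
            sep = (a.mean() - r.mean()) / pooled if pooled > 0 else np.inf
        rows.append(
            {
                "tcs_um2": tcs,
                "n_accepted": len(accepted),
                "detection_rate": score.detection_rate,
                "mean_area_accuracy": score.mean_area_accuracy,
                "soma_separation": sep,
            }
        )
    return pd.DataFrame(rows)


def _setup_logging(quiet: bool) -> None:
    if not log.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(h)
    log.setLevel(logging.WARNING if quiet else logging.INFO)
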