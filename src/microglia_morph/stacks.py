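"""Calibrated image stacks and 2D slab projections.

All downstream analysis (detection, segmentation, morphometry, expression)
runs on 2D projections of thin sub-volumes ("slabs").  The canonical
acquisition emulated here is a confocal/2-photon volume projected over the
top 10 µm, or — for deeper in vivo volumes — repeated 10 µm slabs separated
by 20 µm gaps so that no cell (soma diameter ≈ 10 µm) appears in two
projections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import ConfigurationError


@dataclass
class ImageStack:
    """Calibrated 3D multi-channel intensity volume.

    Parameters
    ----------
    channels : dict of str -> ndarray
        One (z, row, col) non-negative intensity grid per channel name.
    pixel_size_um : float
        Lateral calibration in µm/pixel (x and y).
    z_step_um : float
        Axial spacing between planes in µm.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    z_step_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")
        if self.z_step_um <= 0:
            raise ConfigurationError("z_step_um must be positive")
        shapes = {np.asarray(v).shape for v in self.channels.values()}
        if len(shapes) > 1:
            raise ConfigurationError(f"channels differ in shape: {shapes}")
        for name, vol in self.channels.items():
            vol = np.asarray(vol)
            if vol.ndim != 3:
                raise ConfigurationError(f"channel {name!r} is not 3D")
            if np.any(vol < 0):
                raise ConfigurationError(f"channel {name!r} has negative intensities")
            self.channels[name] = vol

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def n_planes(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def depth_um(self) -> float:
        """Total axial extent covered by the planes (n_planes × z_step)."""
        return self.n_planes * self.z_step_um


@dataclass
class Projection:
    """Calibrated 2D image per channel, produced from one slab of a stack."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    slab_start_um: float = 0.0
    slab_end_um: float = 0.0
    projection_mode: str = "maximum"

    def __post_init__(self) -> None:
        for name, img in self.channels.items():
            self.channels[name] = np.asarray(img, dtype=float)

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def save(self, path, channel: str | None = None) -> None:
        """Write one channel (or a (c, r, c) array of all) as a TIFF."""
        if channel is not None:
            tifffile.imwrite(path, self.channels[channel].astype(np.float32))
        else:
            arr = np.stack([self.channels[c] for c in self.channel_names])
            tifffile.imwrite(path, arr.astype(np.float32))


def load_stack(
    path,
    pixel_size_um: float,
    z_step_um: float,
    channel_map: dict[str, object] | None = None,
) -> ImageStack:
    """Read a calibrated stack from TIFF file(s).

    ``channel_map`` maps channel names either to page indices within a
    single multi-page grayscale TIFF at ``path`` (``{"egfp": [0, 2, 4]}``
    or ``{"egfp": 0}`` meaning every ``n_channels``-th page starting at 0),
    or to separate single-channel TIFF paths (``{"egfp": "a.tif"}``).
    With ``channel_map=None`` the whole file is read as one channel
    named ``"egfp"``.  Intensities are preserved bit-exactly.
    """
    if pixel_size_um <= 0 or z_step_um <= 0:
        raise ConfigurationError("calibration values must be positive")

    if channel_map is not None and all(
        isinstance(v, (str,)) or hasattr(v, "__fspath__") for v in channel_map.values()
    ):
        channels = {}
        for name, p in channel_map.items():
            try:
                vol = tifffile.imread(p)
            except (OSError, ValueError) as exc:
                raise OSError(f"cannot read TIFF {p!r}: {exc}") from exc
            channels[name] = _as_volume(vol, name)
        return ImageStack(channels, pixel_size_um, z_step_um)

    try:
        data = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF {path!r}: {exc}") from exc

    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ConfigurationError(
            f"{path!r} has shape {data.shape}; RGB/multi-sample TIFFs need an "
            "explicit channel_map with one file per channel"
        )

    if channel_map is None:
        return ImageStack({"egfp": data}, pixel_size_um, z_step_um)

    n_pages = data.shape[0]
    channels = {}
    for name, pages in channel_map.items():
        if isinstance(pages, int):
            pages = list(range(pages, n_pages, len(channel_map)))
        pages = list(pages)
        if any(p < 0 or p >= n_pages for p in pages):
            raise ConfigurationError(
                f"channel_map for {name!r} references pages outside 0..{n_pages - 1}"
            )
        channels[name] = data[pages]
    return ImageStack(channels, pixel_size_um, z_step_um)


def slab_starts(depth_um: float, slab_um: float, gap_um: float) -> list[float]:
    """Slab start depths: 0, slab+gap, 2(slab+gap), ... below ``depth_um``,
    dropping a trailing slab with less than ``slab_um / 2`` of volume left."""
    period = slab_um + gap_um
    starts = []
    s = 0.0
    while s < depth_um:
        if depth_um - s >= slab_um / 2:
            starts.append(s)
        s += period
    return starts


def project_slabs(
    stack: ImageStack,
    slab_um: float = 10.0,
    gap_um: float = 20.0,
    mode: str = "maximum",
) -> list[Projection]:
    """Project a stack into an ordered list of 2D slab projections.

    Slabs of thickness ``slab_um`` start at depth 0 and repeat with period
    ``slab_um + gap_um``; a plane at index i has depth ``i * z_step_um`` and
    belongs to the slab whose half-open interval [start, start + slab_um)
    contains it.  The gap guarantees no plane contributes twice.
    """
    if mode not in ("maximum", "mean"):
        raise ConfigurationError(f"unknown projection mode {mode!r}")
    if slab_um < stack.z_step_um:
        raise ConfigurationError("slab_um must be at least one z step")
    if stack.depth_um < slab_um:
        warnings.warn(
            f"stack depth {stack.depth_um} µm is thinner than one "
            f"{slab_um} µm slab; returning no projections",
            stacklevel=2,
        )
        return []

    depths = np.arange(stack.n_planes) * stack.z_step_um
    reduce = np.max if mode == "maximum" else np.mean
    out = []
    for start in slab_starts(stack.depth_um, slab_um, gap_um):
        in_slab = (depths >= start) & (depths < start + slab_um)
        if not in_slab.any():
            continue
        chans = {
            name: reduce(vol[in_slab], axis=0).astype(float)
            for name, vol in stack.channels.items()
        }
        out.append(
            Projection(
                chans,
                pixel_size_um=stack.pixel_size_um,
                slab_start_um=float(start),
                slab_end_um=float(start + slab_um),
                projection_mode=mode,
            )
        )
    return out


def _as_volume(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ConfigurationError(f"channel {name!r} file is not a grayscale stack")
    return arr
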