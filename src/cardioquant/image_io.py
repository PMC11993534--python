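"""Reading multichannel fluorescence TIFFs and shared preprocessing.

A micrograph is represented as a :class:`MultichannelImage` holding up to
three registered single-channel rasters, one per stain role:

* ``nuclear`` — DAPI (conventionally the blue plane of an RGB composite),
* ``matrix``  — WGA membrane/extracellular staining (red plane),
* ``vessel``  — isolectin-B4 endothelial staining (green plane).

All intensities are normalized to floating point on ``[0, 1]`` by the
bit-depth maximum at load time; every downstream operation works on that
scale.  Preprocessing consists of contrast-limited adaptive histogram
equalization (CLAHE) followed by Gaussian smoothing; both are exposed here
as free functions so segmentation of each channel can compose them as
needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage import exposure

from .errors import (
    ConfigError,
    FormatError,
    InputError,
    MissingChannelError,
    ParameterError,
)

ROLES = ("nuclear", "matrix", "vessel")

#: Conventional RGB assignment: DAPI=blue, WGA=red, isolectin B4=green.
DEFAULT_CHANNEL_MAP: dict[str, int | str] = {"nuclear": "B", "matrix": "R", "vessel": "G"}

_LETTER_TO_INDEX = {"R": 0, "G": 1, "B": 2}


@dataclass
class MultichannelImage:
    """Registered stain rasters of one field of view.

    Rasters are ``float64`` arrays on ``[0, 1]`` sharing one shape; a role
    that was not loaded is ``None`` and operations requiring it raise
    :class:`~cardioquant.errors.MissingChannelError`.
    """

    nuclear: np.ndarray | None = None
    matrix: np.ndarray | None = None
    vessel: np.ndarray | None = None
    channel_map: dict[str, int | str] = field(default_factory=dict)
    pixel_size: float | None = None  # µm/px, optional; outputs stay in px (a.u.)

    def __post_init__(self) -> None:
        shapes = {r.shape for r in (self.nuclear, self.matrix, self.vessel) if r is not None}
        if len(shapes) > 1:
            raise InputError(f"channel rasters disagree in shape: {sorted(shapes)}")
        for name in ROLES:
            r = getattr(self, name)
            if r is not None and r.size and (r.min() < -1e-9 or r.max() > 1 + 1e-9):
                raise InputError(f"{name} raster not normalized to [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        for name in ROLES:
            r = getattr(self, name)
            if r is not None:
                return r.shape
        raise MissingChannelError("image holds no channel at all")

    @property
    def height(self) -> int:
        return self.shape[0]

    @property
    def width(self) -> int:
        return self.shape[1]

    def require(self, role: str) -> np.ndarray:
        """Return the raster for *role* or fail fast if it was not loaded."""
        if role not in ROLES:
            raise ConfigError(f"unknown channel role {role!r}; expected one of {ROLES}")
        raster = getattr(self, role)
        if raster is None:
            raise MissingChannelError(f"required channel role {role!r} is absent")
        return raster


def _normalize_plane(plane: np.ndarray) -> np.ndarray:
    if np.issubdtype(plane.dtype, np.unsignedinteger):
        maxval = float(np.iinfo(plane.dtype).max)
        return plane.astype(np.float64) / maxval
    if np.issubdtype(plane.dtype, np.floating):
        out = plane.astype(np.float64)
        if out.size and (out.min() < 0 or out.max() > 1):
            raise FormatError("floating-point TIFF planes must already lie in [0, 1]")
        return out
    raise FormatError(f"unsupported TIFF sample dtype {plane.dtype}")


def _resolve_plane(data: np.ndarray, spec: int | str) -> np.ndarray:
    """Extract one plane from a 2-D or 3-D TIFF array."""
    if data.ndim == 2:
        if spec in ("R", "G", "B"):
            raise ConfigError(f"letter channel spec {spec!r} on a single-plane image")
        if int(spec) != 0:
            raise ConfigError(f"channel index {spec} out of range for single-plane image")
        return data
    if data.ndim != 3:
        raise FormatError(f"expected a 2-D or 3-D raster, got ndim={data.ndim}")
    # channels-last (H, W, C) for small C, else channels-first (C, H, W)
    if data.shape[-1] <= 4:
        planes, n = np.moveaxis(data, -1, 0), data.shape[-1]
    else:
        planes, n = data, data.shape[0]
    if isinstance(spec, str):
        if spec not in _LETTER_TO_INDEX:
            raise ConfigError(f"unknown channel letter {spec!r}")
        idx = _LETTER_TO_INDEX[spec]
        if n < 3:
            raise ConfigError(f"letter channel spec {spec!r} needs >= 3 planes, found {n}")
    else:
        idx = int(spec)
    if not 0 <= idx < n:
        raise ConfigError(f"channel index {idx} out of range for {n} planes")
    return planes[idx]


def load_image(
    path: str | Path,
    channel_map: dict[str, int | str] | None = None,
    pixel_size: float | None = None,
) -> MultichannelImage:
    """Load a TIFF and distribute its planes onto stain roles.

    Parameters
    ----------
    path:
        TIFF file, single- or multi-plane, 8- or 16-bit.
    channel_map:
        Maps each role in ``{"nuclear", "matrix", "vessel"}`` to a plane,
        either an integer index or one of the letters ``"R"/"G"/"B"`` for
        RGB composites.  Roles may be omitted (or mapped to ``None``) for
        partial analyses.  Defaults to blue=nuclear, red=matrix,
        green=vessel.
    """
    path = Path(path)
    if channel_map is None:
        channel_map = dict(DEFAULT_CHANNEL_MAP)
    unknown = set(channel_map) - set(ROLES)
    if unknown:
        raise ConfigError(f"unknown channel roles in map: {sorted(unknown)}")
    try:
        data = tifffile.imread(path)
    except FileNotFoundError as exc:
        raise InputError(f"TIFF not found: {path}") from exc
    except Exception as exc:  # tifffile raises assorted types on corrupt files
        raise InputError(f"cannot read TIFF {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2 and set(channel_map.values()) - {None} == {"R", "G", "B"} & set(
        channel_map.values()
    ):
        pass  # handled per-role below
    rasters: dict[str, np.ndarray | None] = {}
    for role in ROLES:
        spec = channel_map.get(role)
        if spec is None:
            rasters[role] = None
            continue
        rasters[role] = _normalize_plane(_resolve_plane(data, spec))
    if all(r is None for r in rasters.values()):
        raise ConfigError("channel map assigns no role at all")
    return MultichannelImage(
        nuclear=rasters["nuclear"],
        matrix=rasters["matrix"],
        vessel=rasters["vessel"],
        channel_map=dict(channel_map),
        pixel_size=pixel_size,
    )


def write_raster(path: str | Path, raster: np.ndarray, bit_depth: int = 8) -> None:
    """Write a ``[0, 1]`` raster as an 8- or 16-bit single-plane TIFF."""
    if bit_depth not in (8, 16):
        raise ParameterError(f"bit_depth must be 8 or 16, got {bit_depth}")
    raster = np.asarray(raster, dtype=np.float64)
    if raster.size and (raster.min() < -1e-9 or raster.max() > 1 + 1e-9):
        raise InputError("raster must lie in [0, 1] before quantization")
    maxval = 255 if bit_depth == 8 else 65535
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    tifffile.imwrite(Path(path), np.round(raster * maxval).astype(dtype))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit TIFF with values 0/255."""
    tifffile.imwrite(Path(path), np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def equalize_clahe(
    raster: np.ndarray,
    clip_limit: float = 0.01,
    tile_grid: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a ``[0,1]`` raster.

    Tile-wise equalization with clipped histograms; flat rasters are
    returned unchanged (there is no contrast to enhance, and equalizing a
    constant is the identity by convention).
    """
    raster = np.asarray(raster, dtype=np.float64)
    if raster.size == 0:
        raise InputError("empty raster")
    if clip_limit <= 0:
        raise ParameterError("clip_limit must be > 0")
    rows, cols = tile_grid
    if rows < 1 or cols < 1:
        raise ParameterError("tile_grid must be >= (1, 1)")
    if np.ptp(raster) == 0:
        return raster.copy()
    kernel = (max(raster.shape[0] // rows, 1), max(raster.shape[1] // cols, 1))
    out = exposure.equalize_adapthist(raster, kernel_size=kernel, clip_limit=clip_limit)
    return np.clip(out, 0.0, 1.0)


def gaussian_smooth(raster: np.ndarray, sigma: float = 1.5) -> np.ndarray:
    """Gaussian noise suppression with reflective boundary handling."""
    if sigma < 0:
        raise ParameterError(f"sigma must be >= 0, got {sigma}")
    raster = np.asarray(raster, dtype=np.float64)
    if sigma == 0:
        return raster.copy()
    return ndi.gaussian_filter(raster, sigma=sigma, mode="reflect")
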