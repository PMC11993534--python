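"""Binary segmentation of nuclei, WGA matrix staining, and vessels.

Fluorescence micrographs carry smooth illumination inhomogeneity, so a
single global threshold either drowns dim regions or floods bright ones.
All channels are therefore segmented with a *local-mean adaptive
threshold*: a pixel is foreground iff its intensity exceeds the mean over
a sliding window, scaled up by a sensitivity offset.

For nuclei the sensitivity is not fixed but selected per image by a sweep:
at permissive settings noise inflates the number of segmented regions; as
the threshold rises the count falls to a plateau at the true nucleus
count; pushing further disconnects nuclei into bright-chromatin fragments
and the count rises again.  The selected sensitivity is the low point of
this U-shaped region-count curve (after light smoothing), tie-broken
toward the permissive side so nuclei are not split into euchromatin and
heterochromatin islands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, segmentation as skseg

from .errors import ParameterError, SegmentationError
from .image_io import MultichannelImage, equalize_clahe, gaussian_smooth

logger = logging.getLogger(__name__)

#: 8-connectivity — robust to 1-px diagonal necks in rasterized ellipses.
_STRUCTURE = np.ones((3, 3), dtype=bool)


@dataclass
class LabelMap:
    """Connected-component labeling of one segmented channel.

    ``labels`` is an integer raster with 0 = background and consecutive ids
    ``1..n_objects`` for the 8-connected foreground components.
    """

    labels: np.ndarray
    n_objects: int
    source_role: str

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def __post_init__(self) -> None:
        present = np.unique(self.labels)
        present = present[present > 0]
        if len(present) != self.n_objects or (
            len(present) and present.max() != self.n_objects
        ):
            raise SegmentationError("labels must be consecutive 1..n_objects")


@dataclass
class ThresholdSweepResult:
    """Region-count curve of a sensitivity sweep and the selected low point."""

    sensitivities: np.ndarray
    region_counts: np.ndarray
    smoothed_counts: np.ndarray
    selected_sensitivity: float

    def __post_init__(self) -> None:
        if len(self.sensitivities) != len(self.region_counts):
            raise ParameterError("sensitivities and region_counts must align")


def default_window(shape: tuple[int, int]) -> int:
    """Adaptive-threshold window: 1/8 of the smaller image side, forced odd."""
    w = max(min(shape) // 8, 3)
    return w if w % 2 == 1 else w + 1


def adaptive_threshold(
    raster: np.ndarray,
    window: int | None = None,
    sensitivity: float = 0.0,
) -> np.ndarray:
    """Local-mean threshold: foreground iff I > local_mean * (1 + sensitivity).

    The neighbourhood statistic is the plain mean over a ``window``-sized
    square with reflective borders.  Deterministic.
    """
    raster = np.asarray(raster, dtype=np.float64)
    if window is None:
        window = default_window(raster.shape)
    if window < 3 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 3, got {window}")
    if window > min(raster.shape):
        raise ParameterError(
            f"window {window} exceeds smallest image dimension {min(raster.shape)}"
        )
    local_mean = ndi.uniform_filter(raster, size=window, mode="reflect")
    # floor guards against floating-point dust in the filtered mean turning
    # exactly-zero background into foreground
    return raster > np.maximum(local_mean * (1.0 + sensitivity), 1e-9)


def remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Drop 8-connected components with area < min_area (kept iff >=)."""
    if min_area <= 0:
        return mask
    labels, n = ndi.label(mask, structure=_STRUCTURE)
    if n == 0:
        return mask
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[labels]


def _count_regions(mask: np.ndarray, min_area: int) -> int:
    _, n = ndi.label(remove_small(mask, min_area), structure=_STRUCTURE)
    return int(n)


def select_threshold_lowpoint(
    raster: np.ndarray,
    sweep: np.ndarray | None = None,
    window: int | None = None,
    min_area: int = 50,
) -> ThresholdSweepResult:
    """Sweep the threshold sensitivity and pick the region-count low point.

    For each sensitivity the raster is thresholded, objects below
    ``min_area`` are dropped, and 8-connected components are counted.  The
    count curve is smoothed with a moving median of width 3 so single-point
    noise minima cannot hijack the selection, and the *lowest* sensitivity
    attaining the global minimum of the smoothed curve is chosen.
    Sensitivities whose segmentation is empty are excluded from the
    minimum search (an empty image is a failure, not a low point).
    """
    raster = np.asarray(raster, dtype=np.float64)
    if sweep is None:
        sweep = np.linspace(0.0, 0.5, 21)
    sweep = np.asarray(sweep, dtype=np.float64)
    if len(sweep) < 5:
        raise ParameterError("sweep must contain at least 5 sensitivities")
    counts = np.array(
        [_count_regions(adaptive_threshold(raster, window, s), min_area) for s in sweep]
    )
    if not (counts > 0).any():
        raise SegmentationError("all swept thresholds yield zero objects")
    smoothed = ndi.median_filter(counts.astype(float), size=3, mode="nearest")
    valid = counts > 0
    best = smoothed[valid].min()
    selected = float(sweep[valid & (smoothed == best)][0])
    return ThresholdSweepResult(
        sensitivities=sweep,
        region_counts=counts,
        smoothed_counts=smoothed,
        selected_sensitivity=selected,
    )


def _finalize_labels(mask: np.ndarray, min_area: int, source_role: str) -> LabelMap:
    mask = ndi.binary_fill_holes(mask)
    mask = remove_small(mask, min_area)
    labels, n = ndi.label(mask, structure=_STRUCTURE)
    return LabelMap(labels=labels, n_objects=int(n), source_role=source_role)


def segment_nuclei(
    img: MultichannelImage,
    clahe_clip: float = 0.01,
    clahe_grid: tuple[int, int] = (8, 8),
    sigma: float = 1.5,
    window: int | None = None,
    sweep: np.ndarray | None = None,
    min_area: int = 50,
    exclude_border: bool = True,
) -> tuple[LabelMap, ThresholdSweepResult]:
    """Full nuclear segmentation of the DAPI channel.

    Pipeline: CLAHE -> Gaussian smoothing -> sensitivity sweep with
    low-point selection -> adaptive threshold at the selected sensitivity
    -> hole filling -> minimum-area filter -> optional removal of
    border-touching nuclei (partial nuclei bias area and eccentricity) ->
    8-connected labeling.
    """
    raster = img.require("nuclear")
    pre = gaussian_smooth(equalize_clahe(raster, clahe_clip, clahe_grid), sigma)
    sweep_result = select_threshold_lowpoint(pre, sweep, window, min_area)
    mask = adaptive_threshold(pre, window, sweep_result.selected_sensitivity)
    mask = ndi.binary_fill_holes(mask)
    mask = remove_small(mask, min_area)
    if exclude_border:
        mask = skseg.clear_border(mask)
    labels, n = ndi.label(mask, structure=_STRUCTURE)
    return LabelMap(labels=labels, n_objects=int(n), source_role="nuclear"), sweep_result


def segment_matrix(
    img: MultichannelImage,
    window: int | None = None,
    sensitivity: float = 0.05,
    sigma: float = 1.0,
) -> np.ndarray:
    """Binary mask of the WGA membrane/matrix network.

    The WGA network spans the whole image, so there is no object-level
    minimum-size filter; the mask is used as-is for rotation histograms,
    texture, and thickness.
    """
    raster = img.require("matrix")
    mask = adaptive_threshold(gaussian_smooth(raster, sigma), window, sensitivity)
    if not mask.any():
        logger.warning("matrix channel segmentation produced an empty mask")
    return mask


def segment_vessels(
    img: MultichannelImage,
    sigma: float = 1.0,
    min_area: int = 50,
) -> LabelMap:
    """Label vessel cross-sections: threshold, fill lumina, drop debris.

    Vessels are compact bright blobs on a dark field, so the channel
    histogram is bimodal and a global Otsu threshold places the boundary
    halfway up the edge ramp — on the geometric vessel outline.
    """
    raster = img.require("vessel")
    smoothed = gaussian_smooth(raster, sigma)
    if np.ptp(smoothed) == 0:
        raise SegmentationError("vessel channel is constant; nothing to segment")
    mask = smoothed > filters.threshold_otsu(smoothed)
    return _finalize_labels(mask, min_area, "vessel")


def relabel(labels: np.ndarray, keep: np.ndarray, source_role: str) -> LabelMap:
    """Restrict a label raster to the ids in *keep* and relabel 1..n."""
    keep = np.asarray(sorted(set(int(k) for k in keep)))
    out = np.zeros_like(labels)
    for new, old in enumerate(keep, start=1):
        out[labels == old] = new
    return LabelMap(labels=out, n_objects=len(keep), source_role=source_role)


__all__ = [
    "LabelMap",
    "ThresholdSweepResult",
    "adaptive_threshold",
    "default_window",
    "select_threshold_lowpoint",
    "segment_nuclei",
    "segment_matrix",
    "segment_vessels",
    "relabel",
]
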