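"""Vessel architecture metrics and cardiomyocyte-selective nucleus analysis.

The isolectin-B4 channel marks endothelium, so labeled vessel
cross-sections give a density/size/spacing profile of the capillary bed.
The same channel drives *selective* nuclear analysis: endothelial nuclei
sit on vessels, cardiomyocyte nuclei between them, so a nucleus is kept as
cardiomyocyte iff the Euclidean distance from its centroid to the nearest
vessel pixel is at least a proximity threshold.  The centroid (not the
whole footprint) is tested so a large cardiomyocyte nucleus that merely
grazes a vessel is not discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import measure

from .errors import EmptySampleError, InputError
from .image_io import MultichannelImage
from .morphometry import (
    MorphometrySummary,
    NucleusFeature,
    summarize_morphometry,
)
from .orientation import OrientationSummary, summarize_orientation
from .segmentation import LabelMap
from .texture import DEFAULT_OFFSETS, TextureDescriptors, haralick_descriptors, masked_glcm

logger = logging.getLogger(__name__)


@dataclass
class VesselSummary:
    n_vessels: int
    total_area: float
    median_size: float
    mean_size: float
    sd_size: float
    relative_sd_size: float
    nearest_neighbor_distances: list[float] = field(default_factory=list)


@dataclass
class CardioSelection:
    kept_labels: list[int]
    excluded_labels: list[int]
    distance_at_centroid: dict[int, float]
    threshold_used: float


@dataclass
class SelectiveSummary:
    """Morphometry, texture, and orientation restricted to kept nuclei."""

    morphometry: MorphometrySummary
    texture: TextureDescriptors
    orientation: OrientationSummary
    selective: bool = True


def vessel_metrics(vessels: LabelMap) -> VesselSummary:
    """Count, size distribution (population SD), and centroid spacing.

    An empty label map is a valid avascular field of view and yields zero
    counts with empty distributions.
    """
    props = measure.regionprops(vessels.labels)
    if not props:
        return VesselSummary(0, 0.0, 0.0, 0.0, 0.0, 0.0, [])
    areas = np.array([p.area for p in props], dtype=np.float64)
    centroids = np.array([p.centroid for p in props], dtype=np.float64)
    mean_size = float(areas.mean())
    sd_size = float(areas.std(ddof=0))
    if len(props) >= 2:
        tree = cKDTree(centroids)
        dist, _ = tree.query(centroids, k=2)
        nn = [float(d) for d in dist[:, 1]]
    else:
        nn = []
    return VesselSummary(
        n_vessels=len(props),
        total_area=float(areas.sum()),
        median_size=float(np.median(areas)),
        mean_size=mean_size,
        sd_size=sd_size,
        relative_sd_size=sd_size / mean_size if mean_size > 0 else 0.0,
        nearest_neighbor_distances=nn,
    )


def select_cardiomyocyte_nuclei(
    features: list[NucleusFeature],
    vessel_mask: np.ndarray,
    proximity_threshold: float = 15.0,
    image_shape: tuple[int, int] | None = None,
) -> CardioSelection:
    """Partition nuclei into cardiomyocyte (kept) and peri-vascular (excluded).

    A nucleus is kept iff the Euclidean distance transform of the
    vessel-free region, evaluated at its centroid, is at least
    ``proximity_threshold`` pixels.  An empty vessel mask keeps every
    nucleus (with a logged warning): there is nothing to exclude against.
    """
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if image_shape is not None and vessel_mask.shape != tuple(image_shape):
        raise InputError(
            f"vessel mask shape {vessel_mask.shape} != image shape {tuple(image_shape)}"
        )
    if vessel_mask.any():
        dist = ndi.distance_transform_edt(~vessel_mask)
    else:
        logger.warning("empty vessel mask: keeping all nuclei")
        dist = np.full(vessel_mask.shape, np.inf)
    kept, excluded, distances = [], [], {}
    nrow, ncol = vessel_mask.shape
    for f in features:
        r = int(np.clip(round(f.centroid[1]), 0, nrow - 1))
        c = int(np.clip(round(f.centroid[0]), 0, ncol - 1))
        d = float(dist[r, c])
        distances[f.label] = d
        (kept if d >= proximity_threshold else excluded).append(f.label)
    return CardioSelection(
        kept_labels=kept,
        excluded_labels=excluded,
        distance_at_centroid=distances,
        threshold_used=float(proximity_threshold),
    )


def selective_summaries(
    selection: CardioSelection,
    features: list[NucleusFeature],
    img: MultichannelImage,
    labels: LabelMap,
    n_levels: int = 8,
    offsets=DEFAULT_OFFSETS,
    ocp_direction_deg: float = 90.0,
    ocp_cone_half_angle_deg: float = 45.0,
    ocp_max_distance: float = 150.0,
) -> SelectiveSummary:
    """Re-run the per-image summaries on the cardiomyocyte subset only."""
    kept = set(selection.kept_labels)
    if not kept:
        raise EmptySampleError(
            f"selection kept no nucleus ({len(selection.excluded_labels)} excluded "
            f"at threshold {selection.threshold_used})"
        )
    kept_features = [f for f in features if f.label in kept]
    morph = summarize_morphometry(kept_features)
    mask = np.isin(labels.labels, sorted(kept))
    texture = haralick_descriptors(masked_glcm(img.require("nuclear"), mask, n_levels, offsets))
    orient = summarize_orientation(
        kept_features, ocp_direction_deg, ocp_cone_half_angle_deg, ocp_max_distance
    )
    return SelectiveSummary(morphometry=morph, texture=texture, orientation=orient)


__all__ = [
    "VesselSummary",
    "CardioSelection",
    "SelectiveSummary",
    "vessel_metrics",
    "select_cardiomyocyte_nuclei",
    "selective_summaries",
]
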