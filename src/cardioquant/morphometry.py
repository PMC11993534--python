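"""Per-nucleus shape and intensity features, and per-image summaries.

Each labeled nucleus is reduced to the parameters of its inertia-equivalent
ellipse (second central moments of the pixel set): area, centroid,
orientation, eccentricity, and axis lengths, plus intensity statistics
taken from the *raw* (pre-CLAHE) raster so equalization cannot contaminate
staining-intensity comparisons across samples.

Orientation convention: the angle θ of the major axis against the image
horizontal, in degrees on (−90, +90], counterclockwise positive in a y-up
frame.  Orientation is axial — θ and θ+180° describe the same nucleus.

Eccentricity uses the standard ellipse definition
``sqrt(1 − (minor/major)²)``: 0 is a circle, values toward 1 are elongated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .errors import EmptySampleError, InputError
from .segmentation import LabelMap


@dataclass
class NucleusFeature:
    label: int
    area: float  # pixels (a.u.)
    centroid: tuple[float, float]  # (x, y) = (col, row), subpixel
    orientation_deg: float  # (−90, +90], major axis vs horizontal, y-up CCW
    eccentricity: float
    major_axis: float
    minor_axis: float
    mean_intensity: float
    median_intensity: float


@dataclass
class MorphometrySummary:
    n_nuclei: int
    mean_area: float
    sd_area: float
    relative_sd_area: float
    mean_eccentricity: float
    median_intensity: float


def wrap_axial_deg(theta: np.ndarray | float) -> np.ndarray | float:
    """Wrap an axial angle in degrees onto (−90, +90]."""
    wrapped = (np.asarray(theta, dtype=np.float64) + 90.0) % 180.0 - 90.0
    wrapped = np.where(wrapped == -90.0, 90.0, wrapped)
    return float(wrapped) if np.isscalar(theta) else wrapped


def _orientation_from_moments(mu: np.ndarray) -> float:
    """Major-axis angle vs horizontal (y-up, CCW) from central moments.

    ``mu`` is indexed [row_order, col_order]; mapping x=col, y=−row flips
    the sign of the mixed moment.
    """
    cov_rr = mu[2, 0] / mu[0, 0]
    cov_cc = mu[0, 2] / mu[0, 0]
    cov_rc = mu[1, 1] / mu[0, 0]
    theta = 0.5 * np.degrees(np.arctan2(-2.0 * cov_rc, cov_cc - cov_rr))
    return float(wrap_axial_deg(theta))


def measure_nuclei(labels: LabelMap, intensity: np.ndarray) -> list[NucleusFeature]:
    """One :class:`NucleusFeature` per labeled object.

    ``intensity`` must be the raw nuclear raster (pre-CLAHE) and share the
    label raster's shape.
    """
    intensity = np.asarray(intensity, dtype=np.float64)
    if intensity.shape != labels.labels.shape:
        raise InputError(
            f"intensity shape {intensity.shape} != labels shape {labels.labels.shape}"
        )
    features: list[NucleusFeature] = []
    for prop in measure.regionprops(labels.labels, intensity_image=intensity):
        pixels = intensity[prop.slice][prop.image]
        major = float(prop.axis_major_length)
        minor = float(prop.axis_minor_length)
        features.append(
            NucleusFeature(
                label=int(prop.label),
                area=float(prop.area),
                centroid=(float(prop.centroid[1]), float(prop.centroid[0])),
                orientation_deg=_orientation_from_moments(prop.moments_central),
                eccentricity=float(prop.eccentricity),
                major_axis=major,
                minor_axis=minor,
                mean_intensity=float(pixels.mean()),
                median_intensity=float(np.median(pixels)),
            )
        )
    return features


def summarize_morphometry(features: list[NucleusFeature]) -> MorphometrySummary:
    """Per-image morphometry: population mean/SD of size, eccentricity, intensity.

    SDs use the population (n) denominator, matching region-statistics
    conventions; ``relative_sd_area = sd/mean`` quantifies intrasample
    size variability.  The intensity summary is the median over the
    per-nucleus median intensities, reported on the loaded [0, 1] scale.
    """
    if not features:
        raise EmptySampleError("cannot summarize an empty nucleus list")
    areas = np.array([f.area for f in features], dtype=np.float64)
    mean_area = float(areas.mean())
    sd_area = float(areas.std(ddof=0))
    return MorphometrySummary(
        n_nuclei=len(features),
        mean_area=mean_area,
        sd_area=sd_area,
        relative_sd_area=sd_area / mean_area if mean_area > 0 else 0.0,
        mean_eccentricity=float(np.mean([f.eccentricity for f in features])),
        median_intensity=float(np.median([f.median_intensity for f in features])),
    )


__all__ = [
    "NucleusFeature",
    "MorphometrySummary",
    "measure_nuclei",
    "summarize_morphometry",
    "wrap_axial_deg",
]
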