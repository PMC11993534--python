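"""Masked gray-level co-occurrence texture and WGA thickness.

Texture is quantified on a *masked* gray-level co-occurrence matrix
(GLCM): intensities inside the mask are quantized into ``n_levels`` equal
bins between the masked minimum and maximum, and a pixel pair at a given
offset contributes only if **both** endpoints lie inside the mask.
Zero-filling the background instead would create an artificial
high-contrast pair at every object border and swamp the intra-nuclear
signal.  The matrix is symmetrized and normalized to sum 1, accumulating
all offsets into a single orientation-agnostic matrix.

From the normalized matrix the Haralick descriptors are computed with the
standard definitions (0-based level indices i, j):

* contrast     ``Σ p(i,j) (i−j)²``
* correlation  ``Σ p(i,j)(i−μᵢ)(j−μⱼ) / (σᵢσⱼ)`` — undefined (None) when a
  marginal is degenerate
* energy       ``Σ p²``
* homogeneity  ``Σ p / (1+|i−j|)``
* entropy      ``−Σ_{p>0} p log₂ p``  (bits)

WGA network thickness is read off the Euclidean distance transform at the
medial skeleton: the local strip width is ``2·d − 1`` pixels at a skeleton
pixel with distance ``d`` to the background (the medial pixel itself plus
``d−1`` pixels to each side).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from .errors import ContractError, DegenerateInputError, InsufficientTextureError
from .image_io import MultichannelImage
from .segmentation import LabelMap

#: distance-1 offsets at 0°, 45°, 90°, 135° (in (drow, dcol) convention)
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass
class GLCM:
    """A symmetrized, normalized co-occurrence matrix plus its provenance."""

    matrix: np.ndarray
    n_levels: int
    n_pairs: int  # directed pairs accumulated before symmetrization


@dataclass
class TextureDescriptors:
    contrast: float
    correlation: float | None  # None when σi·σj == 0 (constant region)
    energy: float
    homogeneity: float
    entropy: float
    n_levels: int
    n_pairs: int


@dataclass
class ThicknessSummary:
    mean_thickness: float
    median_thickness: float
    max_thickness: float


def quantize(intensity: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Quantize intensities to 0..n_levels−1 between the masked min and max."""
    vals = intensity[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        return np.zeros_like(intensity, dtype=np.intp)
    q = np.floor((intensity - lo) / (hi - lo) * n_levels).astype(np.intp)
    return np.clip(q, 0, n_levels - 1)


def masked_glcm(
    intensity: np.ndarray,
    mask: np.ndarray,
    n_levels: int = 8,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
) -> GLCM:
    """Co-occurrence matrix restricted to in-mask pixel pairs.

    A pair contributes only if both endpoints are inside the mask, so
    background never pollutes the matrix.  Counts are accumulated over all
    offsets, symmetrized (each directed pair counted in both orders), and
    normalized to sum 1.
    """
    intensity = np.asarray(intensity, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if intensity.shape != mask.shape:
        raise ContractError("intensity and mask shapes differ")
    if n_levels < 2:
        raise ContractError("n_levels must be >= 2")
    if not mask.any():
        raise InsufficientTextureError("empty mask")
    q = quantize(intensity, mask, n_levels)
    counts = np.zeros((n_levels, n_levels), dtype=np.float64)
    n_pairs = 0
    nrow, ncol = mask.shape
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(nrow, nrow - dr)
        c0, c1 = max(0, -dc), min(ncol, ncol - dc)
        src = (slice(r0, r1), slice(c0, c1))
        dst = (slice(r0 + dr, r1 + dr), slice(c0 + dc, c1 + dc))
        both = mask[src] & mask[dst]
        a, b = q[src][both], q[dst][both]
        np.add.at(counts, (a, b), 1.0)
        n_pairs += int(both.sum())
    if n_pairs < 2:
        raise InsufficientTextureError(
            f"only {n_pairs} in-mask pixel pair(s); texture undefined"
        )
    counts = counts + counts.T
    return GLCM(matrix=counts / counts.sum(), n_levels=n_levels, n_pairs=n_pairs)


def haralick_descriptors(glcm: GLCM | np.ndarray) -> TextureDescriptors:
    """Haralick descriptors plus entropy from a normalized GLCM."""
    if isinstance(glcm, GLCM):
        p, n_levels, n_pairs = glcm.matrix, glcm.n_levels, glcm.n_pairs
    else:
        p = np.asarray(glcm, dtype=np.float64)
        n_levels, n_pairs = p.shape[0], 0
    if abs(p.sum() - 1.0) > 1e-9:
        raise ContractError(f"GLCM must be normalized to sum 1, got {p.sum():.12f}")
    n = p.shape[0]
    i, j = np.indices((n, n))
    contrast = float((p * (i - j) ** 2).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    energy = float((p**2).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    pi = p.sum(axis=1)
    mu_i = float((np.arange(n) * pi).sum())
    sigma_i = float(np.sqrt(((np.arange(n) - mu_i) ** 2 * pi).sum()))
    pj = p.sum(axis=0)
    mu_j = float((np.arange(n) * pj).sum())
    sigma_j = float(np.sqrt(((np.arange(n) - mu_j) ** 2 * pj).sum()))
    if sigma_i * sigma_j <= 0:
        correlation: float | None = None
    else:
        correlation = float(((p * (i - mu_i) * (j - mu_j)).sum()) / (sigma_i * sigma_j))
    return TextureDescriptors(
        contrast=contrast,
        correlation=correlation,
        energy=energy,
        homogeneity=homogeneity,
        entropy=entropy,
        n_levels=n_levels,
        n_pairs=n_pairs,
    )


def nuclear_texture(
    img: MultichannelImage,
    labels: LabelMap,
    n_levels: int = 8,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
) -> TextureDescriptors:
    """Texture of the raw DAPI signal restricted to segmented nuclei."""
    raster = img.require("nuclear")
    return haralick_descriptors(masked_glcm(raster, labels.mask, n_levels, offsets))


def extracellular_texture(
    img: MultichannelImage,
    wga_mask: np.ndarray,
    n_levels: int = 8,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
) -> TextureDescriptors:
    """Texture of the raw WGA signal restricted to the matrix mask."""
    raster = img.require("matrix")
    return haralick_descriptors(masked_glcm(raster, np.asarray(wga_mask, bool), n_levels, offsets))


def wga_thickness(wga_mask: np.ndarray) -> ThicknessSummary:
    """Strip-width statistics of the WGA network from its distance transform.

    Thickness is sampled only at medial-skeleton pixels; distance values
    off the medial axis systematically under-estimate local width.
    """
    mask = np.asarray(wga_mask, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("thickness of an empty mask")
    dist = ndi.distance_transform_edt(mask)
    skel = morphology.skeletonize(mask)
    samples = 2.0 * dist[skel] - 1.0 if skel.any() else 2.0 * np.array([dist.max()]) - 1.0
    return ThicknessSummary(
        mean_thickness=float(samples.mean()),
        median_thickness=float(np.median(samples)),
        max_thickness=float(samples.max()),
    )


__all__ = [
    "GLCM",
    "TextureDescriptors",
    "ThicknessSummary",
    "DEFAULT_OFFSETS",
    "quantize",
    "masked_glcm",
    "haralick_descriptors",
    "nuclear_texture",
    "extracellular_texture",
    "wga_thickness",
]
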