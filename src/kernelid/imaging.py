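"""Kernel segmentation and morphological feature extraction.

Kernels photographed on a dark background are segmented by Otsu
thresholding followed by a marker-controlled watershed on the distance
transform (so touching kernels with distinct cores split), and each
region yields a 52-feature vector in three families: geometric shape
descriptors, grey-level co-occurrence (GLCM) texture statistics plus a
grey histogram, and per-channel color statistics in RGB and HSV.

Naming follows the conventions used downstream: ``E`` is the minor/major
axis ratio, ``r`` the isoperimetric compactness 4*pi*A/P^2, and ``a_dev``
the standard deviation of the RGB *red* channel (the literal definition
adopted here even though 'a' often denotes Lab a*).  All SDs use the
population convention (ddof=0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.color import rgb2gray, rgb2hsv
from skimage.feature import graycomatrix, peak_local_max
from skimage.measure import find_contours
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

__all__ = [
    "ImageConfig",
    "KernelRegion",
    "IMAGE_FEATURE_NAMES",
    "SELECTED_IMAGE_FEATURES",
    "segment_kernels",
    "regions_from_mask",
    "features_from_labeled_mask",
    "geometric_features",
    "texture_features",
    "color_features",
    "extract_image_features",
]

#: The five downstream image features (chosen by recursive feature
#: elimination in the source methodology).
SELECTED_IMAGE_FEATURES = ("v_mean", "s_dev", "a_dev", "r", "E")

_GEOMETRIC = (
    "area", "perimeter", "major_axis", "minor_axis", "aspect_ratio", "E", "r",
    "eccentricity", "extent", "solidity", "equiv_diameter",
)
_GLCM = ("contrast", "dissimilarity", "homogeneity", "energy", "correlation", "entropy")
_HIST = tuple(f"hist{i}" for i in range(21))
_COLOR = (
    "r_mean", "g_mean", "b_mean", "a_dev", "g_dev", "b_dev",
    "h_mean", "s_mean", "v_mean", "h_dev", "s_dev", "v_dev",
    "grey_mean", "grey_dev",
)

#: Full 52-feature roster, in output order.
IMAGE_FEATURE_NAMES = _GEOMETRIC + _GLCM + _HIST + _COLOR
assert len(IMAGE_FEATURE_NAMES) == 52


@dataclass(frozen=True)
class ImageConfig:
    """Segmentation and texture conventions."""

    min_area: int = 64          # px^2; smaller regions are dropped
    peak_min_distance: int = 12  # px between watershed markers
    marker_smoothing: float = 2.0  # px; suppresses ridge-plateau oversegmentation
    min_intensity: float = 0.15  # grey floor (0-1); keeps Otsu off blank frames
    glcm_levels: int = 8
    glcm_offsets: tuple[tuple[int, int], ...] = ((0, 1), (1, 0))
    hist_bins: int = 21


DEFAULT_IMAGE_CONFIG = ImageConfig()


@dataclass
class KernelRegion:
    """One segmented kernel: full-frame boolean mask plus bookkeeping."""

    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]
    label: int = 0

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValueError("kernel region mask is empty")


def _check_rgb(image: np.ndarray) -> None:
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")


def segment_kernels(
    image: np.ndarray, config: ImageConfig = DEFAULT_IMAGE_CONFIG
) -> list[KernelRegion]:
    """Watershed segmentation of kernels against a dark background."""
    _check_rgb(image)
    grey = rgb2gray(image)
    if grey.max() == grey.min():  # blank frame, Otsu undefined
        return []
    binary = grey > max(threshold_otsu(grey), config.min_intensity)
    # drop sub-threshold specks before the watershed
    components = sk_label(binary)
    areas = np.bincount(components.ravel())
    keep = np.flatnonzero(areas >= config.min_area)
    binary = np.isin(components, keep[keep > 0])
    if not binary.any():
        return []
    distance = ndi.distance_transform_edt(binary)
    if config.marker_smoothing > 0:
        distance = ndi.gaussian_filter(distance, config.marker_smoothing)
    peaks = peak_local_max(
        distance, min_distance=config.peak_min_distance, labels=binary
    )
    markers = np.zeros_like(distance, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers = sk_label(binary)
    labels = watershed(-distance, markers, mask=binary)
    regions = []
    for prop in regionprops(labels):
        if prop.area < config.min_area:
            continue
        mask = labels == prop.label
        regions.append(
            KernelRegion(
                mask=mask, bbox=prop.bbox, centroid=prop.centroid, label=prop.label
            )
        )
    return regions


def _contour_perimeter(mask: np.ndarray, step: int = 5) -> float:
    """Boundary-tracked perimeter: marching-squares contour, lightly
    subsampled so the pixel staircase does not inflate smooth boundaries."""
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    contour = max(contours, key=len)
    idx = np.arange(0, len(contour) - 1, step)
    points = np.vstack([contour[idx], contour[-1:]])
    return float(np.sqrt((np.diff(points, axis=0) ** 2).sum(axis=1)).sum())


def geometric_features(region: KernelRegion) -> dict[str, float]:
    """Shape descriptors from the region mask (pixel units)."""
    prop = regionprops(region.mask.astype(np.uint8))[0]
    if prop.area < 5 or prop.axis_major_length == 0:
        raise ValueError("region too small for geometric features")
    area = float(prop.area)
    perimeter = _contour_perimeter(region.mask)
    major = float(prop.axis_major_length)
    minor = float(prop.axis_minor_length)
    return {
        "area": area,
        "perimeter": perimeter,
        "major_axis": major,
        "minor_axis": minor,
        "aspect_ratio": major / minor if minor > 0 else np.inf,
        "E": minor / major,
        "r": 4.0 * np.pi * area / perimeter**2,
        "eccentricity": float(prop.eccentricity),
        "extent": float(prop.extent),
        "solidity": float(prop.solidity),
        "equiv_diameter": float(prop.equivalent_diameter_area),
    }


def texture_features(
    region: KernelRegion,
    image: np.ndarray,
    levels: int = DEFAULT_IMAGE_CONFIG.glcm_levels,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_IMAGE_CONFIG.glcm_offsets,
    hist_bins: int = DEFAULT_IMAGE_CONFIG.hist_bins,
) -> dict[str, float]:
    """GLCM statistics and a normalized grey histogram over the region.

    The co-occurrence matrix is computed on the bounding-box crop with
    grey levels quantized to ``levels`` bins; level 0 is reserved for
    out-of-mask pixels and its row/column are removed before
    normalization, so only within-kernel pixel pairs contribute.  The
    matrix is symmetric and averaged over the offsets.
    """
    if levels < 2:
        raise ValueError("levels must be at least 2")
    _check_rgb(image)
    r0, c0, r1, c1 = region.bbox
    if (r1 - r0) <= max(dr for dr, _ in offsets) or (c1 - c0) <= max(
        dc for _, dc in offsets
    ):
        raise ValueError("region smaller than the GLCM offset")
    grey255 = rgb2gray(image[r0:r1, c0:c1]) * 255.0
    submask = region.mask[r0:r1, c0:c1]
    quant = (grey255 / 256.0 * levels).astype(np.uint8) + 1  # 1..levels
    quant[~submask] = 0
    glcm = graycomatrix(
        quant,
        distances=[1],
        angles=[0.0, np.pi / 2],
        levels=levels + 1,
        symmetric=True,
        normed=False,
    ).astype(float)
    # offsets (0,1) and (1,0) correspond to angles 0 and pi/2
    wanted = {(0, 1): 0, (1, 0): 1}
    mats = []
    for off in offsets:
        if off not in wanted:
            raise ValueError(f"unsupported GLCM offset {off}")
        m = glcm[:, :, 0, wanted[off]]
        m = m[1:, 1:]  # drop the out-of-mask level
        total = m.sum()
        if total == 0:
            raise ValueError("no valid pixel pairs for GLCM")
        mats.append(m / total)
    p = np.mean(mats, axis=0)
    i, j = np.indices(p.shape)
    diff = i - j
    mu_i = (i * p).sum()
    mu_j = (j * p).sum()
    sd_i = np.sqrt(((i - mu_i) ** 2 * p).sum())
    sd_j = np.sqrt(((j - mu_j) ** 2 * p).sum())
    if sd_i > 0 and sd_j > 0:
        correlation = (((i - mu_i) * (j - mu_j) * p).sum()) / (sd_i * sd_j)
    else:
        correlation = 1.0
    nz = p[p > 0]
    out = {
        "contrast": float((p * diff**2).sum()),
        "dissimilarity": float((p * np.abs(diff)).sum()),
        "homogeneity": float((p / (1.0 + diff**2)).sum()),
        "energy": float((p**2).sum()),
        "correlation": float(correlation),
        "entropy": float(-(nz * np.log2(nz)).sum()),
    }
    pixels = grey255[submask]
    hist, _ = np.histogram(pixels, bins=hist_bins, range=(0.0, 256.0))
    hist = hist / hist.sum()
    out.update({f"hist{k}": float(v) for k, v in enumerate(hist)})
    return out


def color_features(region: KernelRegion, image: np.ndarray) -> dict[str, float]:
    """Per-channel mean/SD in RGB (0-255) and HSV (0-1) over the mask."""
    _check_rgb(image)
    mask = region.mask
    rgb = image[mask].astype(float)
    hsv = rgb2hsv(image)[mask]
    grey = rgb2gray(image)[mask] * 255.0
    r, g, b = rgb[:, 0], rgb[:, 1], rgb[:, 2]
    h, s, v = hsv[:, 0], hsv[:, 1], hsv[:, 2]
    return {
        "r_mean": float(r.mean()),
        "g_mean": float(g.mean()),
        "b_mean": float(b.mean()),
        "a_dev": float(r.std()),  # SD of the red channel, by convention
        "g_dev": float(g.std()),
        "b_dev": float(b.std()),
        "h_mean": float(h.mean()),
        "s_mean": float(s.mean()),
        "v_mean": float(v.mean()),
        "h_dev": float(h.std()),
        "s_dev": float(s.std()),
        "v_dev": float(v.std()),
        "grey_mean": float(grey.mean()),
        "grey_dev": float(grey.std()),
    }


def regions_from_mask(mask: np.ndarray) -> list[KernelRegion]:
    """Build kernel regions from a labeled ground-truth mask (label order)."""
    regions = []
    for prop in regionprops(np.asarray(mask, dtype=np.int32)):
        regions.append(
            KernelRegion(
                mask=mask == prop.label,
                bbox=prop.bbox,
                centroid=prop.centroid,
                label=prop.label,
            )
        )
    return regions


def _feature_rows(
    regions: list[KernelRegion], image: np.ndarray, config: ImageConfig
) -> pd.DataFrame:
    rows = []
    for region in regions:
        row: dict[str, float] = {}
        row.update(geometric_features(region))
        row.update(
            texture_features(
                region, image, config.glcm_levels, config.glcm_offsets, config.hist_bins
            )
        )
        row.update(color_features(region, image))
        rows.append(row)
    frame = pd.DataFrame(rows)[list(IMAGE_FEATURE_NAMES)]
    frame.index.name = "kernel_id"
    return frame


def features_from_labeled_mask(
    image: np.ndarray, mask: np.ndarray, config: ImageConfig = DEFAULT_IMAGE_CONFIG
) -> pd.DataFrame:
    """52-feature rows for regions given by a labeled mask (no segmentation)."""
    regions = regions_from_mask(mask)
    if not regions:
        return pd.DataFrame(columns=list(IMAGE_FEATURE_NAMES))
    return _feature_rows(regions, image, config)


def extract_image_features(
    image: np.ndarray, config: ImageConfig = DEFAULT_IMAGE_CONFIG
) -> pd.DataFrame:
    """Segment an image and return one 52-feature row per kernel."""
    regions = segment_kernels(image, config)
    if not regions:
        warnings.warn("no kernels found in image", stacklevel=2)
        return pd.DataFrame(columns=list(IMAGE_FEATURE_NAMES))
    return _feature_rows(regions, image, config)
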