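"""Morphology-driven prostate-gland segmentation on stain density maps.

The stromal density map drives the segmentation: glands are the
low-stromal-density regions enclosed by Picrosirius-red-stained
stroma.  The algorithm (1) smooths the stromal map with a grayscale
opening, (2) thresholds it by gradient maximization to obtain a binary
mask of gland clusters, (3) extracts one seed per gland by adaptive
elliptical erosion of the gland foreground — severing thin
inter-gland bridges without erasing small glands — followed by a
second gradient-maximization thresholding, (4) grows the seeds with a
marker-controlled watershed on the stromal gradient, bounded by the
mask, and (5) removes objects that are too small or contain no
nucleus, since every true gland has at least one epithelial nucleus.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import structure_tensor
from skimage.filters import sobel
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .config import PipelineConfig, SegmentationConfig
from .errors import (
    DegenerateInputError,
    InvalidConfigError,
    InvalidSeedError,
)
from .types import (
    BinaryMask,
    DensityMapPair,
    LabelMap,
    RGBImage,
    SeedMap,
    SegmentationResult,
    StainModel,
)

__all__ = [
    "smooth_stroma",
    "gradient_threshold",
    "local_structure_tensor_se",
    "adaptive_erode",
    "extract_seeds",
    "watershed_glands",
    "filter_objects",
    "segment_glands",
]

_REJECT_TOO_SMALL = "too_small"
_REJECT_NO_NUCLEUS = "no_nucleus"


def _connectivity_value(config: SegmentationConfig) -> int:
    # skimage connectivity: 1 = 4-connected, 2 = 8-connected
    return 2 if config.connectivity == 8 else 1


def smooth_stroma(stromal: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Grayscale morphological opening with a rectangular kernel.

    Removes structures smaller than the kernel and smooths gland
    boundaries.  The default 6 x 6 px kernel trades off separating
    distinct glands against grouping them.
    """
    cfg = config or SegmentationConfig()
    kh, kw = cfg.opening_kernel
    h, w = stromal.shape
    if kh > h or kw > w:
        raise InvalidConfigError(f"opening kernel {cfg.opening_kernel} larger than image {stromal.shape}")
    return ndi.grey_opening(stromal, size=(kh, kw), mode="nearest")


def _boundary_pixels(high: np.ndarray) -> np.ndarray:
    """Pixels 8-adjacent to the opposite class (both sides of the split)."""
    struct = np.ones((3, 3), dtype=bool)
    return (ndi.binary_dilation(high, structure=struct) & ~high) | (
        ndi.binary_dilation(~high, structure=struct) & high
    )


def _gradient_threshold_value(image: np.ndarray, n_levels: int = 256) -> float:
    """Threshold maximizing mean gradient magnitude over boundary pixels.

    Candidates are ``n_levels`` uniformly spaced gray levels over the
    map's range; ties resolve to the lower threshold.  This uses local
    image content (how sharp the resulting boundary is) rather than the
    global histogram.
    """
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        raise DegenerateInputError("constant map has no threshold")
    grad = sobel(image)
    candidates = np.linspace(lo, hi, n_levels)
    best_t, best_score = None, -np.inf
    for t in candidates:
        high = image >= t
        boundary = _boundary_pixels(high)
        n_b = int(boundary.sum())
        if n_b == 0:
            continue
        score = float(grad[boundary].mean())
        if score > best_score:  # strict: ties keep the lower threshold
            best_score, best_t = score, float(t)
    if best_t is None:
        raise DegenerateInputError("no candidate threshold produced a boundary")
    return best_t


def gradient_threshold(stromal: np.ndarray) -> BinaryMask:
    """Gradient-maximization binarization of a stroma-high density map.

    Returns the gland-candidate mask: pixels strictly below the selected
    threshold (low stromal density = possible gland interior).
    """
    t = _gradient_threshold_value(stromal)
    return BinaryMask(mask=stromal < t, polarity="gland_candidate")


def _tensor_eig(arr: np.ndarray, arc: np.ndarray, acc: np.ndarray):
    """Closed-form eigendecomposition of the 2x2 structure tensor field.

    Returns (lam1, lam2, theta): eigenvalues lam1 >= lam2 >= 0 and the
    orientation (radians, atan2(row, col) convention) of the lam2
    eigenvector — the direction of least gray-level variation, i.e.
    along edges.
    """
    tr = arr + acc
    disc = np.sqrt(np.maximum((arr - acc) ** 2 + 4.0 * arc**2, 0.0))
    lam1 = 0.5 * (tr + disc)
    lam2 = 0.5 * (tr - disc)
    # eigenvector for lam2 of [[arr, arc], [arc, acc]]: (arc, lam2 - arr),
    # falling back to the axis when the off-diagonal vanishes
    vr = np.where(np.abs(arc) > 1e-15, arc, np.where(arr <= acc, 1.0, 0.0))
    vc = np.where(np.abs(arc) > 1e-15, lam2 - arr, np.where(arr <= acc, 0.0, 1.0))
    theta = np.arctan2(vr, vc)
    return lam1, lam2, theta


def _ellipse_footprint(a: float, b: float, theta: float) -> np.ndarray:
    """Rasterized, center-inclusive ellipse: semi-major a at angle theta, semi-minor b."""
    r_max = int(np.ceil(max(a, b)))
    rr, cc = np.mgrid[-r_max : r_max + 1, -r_max : r_max + 1]
    # rotate into ellipse frame; theta measured as atan2(row, col)
    u = cc * np.cos(theta) + rr * np.sin(theta)  # along major axis
    v = -cc * np.sin(theta) + rr * np.cos(theta)
    fp = (u / max(a, 0.5)) ** 2 + (v / max(b, 0.5)) ** 2 <= 1.0
    fp[r_max, r_max] = True
    return fp


def local_structure_tensor_se(
    image: np.ndarray,
    position: tuple[int, int],
    config: SegmentationConfig | None = None,
) -> tuple[float, tuple[float, float]]:
    """Adaptive elliptical structuring element at one position.

    The Gaussian-smoothed structure tensor encodes the local gradient
    distribution; its anisotropy ``(lam1 - lam2)/(lam1 + lam2)``
    interpolates the SE between a disk (isotropic neighborhood) and a
    line-like ellipse aligned with the direction of least variation
    (along an edge).  Returns ``(orientation_rad, (semi_major, semi_minor))``
    with both semi-axes bounded by ``erosion_max_axis / 2``; a flat
    region (zero tensor) yields a disk of maximal radius.
    """
    cfg = config or SegmentationConfig()
    if cfg.tensor_sigma <= 0:
        raise InvalidConfigError("tensor_sigma must be positive")
    arr, arc, acc = structure_tensor(image, sigma=cfg.tensor_sigma, order="rc")
    r, c = position
    lam1, lam2, theta = _tensor_eig(
        np.asarray(arr[r, c]), np.asarray(arc[r, c]), np.asarray(acc[r, c])
    )
    lam_sum = float(lam1 + lam2)
    a = cfg.erosion_max_axis / 2.0
    if lam_sum <= 1e-15:
        return 0.0, (a, a)
    aniso = float((lam1 - lam2) / lam_sum)
    b = max(a * (1.0 - aniso), 0.5)
    return float(theta), (a, b)


def adaptive_erode(image: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Grayscale erosion with per-pixel tensor-adapted elliptical SEs.

    Implemented as a discretized SE bank: anisotropy is quantized into
    four levels and orientation into six bins over [0, pi); the image is
    eroded once per distinct SE and each pixel takes the result of its
    own bin.  The most isotropic level is a disk, so its orientation is
    irrelevant and it is computed once.
    """
    cfg = config or SegmentationConfig()
    arr, arc, acc = structure_tensor(image, sigma=cfg.tensor_sigma, order="rc")
    lam1, lam2, theta = _tensor_eig(arr, arc, acc)
    lam_sum = lam1 + lam2
    aniso = np.where(lam_sum > 1e-15, (lam1 - lam2) / np.maximum(lam_sum, 1e-300), 0.0)

    a = cfg.erosion_max_axis / 2.0
    aniso_levels = np.array([0.125, 0.375, 0.625, 0.875])
    aniso_bin = np.clip((aniso * 4).astype(int), 0, 3)
    theta_mod = np.mod(theta, np.pi)
    n_theta = 6
    theta_bin = np.clip((theta_mod / np.pi * n_theta).astype(int), 0, n_theta - 1)
    theta_centers = (np.arange(n_theta) + 0.5) * np.pi / n_theta

    out = np.empty_like(image)
    # disk for the isotropic bin
    disk = _ellipse_footprint(a, a, 0.0)
    eroded_disk = ndi.grey_erosion(image, footprint=disk, mode="nearest")
    sel = aniso_bin == 0
    out[sel] = eroded_disk[sel]
    for ai in range(1, 4):
        level_sel = aniso_bin == ai
        if not np.any(level_sel):
            continue
        b = max(a * (1.0 - aniso_levels[ai]), 0.5)
        for ti in range(n_theta):
            sel = level_sel & (theta_bin == ti)
            if not np.any(sel):
                continue
            fp = _ellipse_footprint(a, b, theta_centers[ti])
            eroded = ndi.grey_erosion(image, footprint=fp, mode="nearest")
            out[sel] = eroded[sel]
    return out


def extract_seeds(
    stromal: np.ndarray,
    mask: BinaryMask,
    config: SegmentationConfig | None = None,
) -> SeedMap:
    """One seed per gland by adaptive erosion of the gland foreground.

    The gland foreground (inverted stromal map) is eroded with the
    tensor-adapted elliptical SEs, which severs glands connected by only
    a few pixels; gradient-maximization thresholding of the eroded map
    then yields seed blobs, and connected components inside the mask
    become the seeds.  An empty result is a warning, not an error:
    stroma-only tiles legitimately contain no glands.
    """
    cfg = config or SegmentationConfig()
    eroded_fg = adaptive_erode(1.0 - stromal, cfg)
    try:
        # 1 - eroded foreground is again stroma-high, so reuse the
        # gland-candidate polarity of gradient_threshold
        seed_candidates = gradient_threshold(1.0 - eroded_fg).mask
    except DegenerateInputError:
        seed_candidates = np.zeros_like(mask.mask)
    seed_candidates &= mask.mask
    labels = cc_label(seed_candidates, connectivity=_connectivity_value(cfg))
    if labels.max() == 0:
        warnings.warn("no seeds found", stacklevel=2)
    return SeedMap(labels=labels)


def watershed_glands(stromal: np.ndarray, seeds: SeedMap, mask: BinaryMask) -> LabelMap:
    """Marker-controlled watershed on the stromal gradient, bounded by the mask.

    Each seed floods its basin on the gradient-magnitude surface; the
    mask stops flooding at the gland-cluster boundary, so every output
    region is confined to the mask and contains exactly its seed.
    """
    outside = (seeds.labels > 0) & ~mask.mask
    if np.any(outside):
        bad = int(np.unique(seeds.labels[outside])[0])
        raise InvalidSeedError(bad)
    surface = sobel(stromal)
    labels = watershed(surface, markers=seeds.labels, mask=mask.mask, connectivity=2)
    return LabelMap(labels=labels)


def _has_nucleus(region_epithelial: np.ndarray, region_mask: np.ndarray, cfg: SegmentationConfig) -> bool:
    """Does the region contain a connected blob of bright epithelial pixels?"""
    bright = region_mask & (region_epithelial >= cfg.min_nucleus_intensity)
    if int(bright.sum()) < cfg.min_nucleus_pixels:
        return False
    blobs = cc_label(bright, connectivity=_connectivity_value(cfg))
    if blobs.max() == 0:
        return False
    sizes = np.bincount(blobs.ravel())[1:]
    return bool(sizes.max() >= cfg.min_nucleus_pixels)


def filter_objects(
    labels: LabelMap,
    epithelial: np.ndarray,
    config: SegmentationConfig | None = None,
    seeds: SeedMap | None = None,
    mask: BinaryMask | None = None,
) -> SegmentationResult:
    """Reject segmented objects that cannot be glands.

    Every gland contains at least one nucleus, so a region is kept only
    if (a) its area reaches ``min_object_size`` (the mean epithelial
    nucleus area) and (b) it holds a connected cluster of at least
    ``min_nucleus_pixels`` pixels whose epithelial density reaches
    ``min_nucleus_intensity``.  Each removal is recorded with its reason.
    """
    cfg = config or SegmentationConfig()
    if epithelial.shape != labels.labels.shape:
        raise InvalidConfigError("epithelial map does not match label map shape")
    out = labels.labels.copy()
    rejected: list[tuple[int, str]] = []
    objects = ndi.find_objects(out)
    for rid, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        region_mask = out[sl] == rid
        area = int(region_mask.sum())
        if area < cfg.min_object_size:
            rejected.append((rid, _REJECT_TOO_SMALL))
            out[sl][region_mask] = 0
            continue
        if not _has_nucleus(epithelial[sl], region_mask, cfg):
            rejected.append((rid, _REJECT_NO_NUCLEUS))
            out[sl][region_mask] = 0
    return SegmentationResult(
        labels=LabelMap(labels=out),
        rejected=rejected,
        seeds=seeds if seeds is not None else SeedMap(labels=np.zeros_like(out)),
        mask=mask if mask is not None else BinaryMask(mask=np.ones_like(out, dtype=bool)),
        config={"segmentation": cfg.__dict__.copy()},
        prefilter_labels=labels,
    )


def segment_glands(
    image: RGBImage,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> SegmentationResult:
    """Full gland segmentation of an RGB tile.

    Blind color decomposition, stromal smoothing, mask construction,
    seed extraction, seeded watershed and nucleus filtering, in that
    order; fully deterministic given the seed.
    """
    from .bcd import decompose  # local import to avoid cycle at module load

    cfg = config or PipelineConfig()
    cfg.validate()
    maps, model = decompose(image, seed=seed, config=cfg.bcd)
    return segment_from_maps(maps, cfg, model=model)


def segment_from_maps(
    maps: DensityMapPair,
    config: PipelineConfig | None = None,
    model: StainModel | None = None,
) -> SegmentationResult:
    """Segmentation stages downstream of color decomposition."""
    cfg = config or PipelineConfig()
    seg_cfg = cfg.segmentation
    smoothed = smooth_stroma(maps.stromal, seg_cfg)
    mask = gradient_threshold(smoothed)
    seeds = extract_seeds(smoothed, mask, seg_cfg)
    labels = watershed_glands(smoothed, seeds, mask)
    result = filter_objects(labels, maps.epithelial, seg_cfg, seeds=seeds, mask=mask)
    result.config["bcd"] = cfg.bcd.__dict__.copy()
    if model is not None:
        result.config["stain_model"] = model.to_dict()
    return result
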