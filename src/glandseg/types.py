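"""Core data containers shared across the pipeline.

The pipeline's working representation is a pair of per-stain density
maps obtained by Beer-Lambert color decomposition of a brightfield RGB
tile.  Chromaticity lives in the barycentric triangle of normalized
optical-density (OD) vectors, where distance between points reflects
color difference independent of stain amount; cluster fitting happens
in an orthonormal 2-D coordinate system of that triangle's plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "RGBImage",
    "OpticalDensityImage",
    "ChromaticityCloud",
    "StainModel",
    "DensityMapPair",
    "BinaryMask",
    "SeedMap",
    "LabelMap",
    "SegmentationResult",
    "GroundTruthLabels",
    "barycentric_to_planar",
    "planar_to_barycentric",
]

# Orthonormal basis of the plane x+y+z=1, anchored at the triangle
# centroid.  Barycentric points are rank-2, so Gaussian fitting is done
# in these 2-D coordinates.
_CENTROID = np.full(3, 1.0 / 3.0)
_U = np.array([1.0, -1.0, 0.0]) / np.sqrt(2.0)
_V = np.array([1.0, 1.0, -2.0]) / np.sqrt(6.0)
_BASIS = np.stack([_U, _V], axis=1)  # 3x2


def barycentric_to_planar(points: np.ndarray) -> np.ndarray:
    """Map barycentric points (..., 3) to planar triangle coordinates (..., 2)."""
    pts = np.asarray(points, dtype=float)
    return (pts - _CENTROID) @ _BASIS


def planar_to_barycentric(points: np.ndarray) -> np.ndarray:
    """Inverse of :func:`barycentric_to_planar` (exact for in-plane points)."""
    pts = np.asarray(points, dtype=float)
    return pts @ _BASIS.T + _CENTROID


@dataclass
class RGBImage:
    """Raw 3-channel brightfield tile.

    ``background_intensity`` is the per-channel white level ``I0``; it is
    the incident-light intensity in the Beer-Lambert relation and must be
    strictly positive.
    """

    pixels: np.ndarray  # H x W x 3
    background_intensity: np.ndarray  # 3-vector
    bit_depth: int = 8

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.background_intensity = np.asarray(self.background_intensity, dtype=float).reshape(3)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InvalidInputError(f"expected H x W x 3 pixels, got shape {self.pixels.shape}")
        if np.any(self.pixels < 0):
            raise InvalidInputError("negative pixel intensities")
        max_val = 2**self.bit_depth - 1
        if np.any(self.pixels > max_val):
            raise InvalidInputError(f"pixel intensities exceed {max_val} for bit depth {self.bit_depth}")
        if np.any(self.background_intensity <= 0):
            raise InvalidInputError("background intensity must be strictly positive per channel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class OpticalDensityImage:
    """Per-pixel Beer-Lambert optical density, natural-log scale, >= 0."""

    od: np.ndarray  # H x W x 3

    @property
    def shape(self) -> tuple[int, int]:
        return self.od.shape[:2]


@dataclass
class ChromaticityCloud:
    """Foreground pixels mapped to the Beer-Lambert chromaticity triangle.

    ``points`` are barycentric (each row >= 0, sums to 1); ``total_od``
    keeps the OD magnitude of every pixel in the source image, including
    the near-white pixels excluded from the cloud, for bookkeeping.
    """

    points: np.ndarray  # N x 3 barycentric
    total_od: np.ndarray  # per-pixel OD sum (full image, flattened)

    def __post_init__(self):
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise InvalidInputError("chromaticity points must be N x 3")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def planar(self) -> np.ndarray:
        return barycentric_to_planar(self.points)


@dataclass
class StainModel:
    """Gaussian-mixture stain model fitted in planar triangle coordinates.

    ``reference_chromaticities`` are the component means mapped back to
    barycentric coordinates; ``covariances`` are the planar 2x2 component
    covariances; ``mixing_matrix`` columns are the unit-sum OD direction
    vectors of each stain, so a pixel's OD is ``mixing_matrix @ densities``.
    """

    n_stains: int
    reference_chromaticities: np.ndarray  # n_stains x 3
    covariances: np.ndarray  # n_stains x 2 x 2
    weights: np.ndarray  # n_stains
    mixing_matrix: np.ndarray  # 3 x n_stains
    seed: Optional[int] = None
    n_iter: Optional[int] = None

    def planar_means(self) -> np.ndarray:
        return barycentric_to_planar(self.reference_chromaticities)

    def to_dict(self) -> dict:
        return {
            "n_stains": int(self.n_stains),
            "reference_chromaticities": self.reference_chromaticities.tolist(),
            "covariances": self.covariances.tolist(),
            "weights": self.weights.tolist(),
            "mixing_matrix": self.mixing_matrix.tolist(),
            "seed": self.seed,
            "n_iter": self.n_iter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StainModel":
        return cls(
            n_stains=int(d["n_stains"]),
            reference_chromaticities=np.asarray(d["reference_chromaticities"], dtype=float),
            covariances=np.asarray(d["covariances"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            mixing_matrix=np.asarray(d["mixing_matrix"], dtype=float),
            seed=d.get("seed"),
            n_iter=d.get("n_iter"),
        )


@dataclass
class DensityMapPair:
    """Aligned stromal and epithelial stain-density maps.

    ``normalization`` records the scaling applied (the fixed OD divisor)
    so maps are comparable across tiles; after normalization both maps
    lie in [0, 1] and the downstream nucleus-intensity threshold is
    meaningful.
    """

    stromal: np.ndarray  # H x W
    epithelial: np.ndarray  # H x W
    normalization: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.stromal.shape


@dataclass
class BinaryMask:
    """Binary segmentation mask; True marks gland-candidate (non-stromal) pixels."""

    mask: np.ndarray  # H x W bool
    polarity: str = "gland_candidate"


@dataclass
class SeedMap:
    """Integer seed labels, 0 = background, 1..K = seed identity."""

    labels: np.ndarray  # H x W int

    @property
    def n_seeds(self) -> int:
        return int(self.labels.max())


@dataclass
class LabelMap:
    """Integer instance labels, 0 = background."""

    labels: np.ndarray  # H x W int

    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class SegmentationResult:
    """Final gland objects with accept/reject provenance."""

    labels: LabelMap
    rejected: list  # list of (region_id, reason) with reason in {too_small, no_nucleus}
    seeds: SeedMap
    mask: BinaryMask
    config: dict = field(default_factory=dict)
    prefilter_labels: Optional[LabelMap] = None  # watershed output before filtering

    @property
    def n_accepted(self) -> int:
        return len(self.labels.region_ids())


@dataclass
class GroundTruthLabels:
    """Synthetic per-pixel gland instance labels plus per-gland metadata."""

    instance_labels: np.ndarray  # H x W int
    architecture_per_instance: dict  # id -> architecture tag
    nucleus_mask: np.ndarray  # H x W bool

    def instance_ids(self) -> np.ndarray:
        ids = np.unique(self.instance_labels)
        return ids[ids > 0]
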