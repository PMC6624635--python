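"""Blind color decomposition of brightfield histology into stain density maps.

The transmitted intensity of a two-stain absorption image follows the
Beer-Lambert law, ``I = I0 * exp(-M d)``, where the columns of the
mixing matrix ``M`` are the per-stain optical-density (OD) directions
and ``d`` the per-pixel stain amounts.  Taking logs makes the model
linear in OD.  Normalizing each pixel's OD vector to unit sum projects
it onto the chromaticity triangle, where color is decoupled from stain
amount: scaling the amount of stain at a pixel moves its OD along a ray
but leaves its chromaticity point fixed.  A Gaussian mixture fitted by
EM in the triangle plane recovers the two stain reference colors
blindly, i.e. from the image itself; non-negative least squares against
the resulting mixing matrix then unmixes every pixel into stromal
(Picrosirius red) and epithelial (hematoxylin) densities.
"""

from __future__ import annotations

import numpy as np
from sklearn.mixture import GaussianMixture

from .config import BCDConfig
from .errors import (
    ConvergenceError,
    DegenerateInputError,
    DegenerateStainError,
    InvalidInputError,
)
from .types import (
    ChromaticityCloud,
    DensityMapPair,
    OpticalDensityImage,
    RGBImage,
    barycentric_to_planar,
    planar_to_barycentric,
)

__all__ = [
    "rgb_to_od",
    "od_to_chromaticity",
    "fit_stain_model",
    "unmix",
    "decompose",
    "estimate_background",
]

from .types import StainModel


def estimate_background(pixels: np.ndarray, percentile: float = 99.0) -> np.ndarray:
    """Per-channel white level I0 as a high percentile of the tile.

    Brightfield tiles almost always contain unstained background; its
    intensity is the brightest population in each channel.
    """
    return np.percentile(pixels.reshape(-1, 3), percentile, axis=0)


def rgb_to_od(image: RGBImage) -> OpticalDensityImage:
    """Beer-Lambert transform: ``od = ln(I0 / I)`` per channel.

    Zero intensities are clipped to one count before the ratio so the OD
    stays bounded; OD is clipped below at zero (a pixel brighter than
    the background carries no absorption information).
    """
    i0 = image.background_intensity
    if np.any(i0 <= 0):
        raise InvalidInputError("background intensity must be positive")
    intensity = np.maximum(image.pixels, 1.0)
    od = np.log(i0[None, None, :] / intensity)
    return OpticalDensityImage(od=np.maximum(od, 0.0))


def od_to_chromaticity(od_image: OpticalDensityImage, min_total_od: float = 0.10) -> ChromaticityCloud:
    """Project OD vectors onto the barycentric chromaticity triangle.

    Pixels whose total OD falls below ``min_total_od`` are near-white
    background: their chromaticity is noise-dominated, so they are
    excluded from the cloud (but their OD totals are retained).
    """
    if min_total_od < 0:
        raise InvalidInputError("min_total_od must be >= 0")
    od = od_image.od.reshape(-1, 3)
    total = od.sum(axis=1)
    keep = total > min_total_od
    if not np.any(keep):
        raise DegenerateInputError("all pixels are background; no chromaticity cloud")
    points = od[keep] / total[keep, None]
    return ChromaticityCloud(points=points, total_od=total)


def _canonical_order(means_bary: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Deterministic component order: descending red coordinate, then weight.

    Picrosirius red stains stroma red, so the redder component is the
    stromal stain; putting it first makes column 0 of the mixing matrix
    the stromal direction regardless of EM initialization.
    """
    order = np.lexsort((-weights, -means_bary[:, 0]))
    return order


def fit_stain_model(
    cloud: ChromaticityCloud,
    n_stains: int = 2,
    seed: int = 0,
    config: BCDConfig | None = None,
) -> StainModel:
    """EM fit of a Gaussian mixture to the chromaticity cloud.

    Fitting happens in an orthonormal 2-D basis of the triangle plane
    (barycentric points are rank-2).  Components are returned in
    canonical order (reddest first).  Raises
    :class:`~glandseg.errors.ConvergenceError` if EM does not converge
    and :class:`~glandseg.errors.DegenerateStainError` if component
    means collapse onto each other.
    """
    cfg = config or BCDConfig()
    if n_stains < 1:
        raise InvalidInputError("n_stains must be >= 1")
    if n_stains >= 2 and cloud.n_points < 10 * n_stains:
        raise InvalidInputError(
            f"need at least {10 * n_stains} cloud points for {n_stains} stains, got {cloud.n_points}"
        )
    planar = cloud.planar()
    gm = GaussianMixture(
        n_components=n_stains,
        covariance_type="full",
        max_iter=cfg.em_max_iter,
        tol=cfg.em_tol,
        reg_covar=cfg.em_reg_covar,
        init_params="k-means++",
        n_init=1,
        random_state=int(seed) % (2**31),
    )
    gm.fit(planar)
    if not gm.converged_:
        raise ConvergenceError("EM did not converge", n_iter=int(gm.n_iter_))
    means_bary = planar_to_barycentric(gm.means_)
    if n_stains >= 2:
        for i in range(n_stains):
            for j in range(i + 1, n_stains):
                if np.linalg.norm(means_bary[i] - means_bary[j]) < cfg.min_stain_separation:
                    raise DegenerateStainError(
                        f"stain components {i} and {j} collapsed "
                        f"(separation < {cfg.min_stain_separation})"
                    )
    order = _canonical_order(means_bary, gm.weights_)
    means_bary = means_bary[order]
    mixing = means_bary.T.copy()  # columns are unit-sum OD directions
    return StainModel(
        n_stains=n_stains,
        reference_chromaticities=means_bary,
        covariances=gm.covariances_[order],
        weights=gm.weights_[order],
        mixing_matrix=mixing,
        seed=int(seed),
        n_iter=int(gm.n_iter_),
    )


def _nnls_two_columns(od_flat: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Exact non-negative least squares for a 3x2 system, vectorized.

    With two columns the NNLS solution is either the unconstrained
    least-squares solution (when it is already non-negative) or the
    better of the two single-column projections with the other
    coefficient at zero.
    """
    c1, c2 = M[:, 0], M[:, 1]
    G = M.T @ M
    det = G[0, 0] * G[1, 1] - G[0, 1] ** 2
    if det <= 1e-12 * G[0, 0] * G[1, 1]:
        raise DegenerateStainError("mixing matrix columns are collinear")
    b1 = od_flat @ c1
    b2 = od_flat @ c2
    # unconstrained solution via 2x2 inverse
    x1 = (G[1, 1] * b1 - G[0, 1] * b2) / det
    x2 = (G[0, 0] * b2 - G[0, 1] * b1) / det
    # single-column projections, clipped at zero
    p1 = np.maximum(b1 / G[0, 0], 0.0)
    p2 = np.maximum(b2 / G[1, 1], 0.0)
    # explained sum of squares of each projection; larger is better
    use_p1 = p1**2 * G[0, 0] >= p2**2 * G[1, 1]
    neg = (x1 < 0) | (x2 < 0)
    out = np.stack([x1, x2], axis=1)
    out[neg & use_p1, 0] = p1[neg & use_p1]
    out[neg & use_p1, 1] = 0.0
    out[neg & ~use_p1, 0] = 0.0
    out[neg & ~use_p1, 1] = p2[neg & ~use_p1]
    return out


def unmix(
    od_image: OpticalDensityImage,
    model: StainModel,
    od_scale: float | None = 2.5,
) -> DensityMapPair:
    """Linear unmixing of OD into stromal and epithelial densities.

    Per pixel, solves non-negative least squares of the OD vector
    against the mixing-matrix columns (column 0 = stromal).  With
    ``od_scale`` set, densities are divided by it and clipped to [0, 1]
    so maps are comparable across tiles; ``od_scale=None`` returns raw
    densities in OD units.
    """
    if model.n_stains != 2:
        raise InvalidInputError("unmix requires a 2-stain model")
    h, w = od_image.shape
    dens = _nnls_two_columns(od_image.od.reshape(-1, 3), model.mixing_matrix)
    stromal = dens[:, 0].reshape(h, w)
    epithelial = dens[:, 1].reshape(h, w)
    if od_scale is None:
        norm = {"mode": "raw"}
    else:
        if od_scale <= 0:
            raise InvalidInputError("od_scale must be positive")
        stromal = np.clip(stromal / od_scale, 0.0, 1.0)
        epithelial = np.clip(epithelial / od_scale, 0.0, 1.0)
        norm = {"mode": "fixed_od_scale", "od_scale": float(od_scale)}
    return DensityMapPair(stromal=stromal, epithelial=epithelial, normalization=norm)


def decompose(
    image: RGBImage,
    seed: int = 0,
    config: BCDConfig | None = None,
) -> tuple[DensityMapPair, StainModel]:
    """Full blind decomposition: OD transform, chromaticity cloud, EM fit, unmixing.

    Returns the normalized density-map pair and the fitted stain model.
    If the tile contains a single stain and ``config.single_stain_fallback``
    is set, falls back to a one-component model whose density goes into
    the stromal map (epithelial map zero); otherwise the collapsed fit
    raises :class:`~glandseg.errors.DegenerateStainError`.
    """
    cfg = config or BCDConfig()
    cfg.validate()
    od_image = rgb_to_od(image)
    cloud = od_to_chromaticity(od_image, min_total_od=cfg.min_total_od)
    try:
        model = fit_stain_model(cloud, n_stains=cfg.n_stains, seed=seed, config=cfg)
    except DegenerateStainError:
        if not cfg.single_stain_fallback:
            raise
        model = fit_stain_model(cloud, n_stains=1, seed=seed, config=cfg)
        ref = model.mixing_matrix[:, 0]
        od_flat = od_image.od.reshape(-1, 3)
        raw = np.maximum(od_flat @ ref, 0.0) / (ref @ ref)
        h, w = od_image.shape
        stromal = np.clip(raw.reshape(h, w) / cfg.od_scale, 0.0, 1.0)
        maps = DensityMapPair(
            stromal=stromal,
            epithelial=np.zeros((h, w)),
            normalization={"mode": "fixed_od_scale", "od_scale": cfg.od_scale, "single_stain": True},
        )
        return maps, model
    maps = unmix(od_image, model, od_scale=cfg.od_scale)
    return maps, model
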