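"""Forward-model generator of two-stain prostate-like tiles with ground truth.

Tiles emulate Picrosirius red-hematoxylin absorption imagery: a
red-absorbing stromal field fills the space between glands, glands are
low-stroma regions lined with blue/purple-absorbing epithelial
cytoplasm and dark nuclei, and lumina absorb nothing.  Per-pixel stain
densities are painted first; the RGB tile is then rendered through the
Beer-Lambert relation ``I = I0 * exp(-M d)`` with multiplicative
stain-intensity variation and additive Gaussian CCD noise.  Because
the generator and the decomposition share the same physical model, a
noise-free tile round-trips exactly, and every gland carries a
per-pixel instance label and an architecture tag for object-level
evaluation.

Gland architectures follow the Gleason growth patterns: well-formed
glands (grade 3) with a single lumen and basally placed nuclei,
poorly formed small glands, cribriform masses perforated by several
lumina (grade 4), fused gland unions (grade 4), and isolated single
cells (grade 5).  Two trap architectures reproduce the structures a
nucleus-based filter must reject: nucleus-free epithelial rings and
bare nuclei without cytoplasm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .errors import InvalidInputError
from .types import ChromaticityCloud, GroundTruthLabels, RGBImage, planar_to_barycentric

__all__ = [
    "GlandSpec",
    "TissueSpec",
    "generate_tile",
    "generate_suite",
    "sample_cloud",
    "GLAND_ARCHITECTURES",
    "TRAP_ARCHITECTURES",
    "CATALOGS",
]

GLAND_ARCHITECTURES = frozenset(
    {"benign", "well_formed", "poorly_formed", "cribriform", "fused", "single_cells"}
)
TRAP_ARCHITECTURES = frozenset({"nucleus_free_trap", "bare_nucleus"})

# painted stain densities in OD units (the downstream maps divide by
# od_scale = 2.5): stroma ~0.48 normalized, cytoplasm ~0.18, nuclei
# ~0.84 — comfortably above the 0.7 nucleus-intensity floor
STROMA_DENSITY = 1.2
CYTOPLASM_DENSITY = 0.45
NUCLEUS_DENSITY = 2.1

DEFAULT_STROMAL_REF = np.array([0.60, 0.25, 0.15])
DEFAULT_EPITHELIAL_REF = np.array([0.30, 0.30, 0.40])


@dataclass
class GlandSpec:
    """One gland (or trap object) to paint.

    ``size`` is the mean radius in pixels; lumina are interior disks
    (one for well-formed glands, several for cribriform); ``n_nuclei``
    nuclei of radius ``nucleus_radius`` are placed in the cytoplasm.
    ``fused_offsets`` lists extra lobe centers for fused glands, which
    share a single instance id.
    """

    architecture: str
    position: tuple[float, float]  # (row, col) center
    size: float = 40.0
    n_lumina: int = 1
    lumen_fraction: float = 0.45  # lumen radius as fraction of gland radius
    n_nuclei: int = 8
    nucleus_radius: float = 5.0
    irregularity: float = 0.06  # star-polygon radius modulation amplitude
    fused_offsets: tuple = ()


@dataclass
class TissueSpec:
    """Complete description of one synthetic tile."""

    image_size: tuple[int, int] = (512, 512)
    gland_specs: list = field(default_factory=list)
    stromal_reference: np.ndarray = field(default_factory=lambda: DEFAULT_STROMAL_REF.copy())
    epithelial_reference: np.ndarray = field(default_factory=lambda: DEFAULT_EPITHELIAL_REF.copy())
    stroma_density: float = STROMA_DENSITY
    cytoplasm_density: float = CYTOPLASM_DENSITY
    nucleus_density: float = NUCLEUS_DENSITY
    ccd_sigma: float = 2.0  # additive sensor noise, intensity counts
    stain_intensity_cv: float = 0.05  # multiplicative staining variation
    stroma_texture: float = 0.12  # smooth spatial modulation of stroma density
    background_intensity: float = 240.0
    bit_depth: int = 8
    rng_seed: int = 0
    quantize: bool = True  # round rendered intensities to integer counts

    def validate(self):
        s, e = np.asarray(self.stromal_reference), np.asarray(self.epithelial_reference)
        if np.linalg.norm(np.cross(s, e)) < 1e-9:
            raise InvalidInputError("stromal and epithelial references are collinear")
        h, w = self.image_size
        for g in self.gland_specs:
            r, c = g.position
            if g.architecture == "bare_nucleus":
                margin = g.nucleus_radius + 2
            else:
                margin = g.size * (1 + g.irregularity) + 2
            if not (margin <= r <= h - margin and margin <= c <= w - margin):
                raise InvalidInputError(f"gland at {g.position} does not fit in {self.image_size}")
            if g.architecture not in GLAND_ARCHITECTURES | TRAP_ARCHITECTURES:
                raise InvalidInputError(f"unknown architecture {g.architecture!r}")


def _star_polygon_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    irregularity: float,
    rng: np.random.Generator,
    n_vertices: int = 72,
) -> np.ndarray:
    """Smoothed random-radius star polygon rasterized to a boolean mask."""
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.full(n_vertices, radius, dtype=float)
    for k in range(2, 6):
        amp = irregularity * radius * rng.uniform(0.3, 1.0)
        r += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    rr = center[0] + r * np.sin(theta)
    cc = center[1] + r * np.cos(theta)
    pr, pc = draw_polygon(rr, cc, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[pr, pc] = True
    return mask


def _disk_mask(shape, center, radius) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(center, radius, shape=shape)
    mask[rr, cc] = True
    return mask


def _paint_gland(
    g: GlandSpec,
    shape: tuple[int, int],
    rng: np.random.Generator,
):
    """Rasterize one gland: footprint, cytoplasm, lumina, nuclei masks."""
    if g.architecture == "bare_nucleus":
        foot = _disk_mask(shape, g.position, g.nucleus_radius)
        return foot, np.zeros(shape, bool), np.zeros(shape, bool), foot

    foot = _star_polygon_mask(shape, g.position, g.size, g.irregularity, rng)
    for dr, dc in g.fused_offsets:
        lobe = _star_polygon_mask(
            shape, (g.position[0] + dr, g.position[1] + dc), g.size, g.irregularity, rng
        )
        foot |= lobe

    lumina = np.zeros(shape, bool)
    if g.architecture == "nucleus_free_trap":
        lumina |= _disk_mask(shape, g.position, g.size * g.lumen_fraction)
    elif g.architecture in ("benign", "well_formed") and g.n_lumina > 0:
        lumina |= _disk_mask(shape, g.position, g.size * g.lumen_fraction)
    elif g.architecture == "cribriform":
        # lumina on a ring at distinct angles so they stay disjoint
        n = max(g.n_lumina, 2)
        phase = rng.uniform(0, 2 * np.pi)
        for i in range(n):
            ang = phase + 2 * np.pi * i / n + rng.uniform(-0.1, 0.1)
            rad = 0.38 * g.size
            ctr = (g.position[0] + rad * np.sin(ang), g.position[1] + rad * np.cos(ang))
            lum = _disk_mask(shape, ctr, g.size * rng.uniform(0.10, 0.14))
            lumina |= lum & ndi.binary_erosion(foot, iterations=3)
    elif g.architecture == "fused":
        centers = [g.position] + [
            (g.position[0] + dr, g.position[1] + dc) for dr, dc in g.fused_offsets
        ]
        for ctr in centers:
            lumina |= _disk_mask(shape, ctr, g.size * 0.35)
    lumina &= foot

    cytoplasm = foot & ~lumina

    nuclei = np.zeros(shape, bool)
    if g.architecture not in TRAP_ARCHITECTURES:
        centers = [g.position] + [
            (g.position[0] + dr, g.position[1] + dc) for dr, dc in g.fused_offsets
        ]
        placed = 0
        per_lobe = max(1, g.n_nuclei // len(centers))
        for ctr in centers:
            for i in range(per_lobe):
                if placed >= g.n_nuclei:
                    break
                ang = 2 * np.pi * (i + rng.uniform(-0.2, 0.2)) / per_lobe
                # nuclei sit basally, between lumen and stromal border
                rad = g.size * (0.0 if g.architecture == "single_cells" else rng.uniform(0.62, 0.78))
                ctr_n = (ctr[0] + rad * np.sin(ang), ctr[1] + rad * np.cos(ang))
                nuc = _disk_mask((foot.shape), ctr_n, g.nucleus_radius)
                nuclei |= nuc & cytoplasm
                placed += 1
    return foot, cytoplasm, lumina, nuclei


def _smooth_field(shape, scale, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-std smooth random field (Gaussian-filtered noise)."""
    raw = rng.standard_normal(shape)
    sm = ndi.gaussian_filter(raw, sigma=scale)
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def generate_tile(spec: TissueSpec) -> tuple[RGBImage, GroundTruthLabels]:
    """Render one tile and its per-pixel ground truth.

    Deterministic given ``spec.rng_seed``.  Raises on gland footprints
    overlapping outside a declared fusion.
    """
    spec.validate()
    h, w = spec.image_size
    rng = np.random.default_rng(spec.rng_seed)

    stromal_density = np.full((h, w), spec.stroma_density)
    if spec.stroma_texture > 0:
        stromal_density *= 1.0 + spec.stroma_texture * _smooth_field((h, w), 15, rng)
        stromal_density = np.maximum(stromal_density, 0.3 * spec.stroma_density)
    epithelial_density = np.zeros((h, w))
    instance_labels = np.zeros((h, w), dtype=np.int32)
    nucleus_mask = np.zeros((h, w), bool)
    architecture_per_instance: dict[int, str] = {}

    for idx, g in enumerate(spec.gland_specs, start=1):
        foot, cytoplasm, lumina, nuclei = _paint_gland(g, (h, w), rng)
        if np.any(instance_labels[foot] > 0):
            other = int(instance_labels[foot][instance_labels[foot] > 0][0])
            raise InvalidInputError(
                f"gland {idx} overlaps gland {other} outside a declared fusion"
            )
        instance_labels[foot] = idx
        architecture_per_instance[idx] = g.architecture
        stromal_density[foot] = 0.0
        epithelial_density[cytoplasm] = spec.cytoplasm_density
        epithelial_density[lumina] = 0.0
        epithelial_density[nuclei] = spec.nucleus_density
        nucleus_mask |= nuclei

    if spec.stain_intensity_cv > 0:
        gain = 1.0 + spec.stain_intensity_cv * _smooth_field((h, w), 25, rng)
        gain = np.maximum(gain, 0.2)
        stromal_density = stromal_density * gain
        epithelial_density = epithelial_density * gain

    M = np.stack([np.asarray(spec.stromal_reference), np.asarray(spec.epithelial_reference)], axis=1)
    od = stromal_density[..., None] * M[:, 0] + epithelial_density[..., None] * M[:, 1]
    i0 = spec.background_intensity
    pixels = i0 * np.exp(-od)
    if spec.ccd_sigma > 0:
        pixels = pixels + rng.normal(0.0, spec.ccd_sigma, size=pixels.shape)
    max_val = 2**spec.bit_depth - 1
    pixels = np.clip(pixels, 0.0, max_val)
    if spec.quantize:
        pixels = np.round(pixels)

    image = RGBImage(
        pixels=pixels,
        background_intensity=np.full(3, i0),
        bit_depth=spec.bit_depth,
    )
    truth = GroundTruthLabels(
        instance_labels=instance_labels,
        architecture_per_instance=architecture_per_instance,
        nucleus_mask=nucleus_mask,
    )
    return image, truth


def _grid_positions(h, w, n, margin, rng: np.random.Generator, jitter=6.0):
    """Jittered grid placement that keeps glands apart and inside the tile."""
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    ys = np.linspace(margin, h - margin, rows)
    xs = np.linspace(margin, w - margin, cols)
    pos = []
    for y in ys:
        for x in xs:
            if len(pos) >= n:
                break
            pos.append((y + rng.uniform(-jitter, jitter), x + rng.uniform(-jitter, jitter)))
    return pos[:n]


def _benign_tile(seed, size=(448, 448)):
    rng = np.random.default_rng(seed)
    h, w = size
    specs = [
        GlandSpec("benign", p, size=rng.uniform(38, 48), n_nuclei=10)
        for p in _grid_positions(h, w, 6, 70, rng)
    ]
    return TissueSpec(image_size=size, gland_specs=specs, rng_seed=seed)


def _grade3_tile(seed, size=(448, 448)):
    rng = np.random.default_rng(seed)
    h, w = size
    specs = [
        GlandSpec("well_formed", p, size=rng.uniform(32, 42), n_nuclei=9)
        for p in _grid_positions(h, w, 9, 60, rng)
    ]
    return TissueSpec(image_size=size, gland_specs=specs, rng_seed=seed)


def _cribriform_tile(seed, size=(448, 448)):
    rng = np.random.default_rng(seed)
    h, w = size
    specs = [
        GlandSpec(
            "cribriform", p, size=rng.uniform(55, 65), n_lumina=int(rng.integers(2, 6)),
            n_nuclei=14,
        )
        for p in _grid_positions(h, w, 4, 90, rng)
    ]
    return TissueSpec(image_size=size, gland_specs=specs, rng_seed=seed)


def _fused_tile(seed, size=(448, 448)):
    rng = np.random.default_rng(seed)
    h, w = size
    specs = [
        GlandSpec(
            "fused", (130, 130 + 180 * i), size=40, n_nuclei=12,
            fused_offsets=((rng.uniform(30, 42), rng.uniform(18, 30)),),
        )
        for i in range(2)
    ]
    specs += [
        GlandSpec(
            "well_formed",
            (h - 85 + rng.uniform(-6, 6), c + rng.uniform(-6, 6)),
            size=rng.uniform(30, 38),
            n_nuclei=8,
        )
        for c in (80, 224, 368)
    ]
    return TissueSpec(image_size=size, gland_specs=specs, rng_seed=seed)


def _grade5_tile(seed, size=(448, 448)):
    rng = np.random.default_rng(seed)
    h, w = size
    specs = [
        GlandSpec(
            "single_cells", p, size=rng.uniform(6.2, 7.2), n_lumina=0, n_nuclei=1,
            nucleus_radius=3.2, irregularity=0.03,
        )
        for p in _grid_positions(h, w, 9, 40, rng)
    ]
    specs += [GlandSpec("well_formed", (h - 80, w - 80), size=36, n_nuclei=8)]
    return TissueSpec(image_size=size, gland_specs=specs, rng_seed=seed)


def _trap_tile(seed, size=(448, 448)):
    rng = np.random.default_rng(seed)
    h, w = size
    specs = [
        GlandSpec("nucleus_free_trap", p, size=rng.uniform(22, 30), n_nuclei=0)
        for p in _grid_positions(h, w // 2, 3, 50, rng)
    ]
    specs += [
        GlandSpec("bare_nucleus", (r, c), nucleus_radius=5.0)
        for r, c in _grid_positions(h, w // 2, 3, 40, rng)
    ]
    for s in specs[3:]:
        s.position = (s.position[0], s.position[1] + w // 2)
    specs += [GlandSpec("well_formed", (h // 2, w // 2), size=34, n_nuclei=8)]
    return TissueSpec(image_size=size, gland_specs=specs, rng_seed=seed)


CATALOGS = {
    "benign": (_benign_tile, 2),
    "grade3": (_grade3_tile, 2),
    "grade4_cribriform": (_cribriform_tile, 2),
    "grade4_fused": (_fused_tile, 2),
    "grade5_cells": (_grade5_tile, 2),
    "nucleus_free_traps": (_trap_tile, 2),
}


def generate_suite(catalog: str, seed: int = 0) -> list[tuple[RGBImage, GroundTruthLabels]]:
    """Generate a named suite of challenge tiles, byte-identical per seed.

    ``mixed`` draws one tile from every other catalog; the remaining
    catalogs each produce a small number of tiles of one architecture.
    """
    if catalog == "mixed":
        tiles = []
        for i, name in enumerate(sorted(CATALOGS)):
            builder, _ = CATALOGS[name]
            tiles.append(generate_tile(builder(seed * 101 + i)))
        return tiles
    if catalog not in CATALOGS:
        raise InvalidInputError(f"unknown catalog {catalog!r}; choose from {sorted(CATALOGS) + ['mixed']}")
    builder, n_tiles = CATALOGS[catalog]
    return [generate_tile(builder(seed * 101 + i)) for i in range(n_tiles)]


def sample_cloud(
    means_barycentric: np.ndarray,
    sigmas,
    weights,
    n: int,
    seed: int = 0,
) -> tuple[ChromaticityCloud, np.ndarray]:
    """Sample a chromaticity cloud from a known planar Gaussian mixture.

    Returns the cloud and the true component label of every point; used
    for EM parameter-recovery tests and stain-quality comparisons (a
    separated pair of clusters emulates PSR-Htx, an overlapped pair
    emulates H&E).
    """
    from .types import barycentric_to_planar

    rng = np.random.default_rng(seed)
    means = barycentric_to_planar(np.asarray(means_barycentric, dtype=float))
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    labels = rng.choice(len(weights), size=n, p=weights)
    pts = np.empty((n, 2))
    for j, sigma in enumerate(np.broadcast_to(np.asarray(sigmas, dtype=float), (len(weights),))):
        sel = labels == j
        pts[sel] = means[j] + sigma * rng.standard_normal((int(sel.sum()), 2))
    bary = planar_to_barycentric(pts)
    cloud = ChromaticityCloud(points=bary, total_od=np.ones(n))
    return cloud, labels
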