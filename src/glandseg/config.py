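"""Pipeline configuration: nested dataclasses with YAML round-trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidConfigError

__all__ = ["BCDConfig", "SegmentationConfig", "EvaluationConfig", "SyntheticConfig", "PipelineConfig"]


@dataclass
class BCDConfig:
    """Color-decomposition parameters.

    ``i0_percentile``: per-channel percentile of the tile used as the
    white level I0 when none is supplied (estimate of unstained
    background).  ``min_total_od``: pixels whose OD sum falls below this
    are treated as background and excluded from the chromaticity cloud.
    ``od_scale``: fixed divisor applied to raw densities so both maps lie
    in [0, 1]; the nucleus-intensity threshold presumes this scale.
    """

    i0_percentile: float = 99.0
    min_total_od: float = 0.10
    od_scale: float = 2.5
    n_stains: int = 2
    em_max_iter: int = 500
    em_tol: float = 1e-8
    em_reg_covar: float = 1e-6
    min_stain_separation: float = 0.05  # barycentric distance below which components count as collapsed
    single_stain_fallback: bool = False

    def validate(self):
        if not (0 < self.i0_percentile <= 100):
            raise InvalidConfigError("i0_percentile must be in (0, 100]")
        if self.min_total_od < 0:
            raise InvalidConfigError("min_total_od must be >= 0")
        if self.od_scale <= 0:
            raise InvalidConfigError("od_scale must be positive")
        if self.n_stains < 1:
            raise InvalidConfigError("n_stains must be >= 1")


@dataclass
class SegmentationConfig:
    """Gland-segmentation parameters.

    Defaults follow the published protocol: a 6 x 6 px opening kernel
    (compromise between separating distinct glands and not merging
    them), a 90 px minimum object size (mean epithelial-nucleus area),
    and a 0.7 nucleus-intensity floor on the epithelial density map.
    """

    opening_kernel: tuple[int, int] = (6, 6)
    min_object_size: int = 90
    min_nucleus_intensity: float = 0.7
    min_nucleus_pixels: int = 10
    erosion_max_axis: int = 9
    tensor_sigma: float = 3.0
    connectivity: int = 8

    def validate(self):
        if any(k <= 0 for k in self.opening_kernel):
            raise InvalidConfigError("opening_kernel sizes must be positive")
        if self.min_object_size <= 0:
            raise InvalidConfigError("min_object_size must be positive")
        if not (0 < self.min_nucleus_intensity <= 1):
            raise InvalidConfigError("min_nucleus_intensity must be in (0, 1]")
        if self.min_nucleus_pixels <= 0:
            raise InvalidConfigError("min_nucleus_pixels must be positive")
        if self.erosion_max_axis <= 0:
            raise InvalidConfigError("erosion_max_axis must be positive")
        if self.tensor_sigma <= 0:
            raise InvalidConfigError("tensor_sigma must be positive")
        if self.connectivity not in (4, 8):
            raise InvalidConfigError("connectivity must be 4 or 8")


@dataclass
class EvaluationConfig:
    """Object-matching thresholds for the correct/over/under categorization.

    These are numeric surrogates for a visual expert judgment and are
    deliberately prominent here.
    """

    iou_match: float = 0.5
    coverage_low: float = 0.2
    coverage_high: float = 0.7

    def validate(self):
        if not (0 < self.coverage_low < self.coverage_high <= 1):
            raise InvalidConfigError("need 0 < coverage_low < coverage_high <= 1")
        if not (0 < self.iou_match <= 1):
            raise InvalidConfigError("iou_match must be in (0, 1]")


@dataclass
class SyntheticConfig:
    """Defaults for the synthetic tile generator."""

    image_size: tuple[int, int] = (512, 512)
    ccd_sigma: float = 2.0
    stain_intensity_cv: float = 0.05

    def validate(self):
        if any(s <= 0 for s in self.image_size):
            raise InvalidConfigError("image_size must be positive")
        if self.ccd_sigma < 0 or self.stain_intensity_cv < 0:
            raise InvalidConfigError("noise levels must be >= 0")


@dataclass
class PipelineConfig:
    bcd: BCDConfig = field(default_factory=BCDConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    seed: int = 0
    verbosity: int = 0

    def validate(self):
        self.bcd.validate()
        self.segmentation.validate()
        self.evaluation.validate()
        self.synthetic.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # YAML has no tuple type; store as lists and restore on load
        d["segmentation"]["opening_kernel"] = list(self.segmentation.opening_kernel)
        d["synthetic"]["image_size"] = list(self.synthetic.image_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        if "bcd" in d:
            cfg.bcd = BCDConfig(**d["bcd"])
        if "segmentation" in d:
            seg = dict(d["segmentation"])
            if "opening_kernel" in seg:
                seg["opening_kernel"] = tuple(seg["opening_kernel"])
            cfg.segmentation = SegmentationConfig(**seg)
        if "evaluation" in d:
            cfg.evaluation = EvaluationConfig(**d["evaluation"])
        if "synthetic" in d:
            syn = dict(d["synthetic"])
            if "image_size" in syn:
                syn["image_size"] = tuple(syn["image_size"])
            cfg.synthetic = SyntheticConfig(**syn)
        cfg.seed = int(d.get("seed", 0))
        cfg.verbosity = int(d.get("verbosity", 0))
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d or {})
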