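"""Pipeline configuration: nested dataclasses mirroring the processing stages.

A flat TOML file with one section per stage (``[denoise]``, ``[sdd]``,
``[entropy]``, ``[segment]``, ``[baseline]``, ``[grid]``) can be loaded with
:func:`PipelineConfig.from_toml`; unknown keys are rejected so that every
parameter in a run is auditable.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

__all__ = [
    "DenoiseConfig",
    "SDDConfig",
    "EntropyConfig",
    "SegmentConfig",
    "BaselineConfig",
    "GridConfig",
    "PipelineConfig",
]


@dataclass
class DenoiseConfig:
    """Non-local-means pre-filter settings (patch sizes in pixels, strength in
    intensity levels)."""

    enabled: bool = True
    patch_size: int = 7
    search_window: int = 21
    strength: float | None = None
    auto_strength: bool = True

    def validate(self) -> None:
        if self.patch_size % 2 == 0 or self.search_window % 2 == 0:
            raise ValueError("patch_size and search_window must be odd")
        if self.patch_size >= self.search_window:
            raise ValueError("patch_size must be smaller than search_window")
        if not self.auto_strength and (self.strength is None or self.strength <= 0):
            raise ValueError("strength must be > 0 when auto_strength is off")


@dataclass
class SDDConfig:
    """Slope-difference-distribution settings.

    ``domain`` selects whether candidate thresholds are discovered on the
    intensity histogram (default; the threshold is an intensity cut) or on
    the gradient-magnitude histogram with the candidate mapped back to an
    intensity level by its fractional histogram position.
    """

    n_bins: int = 256
    fit_window: int = 5
    smooth_sigma: float = 2.0
    domain: str = "intensity"
    range_mode: str = "auto"
    range_A: int | None = None
    range_B: int | None = None

    def validate(self) -> None:
        if self.n_bins < 16:
            raise ValueError("n_bins must be >= 16")
        if self.fit_window < 2:
            raise ValueError("fit_window must be >= 2")
        if self.domain not in ("intensity", "gradient"):
            raise ValueError(f"unknown sdd.domain {self.domain!r}")
        if self.range_mode not in ("auto", "manual"):
            raise ValueError(f"unknown sdd.range_mode {self.range_mode!r}")
        if self.range_mode == "manual" and (self.range_A is None or self.range_B is None):
            raise ValueError("manual range mode requires range_A and range_B")


@dataclass
class EntropyConfig:
    """Threshold-selection settings for the entropy-maximizing search."""

    search_space: str = "candidates"
    exhaustive: bool = False
    polarity: str = "dark"

    def validate(self) -> None:
        if self.search_space not in ("candidates", "levels"):
            raise ValueError(f"unknown entropy.search_space {self.search_space!r}")
        if self.polarity not in ("dark", "bright"):
            raise ValueError(f"unknown entropy.polarity {self.polarity!r}")


@dataclass
class SegmentConfig:
    """Binarization and mask clean-up settings.

    The ``profile`` presets encode two use cases: ``particles`` (isolated
    particles; holes inside a particle are segmentation noise and are
    filled) and ``aggregates`` (dense aggregates; interior pores are real
    structure and hole filling is off).
    """

    polarity: str = "dark"
    min_area: int = 9
    max_area: int | None = None
    fill_holes: bool = True
    convexity_min: float | None = None
    contour_method: str = "boundary"
    profile: str = "particles"

    def validate(self) -> None:
        if self.polarity not in ("dark", "bright"):
            raise ValueError(f"unknown segment.polarity {self.polarity!r}")
        if self.min_area < 0:
            raise ValueError("min_area must be >= 0")
        if self.contour_method not in ("boundary", "canny"):
            raise ValueError(f"unknown segment.contour_method {self.contour_method!r}")
        if self.profile not in ("particles", "aggregates"):
            raise ValueError(f"unknown segment.profile {self.profile!r}")

    def with_profile(self, profile: str) -> "SegmentConfig":
        """Return a copy with profile-dependent defaults applied."""
        cfg = dataclasses.replace(self, profile=profile)
        cfg.fill_holes = profile == "particles"
        cfg.validate()
        return cfg


@dataclass
class BaselineConfig:
    """Settings for the two reference segmenters."""

    method: str = "histogram"
    block_size: int = 51
    offset: float = 5.0

    def validate(self) -> None:
        if self.method not in ("histogram", "dynamic"):
            raise ValueError(f"unknown baseline.method {self.method!r}")
        if self.block_size < 3 or self.block_size % 2 == 0:
            raise ValueError("block_size must be odd and >= 3")


@dataclass
class GridConfig:
    """Grid-cell counting settings; cell_size should be close to one particle
    diameter."""

    cell_size: int = 10
    origin: tuple[int, int] = (0, 0)
    coverage_frac: float = 0.5
    scan_alignments: bool = False

    def validate(self) -> None:
        if self.cell_size < 2:
            raise ValueError("cell_size must be >= 2")
        if not (0 < self.coverage_frac <= 1):
            raise ValueError("coverage_frac must be in (0, 1]")


_SECTIONS = {
    "denoise": DenoiseConfig,
    "sdd": SDDConfig,
    "entropy": EntropyConfig,
    "segment": SegmentConfig,
    "baseline": BaselineConfig,
    "grid": GridConfig,
}


@dataclass
class PipelineConfig:
    """Fully resolved configuration for one pipeline run."""

    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    sdd: SDDConfig = field(default_factory=SDDConfig)
    entropy: EntropyConfig = field(default_factory=EntropyConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    seed: int = 0

    def validate(self) -> None:
        for name in _SECTIONS:
            getattr(self, name).validate()

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        cfg = cls()
        for section, values in data.items():
            if section == "seed":
                cfg.seed = int(values)
                continue
            if section not in _SECTIONS:
                raise ValueError(f"unknown config section {section!r}")
            sub_cls = _SECTIONS[section]
            known = {f.name for f in fields(sub_cls)}
            unknown = set(values) - known
            if unknown:
                raise ValueError(
                    f"unknown keys in [{section}]: {sorted(unknown)}"
                )
            sub = getattr(cfg, section)
            for key, val in values.items():
                if key == "origin":
                    val = tuple(int(v) for v in val)
                setattr(sub, key, val)
        cfg.validate()
        return cfg

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)
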