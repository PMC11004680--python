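"""End-to-end fusion of a registered structural/functional image pair.

The pipeline is: HSV transform on both inputs -> (optional) contrast
stretch of the value channels -> MLGEPF decomposition of each value channel
into SC(1..3), LC(1..3), BC -> ST-PCNN winner-take-all fusion of each
corresponding SC/LC pair -> elementwise-maximum fusion of the BC pair ->
linear addition of the seven fused layers -> clip to [0, 1] -> inverse HSV.

Colour policy: fusion acts on value channels only; hue and saturation of
the output are copied from the functional (PET/SPECT) image, whose colour
encodes the physiology — the structural image carries no chroma.  Setting
``fuse_saturation`` additionally fuses the saturation channels through the
same layer machinery.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from .decomposition import DEFAULT_SIGMAS, LayerStack, mlgepf_decompose, recompose
from .enhancement import enhance_contrast
from .exceptions import DimensionError
from .filters import GuidedFilterParams
from .image_io import HsvImage, read_image, to_working_pair, write_image
from .pcnn_fusion import PcnnParams, fuse_layer

__all__ = ["FusionConfig", "fuse_bc", "fuse_stacks", "fuse_pair", "fuse_files"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FusionConfig:
    """All tunables of the pipeline, nestable from a YAML mapping."""

    levels: int = 3
    guided: GuidedFilterParams = field(default_factory=GuidedFilterParams)
    sigmas: tuple[float, ...] = DEFAULT_SIGMAS
    pcnn: PcnnParams = field(default_factory=PcnnParams)
    enhancement_enabled: bool = False
    enhancement_low_pct: float = 1.0
    enhancement_high_pct: float = 99.0
    fuse_saturation: bool = False
    prefer_earlier_firing: bool = False

    def __post_init__(self) -> None:
        if len(self.sigmas) != self.levels:
            raise ValueError(
                f"len(sigmas)={len(self.sigmas)} must equal levels={self.levels}"
            )

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "FusionConfig":
        """Build from a (possibly partial) nested mapping mirroring the YAML
        layout: filters.guided.{radius,eps}, filters.gaussian.sigmas,
        pcnn.*, enhancement.{enabled,low_pct,high_pct},
        colour.fuse_saturation, selection.prefer_earlier_firing."""
        kw: dict[str, Any] = {}
        filters = d.get("filters", {})
        if "guided" in filters:
            kw["guided"] = GuidedFilterParams(**filters["guided"])
        if "gaussian" in filters and "sigmas" in filters["gaussian"]:
            kw["sigmas"] = tuple(filters["gaussian"]["sigmas"])
            kw["levels"] = len(kw["sigmas"])
        if "levels" in d:
            kw["levels"] = d["levels"]
        if "pcnn" in d:
            pk = dict(d["pcnn"])
            if "linking_kernel" in pk:
                pk["linking_kernel"] = tuple(tuple(row) for row in pk["linking_kernel"])
            kw["pcnn"] = PcnnParams(**pk)
        enh = d.get("enhancement", {})
        if "enabled" in enh:
            kw["enhancement_enabled"] = bool(enh["enabled"])
        if "low_pct" in enh:
            kw["enhancement_low_pct"] = float(enh["low_pct"])
        if "high_pct" in enh:
            kw["enhancement_high_pct"] = float(enh["high_pct"])
        if "fuse_saturation" in d.get("colour", {}):
            kw["fuse_saturation"] = bool(d["colour"]["fuse_saturation"])
        if "prefer_earlier_firing" in d.get("selection", {}):
            kw["prefer_earlier_firing"] = bool(d["selection"]["prefer_earlier_firing"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FusionConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict[str, Any]:
        return {
            "levels": self.levels,
            "filters": {
                "guided": {"radius": self.guided.radius, "eps": self.guided.eps},
                "gaussian": {"sigmas": list(self.sigmas)},
            },
            "pcnn": {
                "iterations": self.pcnn.iterations,
                "alpha_theta": self.pcnn.alpha_theta,
                "v_theta": self.pcnn.v_theta,
                "alpha_l": self.pcnn.alpha_l,
                "v_l": self.pcnn.v_l,
                "theta_init": self.pcnn.theta_init,
                "linking_kernel": [list(r) for r in self.pcnn.linking_kernel],
            },
            "enhancement": {
                "enabled": self.enhancement_enabled,
                "low_pct": self.enhancement_low_pct,
                "high_pct": self.enhancement_high_pct,
            },
            "colour": {"fuse_saturation": self.fuse_saturation},
            "selection": {"prefer_earlier_firing": self.prefer_earlier_firing},
        }

    def with_enhancement(self, enabled: bool = True) -> "FusionConfig":
        return replace(self, enhancement_enabled=enabled)


def fuse_bc(bc_a: np.ndarray, bc_b: np.ndarray) -> np.ndarray:
    """Maximum fusion of the background components: the fused background
    keeps, per pixel, the brighter of the two bases."""
    bc_a = np.asarray(bc_a, dtype=np.float64)
    bc_b = np.asarray(bc_b, dtype=np.float64)
    if bc_a.shape != bc_b.shape:
        raise DimensionError(f"BC shapes differ: {bc_a.shape} vs {bc_b.shape}")
    return np.maximum(bc_a, bc_b)


def fuse_stacks(stack_a: LayerStack, stack_b: LayerStack, cfg: FusionConfig) -> LayerStack:
    """Fuse two layer stacks level by level: SC/LC pairs by ST-PCNN
    selection (stack_a in the structural slot), BC by maximum."""
    if stack_a.levels != stack_b.levels:
        raise DimensionError(
            f"stacks have different level counts: {stack_a.levels} vs {stack_b.levels}"
        )
    sel = dict(p=cfg.pcnn, prefer_earlier=cfg.prefer_earlier_firing)
    return LayerStack(
        sc=[fuse_layer(a, b, **sel) for a, b in zip(stack_a.sc, stack_b.sc)],
        lc=[fuse_layer(a, b, **sel) for a, b in zip(stack_a.lc, stack_b.lc)],
        bc=fuse_bc(stack_a.bc, stack_b.bc),
        source_shape=stack_a.source_shape,
    )


def _fuse_channel(ch_a: np.ndarray, ch_b: np.ndarray, cfg: FusionConfig) -> np.ndarray:
    if cfg.enhancement_enabled:
        ch_a = enhance_contrast(ch_a, cfg.enhancement_low_pct, cfg.enhancement_high_pct)
        ch_b = enhance_contrast(ch_b, cfg.enhancement_low_pct, cfg.enhancement_high_pct)
    t0 = time.perf_counter()
    stack_a = mlgepf_decompose(ch_a, cfg.levels, cfg.guided, cfg.sigmas)
    stack_b = mlgepf_decompose(ch_b, cfg.levels, cfg.guided, cfg.sigmas)
    t1 = time.perf_counter()
    fused = fuse_stacks(stack_a, stack_b, cfg)
    t2 = time.perf_counter()
    logger.info("decompose %.3fs, fuse layers %.3fs", t1 - t0, t2 - t1)
    return np.clip(recompose(fused), 0.0, 1.0)


def fuse_pair(
    structural: HsvImage, functional: HsvImage, cfg: FusionConfig | None = None
) -> HsvImage:
    """Fuse a registered pair and return the fused HSV image.

    The fused value channel is rebuilt from the fused layers and clipped to
    [0, 1] once, after recomposition (clipping the signed layers themselves
    would break additivity).  Hue — and by default saturation — pass
    through from the functional image untouched.
    """
    cfg = cfg or FusionConfig()
    v_a, v_b, func = to_working_pair(structural, functional)
    fused_v = _fuse_channel(v_a, v_b, cfg)
    fused_s = (
        _fuse_channel(structural.s, func.s, cfg) if cfg.fuse_saturation else func.s.copy()
    )
    return HsvImage(h=func.h.copy(), s=fused_s, v=fused_v)


def fuse_files(
    path_a: str | Path,
    path_b: str | Path,
    out_path: str | Path,
    cfg: FusionConfig | None = None,
) -> Path:
    """Read two image files, fuse them, write the result to ``out_path``."""
    cfg = cfg or FusionConfig()
    logger.info("config: %s", cfg.to_dict())
    t0 = time.perf_counter()
    a = read_image(path_a)
    b = read_image(path_b)
    if a.shape != b.shape:
        raise DimensionError(
            f"{path_a} ({a.shape}) and {path_b} ({b.shape}) are not co-registered"
        )
    fused = fuse_pair(a, b, cfg)
    out = write_image(fused, out_path)
    logger.info("fused %s + %s -> %s in %.3fs", path_a, path_b, out, time.perf_counter() - t0)
    return out
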