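"""Declarative run configuration with lossless YAML round-tripping.

A :class:`RunConfig` describes a full run: corpus parameters, acquisition
geometry, network settings, reconstruction grid and the master seed.  The
master seed hierarchically derives all per-stage seeds (dataset, split,
network initialization) through ``numpy.random.SeedSequence`` spawning, so
stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .phantoms import AugmentationSpec, MouseParams
from .pipeline import PipelineConfig
from .projector import Geometry
from .recon import GridSpec

__all__ = ["RunConfig", "derive_stage_seeds"]

STAGES = ("dataset", "split", "network", "noise")


def derive_stage_seeds(master_seed: int) -> dict:
    """Per-stage seeds (< 2**31) derived from one master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(STAGES))
    return {name: int(c.generate_state(1)[0] % 2**31)
            for name, c in zip(STAGES, children)}


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a full simulate/train/evaluate run."""

    master_seed: int = 0
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    grid: GridSpec = field(default_factory=GridSpec.desk)
    recon_filter: str = "ram-lak"
    noise_photons: float | None = None

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return _listify(d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def save(self, path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        pl = dict(d.pop("pipeline", {}))
        if "geometry" in pl:
            g = dict(pl["geometry"])
            for key in ("det_size_mm", "pixel_mm", "rotation_axis"):
                if key in g:
                    g[key] = tuple(g[key])
            pl["geometry"] = Geometry(**g)
        if "mouse_params" in pl:
            m = dict(pl["mouse_params"])
            for key in ("shape", "voxel_size", "body_length_frac",
                        "body_width_frac"):
                if key in m:
                    m[key] = tuple(m[key])
            pl["mouse_params"] = MouseParams(**m)
        if "augmentation" in pl:
            a = dict(pl["augmentation"])
            for key in ("voxel_range", "angle_range"):
                if a.get(key) is not None:
                    a[key] = tuple(a[key])
            pl["augmentation"] = AugmentationSpec(**a)
        for key in ("cylinder_shape", "cylinder_voxel"):
            if key in pl:
                pl[key] = tuple(pl[key])
        d["pipeline"] = PipelineConfig(**pl)
        if "grid" in d:
            g = dict(d["grid"])
            g["shape"] = tuple(g["shape"])
            g["voxel_mm"] = tuple(g["voxel_mm"])
            if g.get("origin_mm") is not None:
                g["origin_mm"] = tuple(g["origin_mm"])
            d["grid"] = GridSpec(**g)
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    def stage_seeds(self) -> dict:
        return derive_stage_seeds(self.master_seed)


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, list):
        return [_listify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
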