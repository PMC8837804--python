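"""File formats: projection stacks, phantoms, volumes, spectra, checkpoints.

* Projection sets: multi-page 32-bit float TIFF (one page per angle) plus a
  YAML sidecar (``<stem>.geometry.yaml``) holding distances, pixel pitch,
  angles, kind and metadata; the reader cross-validates both.
* Phantoms: NIfTI label volume with the voxel size in the affine, plus a
  YAML material sidecar (label, name, density, composition).
* Volumes: NIfTI with voxel-spacing metadata, values in 1/cm.
* Spectra: two-column text (energy keV, relative fluence).
* Model checkpoints: ``.npz`` weights next to a YAML config/history file.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
import yaml

from .network import NetConfig, TrainedModel, UNet, build_network
from .phantoms import VoxelPhantom
from .physics import Material, load_spectrum, save_spectrum  # noqa: F401 (re-export)
from .projector import Geometry, ProjectionSet
from .recon import Volume

__all__ = [
    "write_projections",
    "read_projections",
    "write_phantom",
    "read_phantom",
    "write_volume",
    "read_volume",
    "save_checkpoint",
    "load_checkpoint",
    "load_spectrum",
    "save_spectrum",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".geometry.yaml")


def write_projections(proj: ProjectionSet, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, proj.images.astype(np.float32),
                     photometric="minisblack")
    g = proj.geometry
    meta = {
        "kind": proj.kind,
        "angles_deg": [float(a) for a in proj.angles],
        "geometry": {
            "sid_mm": g.sid_mm, "idd_mm": g.idd_mm,
            "det_size_mm": list(g.det_size_mm),
            "pixel_mm": list(g.pixel_mm),
            "rotation_axis": list(g.rotation_axis),
        },
        "meta": _plain(proj.meta),
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_projections(path) -> ProjectionSet:
    path = Path(path)
    images = tifffile.imread(path)
    if images.ndim == 2:
        images = images[None]
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(f"missing geometry sidecar {side}")
    meta = yaml.safe_load(side.read_text())
    gd = meta["geometry"]
    geometry = Geometry(gd["sid_mm"], gd["idd_mm"], tuple(gd["det_size_mm"]),
                        tuple(gd["pixel_mm"]), tuple(gd["rotation_axis"]))
    angles = np.asarray(meta["angles_deg"], float)
    if images.shape[0] != angles.size:
        raise ValueError(
            f"{path}: {images.shape[0]} pages but {angles.size} angles in sidecar")
    return ProjectionSet(images, angles, geometry, meta["kind"],
                         meta.get("meta") or {})


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_phantom(phantom: VoxelPhantom, path) -> None:
    path = Path(path)
    affine = np.diag([*phantom.voxel_size, 1.0])
    affine[:3, 3] = phantom.origin
    nib.save(nib.Nifti1Image(phantom.labels.astype(np.int16), affine), path)
    table = {
        int(label): {
            "name": m.name,
            "density_g_cm3": float(m.density),
            "composition": {k: float(v) for k, v in m.composition.items()},
        }
        for label, m in phantom.materials.items()
    }
    path.with_suffix("").with_suffix(".materials.yaml").write_text(
        yaml.safe_dump(table, sort_keys=True))


def read_phantom(path) -> VoxelPhantom:
    path = Path(path)
    img = nib.load(path)
    labels = np.asarray(img.dataobj, dtype=np.int16)
    affine = img.affine
    voxel = tuple(float(affine[i, i]) for i in range(3))
    origin = tuple(float(affine[i, 3]) for i in range(3))
    side = path.with_suffix("").with_suffix(".materials.yaml")
    if not side.exists():
        raise FileNotFoundError(f"missing material sidecar {side}")
    table = yaml.safe_load(side.read_text())
    materials = {
        int(label): Material(entry["name"], dict(entry["composition"]),
                             float(entry["density_g_cm3"]))
        for label, entry in table.items()
    }
    return VoxelPhantom(labels, voxel, origin, materials)


def write_volume(volume: Volume, path) -> None:
    affine = np.diag([*volume.voxel_mm, 1.0])
    affine[:3, 3] = volume.origin_mm
    nib.save(nib.Nifti1Image(volume.values.astype(np.float32), affine), Path(path))


def read_volume(path) -> Volume:
    img = nib.load(Path(path))
    values = np.asarray(img.dataobj, dtype=np.float32)
    affine = img.affine
    voxel = tuple(float(affine[i, i]) for i in range(3))
    origin = tuple(float(affine[i, 3]) for i in range(3))
    return Volume(values, voxel, origin)


def save_checkpoint(trained: TrainedModel, path) -> None:
    """Weights as .npz plus a YAML file with config, history, provenance."""
    path = Path(path)
    weights = trained.model.get_weights()
    np.savez(path.with_suffix(".npz"),
             **{f"w{i}": w for i, w in enumerate(weights)})
    info = {
        "config": _plain(vars(trained.config)),
        "history": _plain(trained.history),
        "provenance": _plain(trained.provenance),
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(info, sort_keys=False))


def load_checkpoint(path) -> TrainedModel:
    path = Path(path)
    info = yaml.safe_load(path.with_suffix(".yaml").read_text())
    config = NetConfig(**info["config"])
    model = build_network(config)
    data = np.load(path.with_suffix(".npz"))
    model.set_weights([data[f"w{i}"] for i in range(len(data.files))])
    return TrainedModel(model, config, info["history"], info["provenance"])
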