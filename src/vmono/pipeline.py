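"""Desk-scale end-to-end pipeline: simulate -> train -> predict -> evaluate.

This is the reduced-size counterpart of the full study protocol (9 mouse
phantoms x 105 pairs + 945 cylinder pairs, 7-level network, 300 epochs): a
64 x 64-pixel detector, 200 projection pairs (6 procedural mouse phantoms
x 20 pairs + 80 cylinder pairs), a depth-4/base-8 network and 100 epochs.
The 80/20 split, batch size 18, Adam moments and the MAE loss are kept; the
learning rate is scaled inversely with the number of weight updates (see
docs/methods.md).  Every stage draws its seed from one master seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from . import network as net_mod
from .metrics import AIR_THRESHOLD, mae, percentage_error
from .phantoms import AugmentationSpec, MouseParams, make_dataset
from .physics import DetectorModel, imaging_spectrum
from .projector import Geometry, simulate_pair

__all__ = ["PipelineConfig", "simulate_corpus", "run_end_to_end"]


@dataclass(frozen=True)
class PipelineConfig:
    """Study conditions of the desk-scale end-to-end run."""

    n_mouse_phantoms: int = 6
    pairs_per_phantom: int = 20
    n_cylinder_pairs: int = 80
    geometry: Geometry = field(default_factory=lambda: Geometry.desk(64, 0.7))
    mouse_params: MouseParams = field(default_factory=MouseParams)
    cylinder_shape: tuple = (64, 64, 64)
    cylinder_voxel: tuple = (0.25, 0.25, 0.25)
    # full-range voxel/elemental/density augmentation; the translation range
    # is scaled to the reduced field of view (see docs/methods.md)
    augmentation: AugmentationSpec = field(
        default_factory=lambda: AugmentationSpec(translation_mm=2.5))
    kvp: float = 60.0
    mono_energy_kev: float = 35.0
    train_fraction: float = 0.8
    air_threshold: float = AIR_THRESHOLD
    depth: int = 4
    base_features: int = 8
    epochs: int = 100
    learning_rate: float = 6e-3
    lr_schedule: str = "cosine"
    batch_size: int = 18

    @property
    def n_pairs(self) -> int:
        return self.n_mouse_phantoms * self.pairs_per_phantom + self.n_cylinder_pairs


def _derive_seeds(master_seed: int, n: int):
    ss = np.random.SeedSequence(master_seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def simulate_corpus(config: PipelineConfig, seed: int, verbose: bool = False):
    """Render the full (poly, mono) image corpus; returns (X, Y, specs)."""
    specs = make_dataset(config.n_mouse_phantoms, config.pairs_per_phantom,
                         config.n_cylinder_pairs, seed=seed,
                         augmentation=config.augmentation)
    spectrum = imaging_spectrum(config.kvp)
    detector = DetectorModel()
    g = config.geometry
    x = np.empty((len(specs), g.n_v, g.n_u), np.float32)
    y = np.empty_like(x)
    t0 = time.time()
    for i, spec in enumerate(specs):
        poly, mono = simulate_pair(
            spec, g, spectrum, detector, config.augmentation,
            config.mouse_params, config.cylinder_shape, config.cylinder_voxel,
            config.mono_energy_kev)
        x[i] = poly.images[0]
        y[i] = mono.images[0]
        if verbose and (i + 1) % 50 == 0:
            print(f"  simulated {i + 1}/{len(specs)} pairs "
                  f"({time.time() - t0:.0f} s)")
    return x, y, specs


def run_end_to_end(seed: int = 0, config: PipelineConfig | None = None,
                   verbose: bool = False) -> dict:
    """Simulate, split 80/20, train, and evaluate on the held-out pairs.

    Returns a dict with the trained model, the split, the loss history and
    the held-out metrics (air-excluded mean/SD percentage error and MAE).
    """
    config = config or PipelineConfig()
    data_seed, split_seed, net_seed = _derive_seeds(seed, 3)

    if verbose:
        print(f"simulating {config.n_pairs} projection pairs ...")
    x, y, specs = simulate_corpus(config, data_seed, verbose=verbose)

    tr_idx, te_idx = net_mod.split_indices(len(specs), config.train_fraction,
                                           split_seed)
    net_cfg = net_mod.NetConfig(
        depth=config.depth, base_features=config.base_features,
        learning_rate=config.learning_rate, batch_size=config.batch_size,
        epochs=config.epochs, lr_schedule=config.lr_schedule, seed=net_seed)
    model = net_mod.build_network(net_cfg)
    if verbose:
        print(f"training {net_cfg.depth}-level network "
              f"({model.num_params} parameters, {config.epochs} epochs) ...")
    trained = net_mod.train(model, x[tr_idx, None], y[tr_idx, None], net_cfg,
                            x[te_idx, None], y[te_idx, None], verbose=verbose)

    pred = net_mod.predict_images(trained, x[te_idx])
    summary = percentage_error(pred, y[te_idx], config.air_threshold)
    test_mae = mae(pred, y[te_idx])
    return {
        "config": config,
        "trained": trained,
        "train_indices": tr_idx,
        "test_indices": te_idx,
        "specs": specs,
        "poly": x,
        "mono": y,
        "predicted_test": pred,
        "percentage_error_mean": summary.mean,
        "percentage_error_std": summary.std,
        "test_mae": test_mae,
        "n_test": int(te_idx.size),
    }
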