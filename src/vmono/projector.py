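"""Deterministic primary-beam cone-beam forward projection (pancake geometry).

A point X-ray source and a flat-panel detector are stationary while the
phantom rotates about the +z axis through the isocenter.  Because every
phantom's long axis lies along +x (in the rotation plane), the beam
alternates between short lateral and long longitudinal paths as the animal
turns -- the pancake convention.  A conventional acquisition (rotation about
the long axis) is obtained by simply building the phantom with its long
axis along +z.

Per projection angle, exact radiological path lengths through the voxel
grid are accumulated per material label with an incremental ray-grid
(Siddon-style) traversal, and the transmitted signal follows Beer-Lambert::

    I = sum_E w(E) D(E) exp(-sum_m mu_m(E) l_m),        p = -ln(I / I0)

with w the source spectrum, D the detector energy response, mu_m the linear
attenuation of material m and l_m its intersection length.  Only the primary
beam is modelled: no scatter fluence, no secondary electrons, no focal-spot
blur.  Optional Poisson noise can be applied to the transmitted intensity at
a configurable flood-level photon count.

Angle convention: degrees, counterclockwise, 0 deg = beam along +x
(source at x = -SID).  Path lengths are handled in cm and attenuation in
1/cm; detector coordinates are mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from . import physics
from .physics import (DetectorModel, Spectrum, detector_response, material_mu,
                      mono_spectrum)
from .phantoms import (AugmentationSpec, SimulationSpec, VoxelPhantom, augment,
                       make_mouse_phantom, make_random_cylinder_phantom,
                       MouseParams)

log = logging.getLogger(__name__)

__all__ = [
    "Geometry",
    "ProjectionSet",
    "MaterialPathLengths",
    "siddon_raypaths",
    "flood_field",
    "project_mono",
    "project_poly",
    "simulate_pair",
]


@dataclass(frozen=True)
class Geometry:
    """Cone-beam acquisition geometry (defaults: the table-rotating pancake platform)."""

    sid_mm: float = 353.4          # source to isocenter
    idd_mm: float = 271.0          # isocenter to detector
    det_size_mm: tuple = (176.0, 128.0)    # (u, v) active area
    pixel_mm: tuple = (0.5, 0.5)
    rotation_axis: tuple = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if self.sid_mm <= 0 or self.idd_mm <= 0:
            raise ValueError("distances must be > 0")
        if any(p <= 0 for p in self.pixel_mm):
            raise ValueError("pixel pitch must be > 0")
        if tuple(self.rotation_axis) != (0.0, 0.0, 1.0):
            raise ValueError("only a +z rotation axis is supported")

    @property
    def sdd_mm(self) -> float:
        return self.sid_mm + self.idd_mm

    @property
    def n_u(self) -> int:
        return int(round(self.det_size_mm[0] / self.pixel_mm[0]))

    @property
    def n_v(self) -> int:
        return int(round(self.det_size_mm[1] / self.pixel_mm[1]))

    @property
    def magnification(self) -> float:
        return self.sdd_mm / self.sid_mm

    @property
    def fan_angle_deg(self) -> float:
        """Full fan opening angle in the rotation plane."""
        return 2.0 * np.degrees(np.arctan2(0.5 * self.det_size_mm[0], self.sdd_mm))

    @classmethod
    def desk(cls, n: int = 64, pixel_mm: float = 0.7) -> "Geometry":
        """A reduced n x n detector for desk-scale studies."""
        return cls(det_size_mm=(n * pixel_mm, n * pixel_mm),
                   pixel_mm=(pixel_mm, pixel_mm))


def _check_angles(angles) -> np.ndarray:
    a = np.atleast_1d(np.asarray(angles, dtype=float))
    if np.any((a < 0) | (a >= 360)):
        raise ValueError("angles must lie in [0, 360)")
    return a


@dataclass
class ProjectionSet:
    """A stack of line-integral images p = -ln(I/I0) with its geometry."""

    images: np.ndarray        # (n_angles, n_v, n_u), float32
    angles: np.ndarray        # degrees
    geometry: Geometry
    kind: str                 # 'poly' | 'mono' | 'predicted-mono'
    meta: dict = field(default_factory=dict)

    KINDS = ("poly", "mono", "predicted-mono")

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        self.angles = _check_angles(self.angles)
        if self.kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}")
        if self.images.ndim != 3:
            raise ValueError("images must be (n_angles, n_v, n_u)")
        n, nv, nu = self.images.shape
        if n != self.angles.size:
            raise ValueError("one image per angle required")
        g = self.geometry
        if (nv, nu) != (g.n_v, g.n_u):
            raise ValueError(
                f"image size {(nv, nu)} inconsistent with geometry "
                f"{(g.n_v, g.n_u)}")

    def __len__(self):
        return self.images.shape[0]


@dataclass
class MaterialPathLengths:
    """Per-pixel, per-label ray intersection lengths in cm."""

    lengths: np.ndarray       # (n_v, n_u, n_labels_max)
    geometry: Geometry
    angle: float

    def total(self) -> np.ndarray:
        """Total in-grid path per pixel in cm (all labels, including air)."""
        return self.lengths.sum(axis=-1)


@njit(cache=True)
def _siddon_kernel(labels, dx, dy, dz, ox, oy, oz, src, pix, out):
    """Accumulate per-material intersection lengths (mm) for each ray."""
    nx, ny, nz = labels.shape
    ex = ox + nx * dx
    ey = oy + ny * dy
    ez = oz + nz * dz
    n_pix = pix.shape[0]
    for p in range(n_pix):
        rx = pix[p, 0] - src[0]
        ry = pix[p, 1] - src[1]
        rz = pix[p, 2] - src[2]
        # slab clipping of the parameter t in [0, 1]
        t0 = 0.0
        t1 = 1.0
        ok = True
        for axis in range(3):
            if axis == 0:
                r, s0, lo, hi = rx, src[0], ox, ex
            elif axis == 1:
                r, s0, lo, hi = ry, src[1], oy, ey
            else:
                r, s0, lo, hi = rz, src[2], oz, ez
            if r == 0.0:
                if s0 < lo or s0 > hi:
                    ok = False
                    break
            else:
                ta = (lo - s0) / r
                tb = (hi - s0) / r
                if ta > tb:
                    ta, tb = tb, ta
                if ta > t0:
                    t0 = ta
                if tb < t1:
                    t1 = tb
        if not ok or t1 <= t0:
            continue
        rnorm = np.sqrt(rx * rx + ry * ry + rz * rz)
        eps = 1e-9
        tm = t0 + eps
        px = src[0] + tm * rx
        py = src[1] + tm * ry
        pz = src[2] + tm * rz
        ix = int(np.floor((px - ox) / dx))
        iy = int(np.floor((py - oy) / dy))
        iz = int(np.floor((pz - oz) / dz))
        if ix < 0:
            ix = 0
        if ix > nx - 1:
            ix = nx - 1
        if iy < 0:
            iy = 0
        if iy > ny - 1:
            iy = ny - 1
        if iz < 0:
            iz = 0
        if iz > nz - 1:
            iz = nz - 1
        big = 1e30
        if rx > 0:
            step_x, t_max_x, t_del_x = 1, (ox + (ix + 1) * dx - src[0]) / rx, dx / rx
        elif rx < 0:
            step_x, t_max_x, t_del_x = -1, (ox + ix * dx - src[0]) / rx, -dx / rx
        else:
            step_x, t_max_x, t_del_x = 0, big, big
        if ry > 0:
            step_y, t_max_y, t_del_y = 1, (oy + (iy + 1) * dy - src[1]) / ry, dy / ry
        elif ry < 0:
            step_y, t_max_y, t_del_y = -1, (oy + iy * dy - src[1]) / ry, -dy / ry
        else:
            step_y, t_max_y, t_del_y = 0, big, big
        if rz > 0:
            step_z, t_max_z, t_del_z = 1, (oz + (iz + 1) * dz - src[2]) / rz, dz / rz
        elif rz < 0:
            step_z, t_max_z, t_del_z = -1, (oz + iz * dz - src[2]) / rz, -dz / rz
        else:
            step_z, t_max_z, t_del_z = 0, big, big

        tcur = t0
        while tcur < t1 - eps:
            if t_max_x <= t_max_y and t_max_x <= t_max_z:
                tnext = t_max_x
                axis_hit = 0
            elif t_max_y <= t_max_z:
                tnext = t_max_y
                axis_hit = 1
            else:
                tnext = t_max_z
                axis_hit = 2
            if tnext > t1:
                tnext = t1
            seg = (tnext - tcur) * rnorm
            if seg > 0.0:
                m = labels[ix, iy, iz]
                out[p, m] += seg
            tcur = tnext
            if tnext >= t1:
                break
            if axis_hit == 0:
                ix += step_x
                t_max_x += t_del_x
                if ix < 0 or ix >= nx:
                    break
            elif axis_hit == 1:
                iy += step_y
                t_max_y += t_del_y
                if iy < 0 or iy >= ny:
                    break
            else:
                iz += step_z
                t_max_z += t_del_z
                if iz < 0 or iz >= nz:
                    break


def _rot_z(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _detector_positions(geometry: Geometry) -> np.ndarray:
    """Unrotated lab-frame pixel-center positions, shape (n_v * n_u, 3)."""
    g = geometry
    u = (np.arange(g.n_u) - (g.n_u - 1) / 2) * g.pixel_mm[0]
    v = (np.arange(g.n_v) - (g.n_v - 1) / 2) * g.pixel_mm[1]
    vv, uu = np.meshgrid(v, u, indexing="ij")
    pos = np.empty((g.n_v * g.n_u, 3))
    pos[:, 0] = g.idd_mm
    pos[:, 1] = uu.ravel()
    pos[:, 2] = vv.ravel()
    return pos


def siddon_raypaths(phantom: VoxelPhantom, geometry: Geometry,
                    angle: float) -> MaterialPathLengths:
    """Exact per-material radiological path lengths at one projection angle.

    The phantom rotates by ``angle`` about +z; equivalently source and
    detector are rotated by ``-angle`` in the phantom frame, which is what
    is computed here.  Rays missing the grid give all-zero lengths.
    """
    _check_angles([angle % 360.0])
    g = geometry
    rot = _rot_z(-angle)
    src = rot @ np.array([-g.sid_mm, 0.0, 0.0])
    pix = _detector_positions(g) @ rot.T
    n_lab = int(phantom.labels.max()) + 1
    out = np.zeros((pix.shape[0], n_lab))
    _siddon_kernel(phantom.labels, float(phantom.voxel_size[0]),
                   float(phantom.voxel_size[1]), float(phantom.voxel_size[2]),
                   float(phantom.origin[0]), float(phantom.origin[1]),
                   float(phantom.origin[2]), src, pix, out)
    lengths = (out / 10.0).reshape(g.n_v, g.n_u, n_lab)  # mm -> cm
    return MaterialPathLengths(lengths, geometry, float(angle))


def flood_field(spectrum: Spectrum, detector: DetectorModel | None = None,
                db=None) -> float:
    """Open-beam detector signal I0 = sum_E w(E) D(E); uniform across pixels."""
    detector = detector or DetectorModel()
    d = detector_response(spectrum.grid, detector, db)
    i0 = float(np.sum(spectrum.weights * d))
    if i0 <= 0:
        raise ValueError("flood field is zero: empty spectrum/response overlap")
    return i0


def _mu_table(phantom: VoxelPhantom, energies, db=None) -> np.ndarray:
    """mu(E) per label, shape (n_labels_max, n_E); absent labels are zero."""
    e = np.atleast_1d(np.asarray(
        energies.energies if hasattr(energies, "energies") else energies, float))
    n_lab = int(phantom.labels.max()) + 1
    table = np.zeros((n_lab, e.size))
    for label, mat in phantom.materials.items():
        if label < n_lab:
            table[label] = material_mu(mat, e, db)
    return table


def project_mono(phantom: VoxelPhantom, geometry: Geometry,
                 energy: float = physics.MONO_ENERGY_KEV,
                 angles=(0.0,), db=None) -> ProjectionSet:
    """Noise-free monoenergetic line integrals p = sum_m mu_m(E) l_m."""
    angles = _check_angles(angles)
    mu = _mu_table(phantom, [energy], db)[:, 0]
    images = np.empty((angles.size, geometry.n_v, geometry.n_u), np.float32)
    for i, ang in enumerate(angles):
        paths = siddon_raypaths(phantom, geometry, ang)
        images[i] = paths.lengths @ mu
    return ProjectionSet(images, angles, geometry, "mono",
                         {"energy_keV": float(energy)})


def project_poly(phantom: VoxelPhantom, geometry: Geometry, spectrum: Spectrum,
                 detector: DetectorModel | None = None, angles=(0.0,),
                 noise_photons: float | None = None, seed: int | None = None,
                 db=None) -> ProjectionSet:
    """Polyenergetic line integrals with the full spectral Beer-Lambert sum.

    ``noise_photons`` switches on Poisson noise with that expected photon
    count per pixel at flood level (off by default); seeded, deterministic.
    """
    angles = _check_angles(angles)
    detector = detector or DetectorModel()
    d = detector_response(spectrum.grid, detector, db)
    wd = spectrum.weights * d
    i0 = float(np.sum(wd))
    if i0 <= 0:
        raise ValueError("flood field is zero")
    mu = _mu_table(phantom, spectrum.grid, db)        # (n_lab, n_E)
    rng = np.random.default_rng(seed)
    images = np.empty((angles.size, geometry.n_v, geometry.n_u), np.float32)
    n_clamped = 0
    for i, ang in enumerate(angles):
        paths = siddon_raypaths(phantom, geometry, ang)
        a = paths.lengths.reshape(-1, mu.shape[0]) @ mu   # (n_pix, n_E)
        trans = np.exp(-a) @ wd / i0                       # I / I0
        if noise_photons is not None:
            counts = rng.poisson(trans * noise_photons).astype(float)
            bad = counts <= 0
            n_clamped += int(bad.sum())
            counts[bad] = 1.0  # smallest positive count
            trans = counts / noise_photons
        images[i] = (-np.log(trans)).reshape(geometry.n_v, geometry.n_u)
    if n_clamped:
        log.warning("project_poly: clamped %d zero-count pixels to one count",
                    n_clamped)
    meta = {"kvp_mean_energy_keV": spectrum.mean_energy(),
            "noise_photons": noise_photons, "seed": seed}
    return ProjectionSet(images, angles, geometry, "poly", meta)


def simulate_pair(spec: SimulationSpec, geometry: Geometry, spectrum: Spectrum,
                  detector: DetectorModel | None = None,
                  augmentation: AugmentationSpec | None = None,
                  mouse_params: MouseParams | None = None,
                  cylinder_shape=(64, 64, 64), cylinder_voxel=(0.25, 0.25, 0.25),
                  mono_energy: float = physics.MONO_ENERGY_KEV,
                  noise_photons: float | None = None, db=None):
    """Render one (poly, mono) projection pair from a simulation spec.

    Both members are computed from the identical augmented phantom, angle and
    ray paths; the mono member is always noise-free.
    """
    base = augmentation or AugmentationSpec()
    if spec.kind == "mouse":
        phantom = make_mouse_phantom(spec.phantom_seed, mouse_params)
    elif spec.kind == "cylinder":
        phantom = make_random_cylinder_phantom(spec.phantom_seed,
                                               cylinder_shape, cylinder_voxel)
    else:
        raise ValueError(f"unknown spec kind {spec.kind!r}")
    aug, angle = augment(phantom, replace(base, seed=spec.augment_seed))
    if angle != spec.angle:
        raise RuntimeError("augmentation angle does not match the spec angle")

    detector = detector or DetectorModel()
    paths = siddon_raypaths(aug, geometry, angle)
    mu_mono = _mu_table(aug, [mono_energy], db)[:, 0]
    p_mono = (paths.lengths @ mu_mono).astype(np.float32)[None]

    d = detector_response(spectrum.grid, detector, db)
    wd = spectrum.weights * d
    i0 = float(np.sum(wd))
    mu = _mu_table(aug, spectrum.grid, db)
    a = paths.lengths.reshape(-1, mu.shape[0]) @ mu
    trans = np.exp(-a) @ wd / i0
    if noise_photons is not None:
        rng = np.random.default_rng(spec.augment_seed)
        counts = rng.poisson(trans * noise_photons).astype(float)
        counts[counts <= 0] = 1.0
        trans = counts / noise_photons
    p_poly = (-np.log(trans)).reshape(1, geometry.n_v, geometry.n_u)

    meta = {"spec_index": spec.index, "kind": spec.kind,
            "phantom_seed": spec.phantom_seed, "augment_seed": spec.augment_seed}
    poly = ProjectionSet(p_poly, [angle], geometry, "poly", dict(meta))
    mono = ProjectionSet(p_mono, [angle], geometry, "mono",
                         dict(meta, energy_keV=mono_energy))
    return poly, mono
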