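"""Voxelized digital phantoms and the randomized training-corpus augmentation.

Two phantom families are provided:

* mathematical cylinders of configurable diameter, length, orientation and
  tissue, used both for dataset augmentation and for uniformity/cupping
  quality-assurance scans;
* a procedural mouse-like phantom: an elongated ellipsoidal body with skin,
  subcutaneous fat and muscle shells, an axial skeleton (spine + skull),
  brain, lungs, heart, liver and kidneys drawn from a 15-entry reference
  tissue library.  An optional head-lift mimics the raised head of an
  animal in an anesthesia cone, and an optional water-filled tube can be
  attached below the body for uniformity analysis.

The long axis of every phantom runs along +x, which lies in the rotation
plane of the pancake acquisition geometry (rotation axis +z).

Training-corpus augmentation randomizes, per projection pair: the
anisotropic voxel size in [0.17, 0.29] mm, the phantom position within
±10 mm per axis, the projection angle in [0, 359] degrees, each material's
elemental mass fractions within ±5 % (independently per element, then
renormalized), and each mass density within ±5 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .physics import MATERIALS, Material, tissue

__all__ = [
    "VoxelPhantom",
    "AugmentationSpec",
    "SimulationSpec",
    "MouseParams",
    "make_cylinder_phantom",
    "make_random_cylinder_phantom",
    "make_mouse_phantom",
    "augment",
    "make_dataset",
]


@dataclass
class VoxelPhantom:
    """A labeled voxel grid with a material table.

    ``labels`` is an integer grid of shape (nx, ny, nz); ``voxel_size`` the
    (possibly anisotropic) voxel edge lengths in mm; ``origin`` the position
    in mm of the corner of voxel (0, 0, 0) relative to the isocenter;
    ``materials`` maps every label that occurs in the grid to a
    :class:`~vmono.physics.Material` (label 0 is air/background).
    """

    labels: np.ndarray
    voxel_size: tuple
    origin: tuple
    materials: dict

    def __post_init__(self):
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int16)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D grid")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be > 0")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.materials)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from material table")

    @property
    def shape(self):
        return self.labels.shape

    @property
    def extent_mm(self):
        """Physical edge lengths of the grid in mm."""
        return tuple(n * v for n, v in zip(self.labels.shape, self.voxel_size))

    def centered(self) -> "VoxelPhantom":
        """Return a copy whose grid is centered on the isocenter."""
        origin = tuple(-0.5 * e for e in self.extent_mm)
        return replace(self, origin=origin)

    def voxel_centers(self):
        """Meshgrid arrays (mm) of voxel-center coordinates, indexing='ij'."""
        axes = [
            self.origin[k] + self.voxel_size[k] * (np.arange(self.labels.shape[k]) + 0.5)
            for k in range(3)
        ]
        return np.meshgrid(*axes, indexing="ij")

    def label_volume_mm3(self, label: int) -> float:
        n = int(np.count_nonzero(self.labels == label))
        return n * float(np.prod(self.voxel_size))


def _centered_origin(shape, voxel_size):
    return tuple(-0.5 * n * v for n, v in zip(shape, voxel_size))


def make_cylinder_phantom(diameter_mm: float, length_mm: float, material: Material,
                          orientation=(0.0, 0.0, 1.0), center=(0.0, 0.0, 0.0),
                          shape=(64, 64, 64), voxel_size=(0.25, 0.25, 0.25),
                          label: int = 1) -> VoxelPhantom:
    """A homogeneous cylinder in an air background, classified voxel-center exact.

    Raises if the cylinder does not fit inside the grid or is thinner than
    one voxel (empty phantom).
    """
    if diameter_mm <= 0 or length_mm <= 0:
        raise ValueError("diameter and length must be > 0")
    axis = np.asarray(orientation, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("orientation must be a nonzero vector")
    axis = axis / norm
    center = np.asarray(center, dtype=float)
    origin = _centered_origin(shape, voxel_size)
    half = np.array([0.5 * n * v for n, v in zip(shape, voxel_size)])
    r = 0.5 * diameter_mm
    # axis-aligned bounding box of the cylinder
    aabb = np.abs(axis) * 0.5 * length_mm + r * np.sqrt(np.maximum(0.0, 1.0 - axis**2))
    if np.any(np.abs(center) + aabb > half + 1e-9):
        raise ValueError("cylinder does not fit inside the voxel grid")

    ph = VoxelPhantom(np.zeros(shape, dtype=np.int16), tuple(voxel_size), origin,
                      {0: MATERIALS["air"], label: material})
    x, y, z = ph.voxel_centers()
    dx, dy, dz = x - center[0], y - center[1], z - center[2]
    t = dx * axis[0] + dy * axis[1] + dz * axis[2]
    rad2 = (dx - t * axis[0])**2 + (dy - t * axis[1])**2 + (dz - t * axis[2])**2
    inside = (np.abs(t) <= 0.5 * length_mm) & (rad2 <= r * r)
    if not np.any(inside):
        raise ValueError("cylinder smaller than one voxel: empty phantom")
    ph.labels[inside] = label
    return ph


def make_random_cylinder_phantom(seed: int, shape=(64, 64, 64),
                                 voxel_size=(0.25, 0.25, 0.25)) -> VoxelPhantom:
    """A randomized cylinder (diameter, position, orientation, tissue)."""
    rng = np.random.default_rng(seed)
    tissues = ["water", "soft_tissue", "muscle", "adipose", "cortical_bone",
               "liver", "brain", "spongiosa", "cartilage", "skin"]
    mat = tissue(rng.choice(tissues))
    extent = min(n * v for n, v in zip(shape, voxel_size))
    d = rng.uniform(0.25, 0.62) * extent
    length = rng.uniform(0.4, 0.8) * extent
    # random orientation biased toward the rotation axis so that most rays
    # cross the full diameter
    v = rng.normal(size=3)
    v[2] *= 3.0
    v /= np.linalg.norm(v)
    margin = 0.5 * extent - 0.5 * max(d, length) - voxel_size[0]
    center = rng.uniform(-1, 1, size=3) * max(0.0, 0.3 * margin)
    for _ in range(8):
        try:
            return make_cylinder_phantom(d, length, mat, v, center, shape, voxel_size)
        except ValueError:
            d *= 0.85
            length *= 0.85
            center *= 0.5
    raise ValueError("could not fit a random cylinder into the grid")


# ---------------------------------------------------------------------------
# Procedural mouse-like phantom
# ---------------------------------------------------------------------------

#: fixed label assignment of the mouse phantom
MOUSE_LABELS = {
    0: "air", 1: "soft_tissue", 2: "skin", 3: "adipose", 4: "muscle",
    5: "cortical_bone", 6: "brain", 7: "lung", 8: "liver", 9: "kidney",
    10: "heart", 11: "water",
}


@dataclass(frozen=True)
class MouseParams:
    """Geometry ranges of the procedural mouse-like phantom."""

    shape: tuple = (96, 64, 64)
    voxel_size: tuple = (0.23, 0.23, 0.23)
    body_length_frac: tuple = (0.80, 0.92)   # of the grid x-extent
    body_width_frac: tuple = (0.58, 0.72)    # of the grid y/z-extent
    head_lift_mm: float = 0.0
    water_tube: bool = False

    def __post_init__(self):
        if not (0 < self.body_length_frac[0] <= self.body_length_frac[1] < 1):
            raise ValueError("invalid body_length_frac range")
        if not (0 < self.body_width_frac[0] <= self.body_width_frac[1] < 1):
            raise ValueError("invalid body_width_frac range")


def _ellipsoid(ii, jj, kk, center, half_axes):
    return ((ii - center[0]) / half_axes[0])**2 + \
           ((jj - center[1]) / half_axes[1])**2 + \
           ((kk - center[2]) / half_axes[2])**2 <= 1.0


def make_mouse_phantom(seed: int, params: MouseParams | None = None) -> VoxelPhantom:
    """Generate a deterministic mouse-like phantom for the given seed.

    The phantom contains at least eight distinct tissue labels; the skeleton
    (spine plus skull) forms one connected component along the body axis.
    """
    params = params or MouseParams()
    rng = np.random.default_rng(seed)
    nx, ny, nz = params.shape
    lab = np.zeros(params.shape, dtype=np.int16)
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")

    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    a = 0.5 * nx * rng.uniform(*params.body_length_frac)
    b = 0.5 * ny * rng.uniform(*params.body_width_frac)
    c = 0.5 * nz * rng.uniform(*params.body_width_frac)
    center = (cx, cy, cz)

    def body(scale):
        return _ellipsoid(ii, jj, kk, center, (a * scale, b * scale, c * scale))

    lab[body(1.00)] = 2                      # skin
    lab[body(0.93)] = 3                      # subcutaneous fat
    lab[body(0.87)] = 4                      # muscle
    lab[body(0.78)] = 1                      # interior soft tissue

    # head with brain inside a skull shell
    hx = cx + 0.62 * a
    skull_half = (0.30 * a, 0.62 * b, 0.62 * c)
    skull = _ellipsoid(ii, jj, kk, (hx, cy, cz), skull_half)
    brain = _ellipsoid(ii, jj, kk, (hx, cy, cz),
                       tuple(0.72 * h for h in skull_half))
    # organs (thorax/abdomen), jittered per seed
    def organ(cx_frac, dy_frac, dz_frac, half_fracs, jitter=0.04):
        ctr = (cx + cx_frac * a + rng.uniform(-jitter, jitter) * a,
               cy + dy_frac * b + rng.uniform(-jitter, jitter) * b,
               cz + dz_frac * c + rng.uniform(-jitter, jitter) * c)
        half = (half_fracs[0] * a, half_fracs[1] * b, half_fracs[2] * c)
        return _ellipsoid(ii, jj, kk, ctr, half)

    lungs = organ(0.18, -0.30, 0.05, (0.16, 0.26, 0.40)) | \
        organ(0.18, 0.30, 0.05, (0.16, 0.26, 0.40))
    heart = organ(0.13, 0.0, -0.12, (0.10, 0.22, 0.26))
    liver = organ(-0.08, 0.0, -0.05, (0.16, 0.48, 0.42))
    kidneys = organ(-0.32, -0.28, 0.10, (0.08, 0.18, 0.24)) | \
        organ(-0.32, 0.28, 0.10, (0.08, 0.18, 0.24))

    lab[lungs & body(0.78)] = 7
    lab[liver & body(0.78)] = 8
    lab[kidneys & body(0.78)] = 9
    lab[heart & body(0.78)] = 10
    lab[skull & ~brain] = 5
    lab[brain] = 6

    # spine: dorsal tube along the body axis, reaching into the skull
    spine_r = max(1.5, 0.09 * min(b, c))
    sz = cz - 0.35 * c
    in_spine = ((jj - cy)**2 + (kk - sz)**2 <= spine_r**2) & \
        (ii >= cx - 0.92 * a) & (ii <= hx)
    lab[in_spine & (body(1.0) | skull)] = 5

    # optional head lift: shear the head slices upward along +z
    if params.head_lift_mm > 0:
        lift_vox = params.head_lift_mm / params.voxel_size[2]
        neck = int(round(cx + 0.35 * a))
        for i in range(neck, nx):
            s = int(round(lift_vox * (i - neck) / max(1, nx - 1 - neck)))
            if s:
                lab[i] = np.roll(lab[i], s, axis=1)

    # optional water tube attached below the body (uniformity insert)
    if params.water_tube:
        tz = cz - 0.93 * c
        tube_r = 0.16 * nz
        in_tube = ((jj - cy)**2 + (kk - tz)**2 <= tube_r**2) & \
            (np.abs(ii - cx) <= 0.45 * nx)
        lab[in_tube & (lab == 0)] = 11

    materials = {k: tissue(v) for k, v in MOUSE_LABELS.items()}
    origin = _centered_origin(params.shape, params.voxel_size)
    return VoxelPhantom(lab, params.voxel_size, origin, materials)


# ---------------------------------------------------------------------------
# Augmentation and dataset assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentationSpec:
    """Sampling ranges for the per-pair randomization.

    ``voxel_range=None`` keeps the phantom's own voxel size.  All sampled
    values lie inside the stated closed ranges.
    """

    voxel_range: tuple | None = (0.17, 0.29)   # mm, per axis
    translation_mm: float = 10.0                # +/- per axis
    angle_range: tuple = (0, 359)               # degrees, integer
    elemental_frac: float = 0.05                # +/- relative, per element
    density_frac: float = 0.05                  # +/- relative
    seed: int = 0

    @classmethod
    def identity(cls, seed: int = 0) -> "AugmentationSpec":
        return cls(voxel_range=None, translation_mm=0.0, angle_range=(0, 0),
                   elemental_frac=0.0, density_frac=0.0, seed=seed)


def _draw_geometry(rng, spec: AugmentationSpec):
    """Fixed draw order shared by :func:`augment` and :func:`make_dataset`."""
    if spec.voxel_range is None:
        voxel = None
        rng.uniform(size=3)  # keep the stream layout fixed
    else:
        voxel = tuple(rng.uniform(spec.voxel_range[0], spec.voxel_range[1], size=3))
    shift = rng.uniform(-spec.translation_mm, spec.translation_mm, size=3)
    angle = int(rng.integers(spec.angle_range[0], spec.angle_range[1] + 1))
    return voxel, shift, angle


def augment(phantom: VoxelPhantom, spec: AugmentationSpec):
    """Apply the randomized augmentation; returns (phantom, projection angle).

    Deterministic given ``spec.seed``.  Material compositions are perturbed
    independently per element by up to ±``elemental_frac`` (relative) and
    renormalized to unit sum; densities by up to ±``density_frac``.
    """
    rng = np.random.default_rng(spec.seed)
    voxel, shift, angle = _draw_geometry(rng, spec)
    if voxel is None:
        voxel = tuple(phantom.voxel_size)
    extent = tuple(n * v for n, v in zip(phantom.shape, voxel))
    origin = tuple(-0.5 * e + s for e, s in zip(extent, shift))

    materials = {}
    for label in sorted(phantom.materials):
        m = phantom.materials[label]
        if label == 0 or (spec.elemental_frac == 0 and spec.density_frac == 0):
            materials[label] = m
            continue
        syms = sorted(m.composition)
        factors = 1.0 + rng.uniform(-spec.elemental_frac, spec.elemental_frac,
                                    size=len(syms))
        comp = {s: m.composition[s] * f for s, f in zip(syms, factors)}
        total = sum(comp.values())
        comp = {s: v / total for s, v in comp.items()}
        density = m.density * (1.0 + rng.uniform(-spec.density_frac,
                                                 spec.density_frac))
        materials[label] = Material(m.name, comp, density)

    out = VoxelPhantom(phantom.labels.copy(), voxel, origin, materials)
    return out, angle


@dataclass(frozen=True)
class SimulationSpec:
    """One renderable entry of the training corpus."""

    index: int
    kind: str              # 'mouse' | 'cylinder'
    phantom_id: int        # mouse phantom number, or cylinder index
    phantom_seed: int
    augment_seed: int
    angle: int


def make_dataset(n_mouse_phantoms: int = 9, pairs_per_phantom: int = 105,
                 n_cylinder_pairs: int = 945, seed: int = 0,
                 augmentation: AugmentationSpec | None = None):
    """Enumerate the simulation specs of the projection-pair corpus.

    Returns ``n_mouse_phantoms * pairs_per_phantom + n_cylinder_pairs``
    specs, each carrying its own phantom seed, augmentation seed and
    projection angle; fully reproducible from the master ``seed``.
    """
    if min(n_mouse_phantoms, pairs_per_phantom, n_cylinder_pairs) < 0:
        raise ValueError("counts must be >= 0")
    base = augmentation or AugmentationSpec()
    ss = np.random.SeedSequence(seed)
    n_total = n_mouse_phantoms * pairs_per_phantom + n_cylinder_pairs
    children = ss.spawn(n_mouse_phantoms + n_total)
    phantom_seeds = [int(c.generate_state(1)[0] % 2**31)
                     for c in children[:n_mouse_phantoms]]
    pair_seeds = [int(c.generate_state(1)[0] % 2**31)
                  for c in children[n_mouse_phantoms:]]

    specs = []
    idx = 0
    for p in range(n_mouse_phantoms):
        for _ in range(pairs_per_phantom):
            aug_seed = pair_seeds[idx]
            rng = np.random.default_rng(aug_seed)
            _, _, angle = _draw_geometry(rng, replace(base, seed=aug_seed))
            specs.append(SimulationSpec(idx, "mouse", p, phantom_seeds[p],
                                        aug_seed, angle))
            idx += 1
    for c in range(n_cylinder_pairs):
        aug_seed = pair_seeds[idx]
        rng = np.random.default_rng(aug_seed)
        _, _, angle = _draw_geometry(rng, replace(base, seed=aug_seed))
        # the cylinder geometry itself is drawn from the pair seed
        specs.append(SimulationSpec(idx, "cylinder", c, pair_seeds[idx] ^ 0x5EED,
                                    aug_seed, angle))
        idx += 1
    return specs
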