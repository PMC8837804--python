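"""FDK cone-beam reconstruction onto a regular voxel grid.

Standard Feldkamp-Davis-Kress filtered backprojection for a circular orbit:
per-projection cosine weighting ``SID / sqrt(SID^2 + u^2 + v^2)`` (u, v on
the virtual detector through the isocenter), row-wise ramp filtering with
zero padding to the next power of two (band-limited Ram-Lak kernel, optional
Hann apodization, cutoff at Nyquist), and distance-weighted voxel-driven
backprojection with bilinear detector interpolation.  A full 360-degree scan
with uniform angular sampling is assumed (angular weight 2*pi/N); the span
must cover at least 180 degrees plus the fan angle.

The pancake acquisition rotates the phantom rather than the source, so
reconstruction is carried out in the rotating-phantom frame, where the
source describes an equivalent circular orbit and standard FDK applies.

Output voxel values are linear attenuation in 1/cm (no CT-number rescale).
The full-scale grid default matches the reference protocol (256 x 256 x 600
at 0.2 mm isotropic); a 64^3, 0.4 mm desk grid is provided for small
studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy.ndimage import map_coordinates

from .projector import Geometry, ProjectionSet

__all__ = ["Volume", "GridSpec", "fdk_reconstruct", "central_slice_profile"]

FILTERS = ("ram-lak", "hann")


@dataclass
class GridSpec:
    """Reconstruction grid: shape, isotropic-or-not voxel size, origin (mm)."""

    shape: tuple = (256, 256, 600)
    voxel_mm: tuple = (0.2, 0.2, 0.2)
    origin_mm: tuple | None = None     # None: centered on the isocenter

    def resolved_origin(self):
        if self.origin_mm is not None:
            return tuple(self.origin_mm)
        return tuple(-0.5 * n * v for n, v in zip(self.shape, self.voxel_mm))

    @classmethod
    def desk(cls, n: int = 64, voxel_mm: float = 0.4) -> "GridSpec":
        return cls((n, n, n), (voxel_mm,) * 3)


@dataclass
class Volume:
    """Reconstructed attenuation map in 1/cm on a regular grid."""

    values: np.ndarray
    voxel_mm: tuple
    origin_mm: tuple

    @property
    def shape(self):
        return self.values.shape

    def voxel_centers_mm(self, axis: int) -> np.ndarray:
        return self.origin_mm[axis] + self.voxel_mm[axis] * (
            np.arange(self.values.shape[axis]) + 0.5)


def _ramp_kernel(n_fft: int, du: float, apodization: str) -> np.ndarray:
    """Frequency response of the band-limited ramp filter (Ram-Lak)."""
    n = np.arange(n_fft)
    n = np.where(n > n_fft // 2, n - n_fft, n)   # signed sample offsets
    h = np.zeros(n_fft)
    h[0] = 1.0 / (4.0 * du * du)
    odd = (n % 2) != 0
    h[odd] = -1.0 / (np.pi * n[odd] * du) ** 2
    resp = np.real(sp_fft.fft(h))
    if apodization == "hann":
        f = sp_fft.fftfreq(n_fft)                # cycles/sample, Nyquist 0.5
        resp = resp * 0.5 * (1.0 + np.cos(2.0 * np.pi * f / 1.0))
    return resp


def fdk_reconstruct(projections: ProjectionSet, grid: GridSpec | None = None,
                    filter_name: str = "ram-lak") -> Volume:
    """Reconstruct a projection set onto ``grid`` with the FDK algorithm."""
    if filter_name not in FILTERS:
        raise ValueError(f"filter must be one of {FILTERS}")
    grid = grid or GridSpec.desk()
    g = projections.geometry
    angles = np.asarray(projections.angles, float)
    if angles.size < 2:
        raise ValueError("FDK needs at least 2 projection angles")
    span = float(angles.max() - angles.min())
    if span < 180.0 + g.fan_angle_deg:
        raise ValueError(
            f"angular span {span:.1f} deg insufficient: need >= "
            f"{180.0 + g.fan_angle_deg:.1f} deg (180 + fan)")
    imgs = projections.images
    if imgs.shape[1:] != (g.n_v, g.n_u):
        raise ValueError("image size does not match the geometry")

    sid = g.sid_mm
    mag = g.magnification
    # virtual detector through the isocenter
    du = g.pixel_mm[0] / mag
    dv = g.pixel_mm[1] / mag
    u = (np.arange(g.n_u) - (g.n_u - 1) / 2) * du
    v = (np.arange(g.n_v) - (g.n_v - 1) / 2) * dv
    cosw = sid / np.sqrt(sid**2 + u[None, :]**2 + v[:, None]**2)

    n_fft = sp_fft.next_fast_len(max(64, 2 * g.n_u))
    ramp = _ramp_kernel(n_fft, du, filter_name)

    nx, ny, nz = grid.shape
    ox, oy, oz = grid.resolved_origin()
    xs = ox + grid.voxel_mm[0] * (np.arange(nx) + 0.5)
    ys = oy + grid.voxel_mm[1] * (np.arange(ny) + 0.5)
    zs = oz + grid.voxel_mm[2] * (np.arange(nz) + 0.5)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    gx = gx.ravel().astype(np.float32)
    gy = gy.ravel().astype(np.float32)
    zcol = zs.astype(np.float32)

    accum = np.zeros((nx * ny, nz), np.float32)
    d_beta = 2.0 * np.pi / angles.size
    for img, ang in zip(imgs, angles):
        beta = np.radians(ang)
        c, s = np.cos(beta), np.sin(beta)
        # filter rows (u direction) of the cosine-weighted projection
        pw = img * cosw
        spec = sp_fft.rfft(pw, n_fft, axis=1)
        q = sp_fft.irfft(spec * ramp[: n_fft // 2 + 1][None, :], n_fft,
                         axis=1)[:, : g.n_u] * du
        # voxel-driven backprojection (phantom frame rotated by +beta in lab)
        px = c * gx - s * gy
        py = s * gx + c * gy
        denom = sid + px
        w2 = (sid / denom) ** 2
        iu = (sid * py / denom) / du + (g.n_u - 1) / 2
        scale = sid / denom / dv
        iu0 = np.floor(iu).astype(np.int32)
        fu = iu - iu0
        valid_u = (iu0 >= 0) & (iu0 < g.n_u - 1)
        iu0c = np.clip(iu0, 0, g.n_u - 2)
        for k, z in enumerate(zcol):
            iv = z * scale + (g.n_v - 1) / 2
            iv0 = np.floor(iv).astype(np.int32)
            fv = iv - iv0
            valid = valid_u & (iv0 >= 0) & (iv0 < g.n_v - 1)
            iv0c = np.clip(iv0, 0, g.n_v - 2)
            q00 = q[iv0c, iu0c]
            q01 = q[iv0c, iu0c + 1]
            q10 = q[iv0c + 1, iu0c]
            q11 = q[iv0c + 1, iu0c + 1]
            val = (q00 * (1 - fu) + q01 * fu) * (1 - fv) + \
                  (q10 * (1 - fu) + q11 * fu) * fv
            accum[:, k] += np.where(valid, w2 * val, 0.0).astype(np.float32)

    vol = accum.reshape(nx, ny, nz) * (0.5 * d_beta)
    vol *= 10.0  # 1/mm -> 1/cm
    return Volume(vol, tuple(grid.voxel_mm), grid.resolved_origin())


def central_slice_profile(volume: Volume, start_mm, end_mm, n: int = 200):
    """Interpolated 1-D profile along a line segment; returns (s_mm, values).

    ``s_mm`` is the distance along the line from ``start_mm``.  Raises if the
    segment leaves the volume.
    """
    start = np.asarray(start_mm, float)
    end = np.asarray(end_mm, float)
    ts = np.linspace(0.0, 1.0, n)
    pts = start[None, :] + ts[:, None] * (end - start)[None, :]
    idx = np.empty((3, n))
    for a in range(3):
        idx[a] = (pts[:, a] - volume.origin_mm[a]) / volume.voxel_mm[a] - 0.5
        if idx[a].min() < -0.5 or idx[a].max() > volume.values.shape[a] - 0.5:
            raise ValueError("profile line leaves the volume")
    vals = map_coordinates(volume.values, idx, order=1, mode="nearest")
    return ts * np.linalg.norm(end - start), vals
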