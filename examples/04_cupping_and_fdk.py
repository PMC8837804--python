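"""Cupping in FDK reconstructions of a water cylinder.

Scans a 10 mm water cylinder over 360 degrees with both beams, reconstructs
with FDK, and compares the radial profile and the UNAAD uniformity score.
The polyenergetic reconstruction is depressed in the center (cupping); the
monoenergetic one is flat at mu_water(35 keV).  Runtime: ~1 minute.
"""

import numpy as np

from vmono import physics as P
from vmono.metrics import unaad
from vmono.phantoms import make_cylinder_phantom
from vmono.projector import Geometry, project_mono, project_poly
from vmono.recon import GridSpec, central_slice_profile, fdk_reconstruct

geometry = Geometry.desk(64, 0.7)
phantom = make_cylinder_phantom(10.0, 16.0, P.tissue("water"), (0, 0, 1),
                                shape=(64, 64, 64),
                                voxel_size=(0.28, 0.28, 0.28))
angles = np.arange(360.0)

print("projecting 360 views (mono 35 keV and poly 60 kVp) ...")
mono = project_mono(phantom, geometry, 35.0, angles)
poly = project_poly(phantom, geometry, P.imaging_spectrum(), angles=angles)

grid = GridSpec.desk(64, 0.25)
vol_mono = fdk_reconstruct(mono, grid)
vol_poly = fdk_reconstruct(poly, grid)

xs = vol_mono.voxel_centers_mm(0)
X, Y, Z = np.meshgrid(xs, vol_mono.voxel_centers_mm(1),
                      vol_mono.voxel_centers_mm(2), indexing="ij")
roi = (np.sqrt(X**2 + Y**2) < 3.0) & (np.abs(Z) < 4.0)

mu_ref = P.material_mu(P.tissue("water"), [35.0])[0]
print(f"\nmono recon ROI mean : {vol_mono.values[roi].mean():.4f} 1/cm "
      f"(analytic mu = {mu_ref:.4f})")
print(f"poly recon ROI mean : {vol_poly.values[roi].mean():.4f} 1/cm "
      "(higher: effective mu of the softer beam)")

for name, vol in (("mono", vol_mono), ("poly", vol_poly)):
    _, prof = central_slice_profile(vol, (-4.0, 0, 0), (4.0, 0, 0), 100)
    dip = 100 * (1 - prof[45:55].mean() / prof[5:15].mean())
    print(f"{name}: UNAAD = {unaad(vol.values[roi]):6.2f}   "
          f"center dip vs rim = {dip:5.2f} %")
print("\nthe poly numbers show the cupping artifact the projection-domain "
      "network removes")
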