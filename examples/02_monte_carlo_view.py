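"""One Monte Carlo view: channel separation and scatter-to-primary ratio.

Transports photons through the 10-cm five-tissue phantom at a 14 mm slit
and tallies the central 5.5 mm ROI of the total, primary and scatter
channels.  Total = primary + scatter holds exactly per pixel.
"""

import numpy as np

from cbctscatter import (CollimatorSetting, ROISpec, ScannerGeometry,
                         build_phantom, build_spectrum, compute_spr,
                         simulate_view)

geom = ScannerGeometry(det_rows=96, det_cols=120, det_pitch_mm=2.0, n_views=40)
spectrum = build_spectrum(120.0, 10.0)
phantom = build_phantom("mc_10cm_five_tissue")
coll = CollimatorSetting(slit_mm=14.0, geometry=geom)

stack, records = simulate_view(phantom, geom, coll, spectrum,
                               n_photons=500_000, seed=1,
                               return_photons=True)
print(f"emitted 500000 photons, detected {stack.meta['n_detected']}")
conserved = np.array_equal(stack["total"],
                           stack["primary"] + stack["scatter"])
print(f"total = primary + scatter per pixel: {conserved}")

roi = ROISpec(domain="projection", shape="square", side_px=3)  # 6 mm at 2 mm px
spr = compute_spr(stack, roi)
print(f"central ROI means: total {spr.mean_total:.1f}, primary "
      f"{spr.mean_primary:.1f}, scatter {spr.mean_scatter:.1f}")
print(f"SPR = scatter/primary = {spr.spr:.3f}")
# At a 14 mm slit (4 cm FOV) the central SPR of a 10 cm water phantom is a
# few tenths at most: narrow collimation keeps scatter low.

n_scat = ((records["n_compton_phantom"] + records["n_rayleigh_phantom"]) > 0).sum()
print(f"list-mode records: {len(records)} photons, {n_scat} scattered in the "
      f"phantom, mean detected energy {records['energy'].mean():.1f} keV")
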