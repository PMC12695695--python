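"""Probe proton range on a phantom with the straight-ray engine.

Converts HU to stopping-power ratio, traces a lateral monoenergetic field
through the head, extracts the distal R80 of every 1x1 mm beamlet, and
compares the map computed on a corrupted volume (the CBCT standing in for a
synthetic CT) against the ground-truth CT map.
"""

import numpy as np

from dualsct import phantom, proton, volio

triplet = phantom.generate_triplet(phantom.PhantomSpec(seed=3))
ct = volio.clip_hu(triplet.ct)
cbct = volio.clip_hu(triplet.cbct)

beam = proton.BeamSpec(direction=(1, 0, 0), field_size_mm=80.0, r80_water_mm=120.0)
curve = proton.default_spr_curve()

map_ct = proton.compute_r80_map(proton.hu_to_spr(ct, curve), beam)
map_cbct = proton.compute_r80_map(proton.hu_to_spr(cbct, curve), beam)
hist = proton.r80_difference_histogram(map_cbct, map_ct, beam.r80_water_mm)

vals = map_ct.r80_mm[map_ct.valid]
print(f"beam: lateral, field {beam.field_size_mm:.0f} mm, "
      f"range in water {beam.r80_water_mm:.0f} mm")
print(f"CT R80 map: {map_ct.valid.sum()} valid beamlets, "
      f"depth {vals.min():.1f}-{vals.max():.1f} mm")
print(f"CBCT-vs-CT R80 error: mean {hist['mean_pct']:+.2f} %, "
      f"sd {hist['sd_pct']:.2f} %, within +-1%: {hist['frac_within_1pct']:.0%}")
print("\nErrors are per-beamlet range differences normalized to the range in "
      "water; 1 mm at 100 mm range = 1%.  The CBCT's HU corruption shifts "
      "the proton range systematically — the error a good sCT must remove.")
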