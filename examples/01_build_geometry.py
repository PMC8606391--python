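"""Build a sleeved-stomach geometry and inspect its dimensions.

A 40 Fr bougie fixes the luminal diameter at 40/3 = 13.33 mm; the sleeve
is 150 mm long with a flared antrum and tapered junction ends.
"""

from sleevesim import BougieSpec, build_sleeve, reference_lumen_volume

bougie = BougieSpec(40)
print(f"bougie: {bougie.size_fr:g} Fr -> lumen diameter {bougie.inner_diameter_mm:.2f} mm")

geometry = build_sleeve(bougie, flare=1.3, antrum_length_mm=50.0)
print(f"stations: {geometry.n_stations} (spacing {geometry.spacing_mm:g} mm)")
print(f"corpus inner radius : {geometry.inner_radius_mm[30]:.3f} mm")
print(f"antrum inner radius : {geometry.inner_radius_mm.max():.3f} mm (flare x corpus)")
print(f"wall at mid-corpus  : {geometry.outer_radius_mm[30] - geometry.inner_radius_mm[30]:.1f} mm"
      " (1.0 mucosa + 1.5 muscularis)")

v = reference_lumen_volume(geometry)
print(f"unloaded lumen volume: {v:.2f} ml")
print("This is the reference state: insufflated volumes below are reported relative to it.")
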