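"""Detector round trip: render a WAXD frame, cake-integrate, refit.

Renders a synthetic Pilatus-class frame of the chitin (110) ring for the
endocuticle parameter preset, regroups the annulus into an azimuthal
profile, and fits the texture model to what a real reduction pipeline
would see.
"""

import numpy as np

import fibretex as fx

geometry = fx.default_geometry()
truth = fx.TELSON_CARINA["IV"]

image = fx.render_image(truth, geometry, peak_counts=1e5, seed=3)
print(f"rendered frame: {image.shape[0]} x {image.shape[1]} pixels, "
      f"max {image.data.max():.0f} counts")

profile = fx.azimuthal_regroup(
    image, geometry, geometry.q_ring - 0.05, geometry.q_ring + 0.05, n_chi=360
)
print(f"regrouped annulus +-0.05 1/A about q_110 = {geometry.q_ring:.3f} 1/A "
      f"into {len(profile)} azimuth bins "
      f"({int(np.isnan(profile.intensity).sum())} empty)")

result = fx.fit_profile(profile, geometry, fx.FitConfig(seed=0))
row = result.to_row()
print("\n         alpha    beta  gamma0 dgamma0   (fitted, degrees)")
for p in ("ip", "op"):
    print(f"{p}:    {row[f'{p}_alpha']:7.2f} {row[f'{p}_beta']:7.2f} "
          f"{row[f'{p}_gamma0']:7.2f} {row[f'{p}_dgamma0']:7.2f}")
print(f"\nout-of-plane fraction: {result.op_volume_fraction:.3f} "
      f"(generator used {truth.op.scale / (truth.ip.scale + truth.op.scale):.2f})")
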