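"""Map fibre texture across a scan grid (carina curvature signature).

Simulates a small scan in which the in-plane lamella tilt beta rotates
linearly across the mesh — the signature of Bouligand planes following the
curvature of a carina ridge — fits every point independently, and prints
the recovered beta map with its sign change across the centreline.
"""

import fibretex as fx
from fibretex.mapping import export_map, fit_scan

geometry = fx.default_geometry()

# 1 x 7 transect, 100 um steps; single dominant in-plane family for speed
base = fx.TwoFamilyModel(
    ip=fx.LamellaModel(1.0, 0.0, fx.FibreDistribution(20.0, 50.0), scale=1.0),
    op=fx.LamellaModel(0.0, 90.0, fx.FibreDistribution(0.0, 45.0), scale=0.0),
)
field = fx.bouligand_field(n_rows=1, n_cols=7, base=base, beta_range=(15.1, -17.5))
scan = fx.simulate_scan(field, geometry, n_chi=360, peak_counts=2e4, seed=4)

table = fit_scan(scan, geometry, fx.FitConfig(seed=0), n_families=1)
print("x_mm   true beta   fitted beta")
for (x, _, model), (_, row) in zip(field, table.iterrows()):
    print(f"{x:5.2f} {model.ip.beta:10.2f} {row.ip_beta:12.2f}")
print("\nbeta decreases monotonically and changes sign across the transect,")
print("as the lamella planes rotate with the ridge curvature.")

export_map(table, "scan_map.tsv", "table")
export_map(table, "scan_glyphs.tsv", "glyphs")
print("wrote scan_map.tsv (parameters per point) and scan_glyphs.tsv "
      "(lamella normals/fibre directions for 3D rendering)")
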