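"""Generate a complete synthetic fragmentation study.

Writes the five input CSVs (design, patches, covers, counts, diet) plus
truth.json recording the generating coefficients.  The design emulates 28
calcareous-grassland fragments: 14 small and 14 large, along independent
gradients of connectivity and arable-land cover.
"""

import sys

from fragweb import simulate

out_dir = sys.argv[1] if len(sys.argv) > 1 else "synthetic_study"
study = simulate.generate_study(seed=42)
paths = study.write(out_dir)

design = study.design
print(f"wrote {len(paths)} files to {out_dir}/")
print(f"fragments: {len(design)} ({(design.size_class == 'small').sum()} small, "
      f"{(design.size_class == 'large').sum()} large)")
print(f"area range: {design.area_ha.min():.2f} - {design.area_ha.max():.2f} ha")
print(f"connectivity: {design.connectivity.min():.0f} - {design.connectivity.max():.0f}")
print(f"arable: {design.arable_pct.min():.0f} - {design.arable_pct.max():.0f} %")
print(f"specimens: {study.counts['count'].sum()}; "
      f"plant records: {len(study.covers)}")
print("truth theta:", {k: round(v, 3) for k, v in study.truth['theta'].items()})
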