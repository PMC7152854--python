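"""Confocal time-course quantification for the four TiO2 coatings.

Simulates fixation time points (0-24 h) for uncoated, F127-, PVP- and
AA4040-coated TiO2, segments each scene (cell interior, in-cell reflectance
spots), measures corona intensity on spots, lysosomal co-localization and
agglomerate size, and normalizes the corona series to percent change.
"""

import numpy as np
import pandas as pd

from nanocorona import (
    ConfocalSceneConfig,
    percent_change_series,
    simulate_time_course,
    two_way_anova,
)

scene = ConfocalSceneConfig(noise_sigma=10.0)  # Gaussian detector noise

frames = []
for material in ("TiO2-un", "TiO2-F127", "TiO2-PVP", "TiO2-AA4040"):
    for rep in range(3):
        frames.append(
            simulate_time_course(
                material,
                rng=np.random.default_rng(100 + rep),
                config=scene,
                replicate=rep,
            )
        )
tc = pd.concat(frames, ignore_index=True)

print("cumulative corona-intensity decrease over 0-24 h:")
for material, sub in tc.groupby("material"):
    series = sub.groupby("time_h")["corona_intensity_bgsub"].mean().sort_index()
    pc = percent_change_series(series.to_numpy())
    coloc = sub["lysosomal_colocalization_pct"].mean()
    size = sub["mean_equivalent_diameter_nm"].mean()
    print(
        f"  {material:12s} decrease {pc.cumulative_decrease:6.2f} %   "
        f"lysosomal coloc {coloc:5.1f} %   agglomerate {size:6.0f} nm"
    )

anova = two_way_anova(tc, value="corona_intensity_bgsub")
print()
print(
    "two-way ANOVA on corona intensity: "
    f"F(material) = {anova['F']['A']:.1f} (p = {anova['p']['A']:.2e}), "
    f"F(time) = {anova['F']['B']:.1f} (p = {anova['p']['B']:.2e})"
)
# Uncoated and PVP-coated TiO2 lose their labelled corona (large decreases);
# F127 and AA4040 coatings retain it (near-zero change), while all four
# traffic to lysosomes (co-localization 40-60%).
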