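"""Radial core--shell structure of a two-color corona object in 3D.

Simulates a corona object whose initial corona (channel 1) forms a tightly
bound 350 nm core and whose exchanged corona (channel 2) forms a looser
secondary layer out to 600 nm, then recovers the core diameter from the
90th-percentile radius of the core channel.  For points uniform in a ball of
radius R the estimate 2 r90 converges to 2R (0.9)^(1/3) ~ 0.965 x 2R.
"""

import numpy as np

from nanocorona import CoronaSceneConfig, ShellGeometry, radial_profile, shell_scene

config = CoronaSceneConfig(
    field_size=(5_000.0, 5_000.0, 800.0),
    n_agglomerates=1,
    shell=ShellGeometry(core_diameter=350.0, outer_diameter=600.0),
    channel_fractions=0.5,
    fluorophores_per_cluster=5_000,
    mean_blinks=1.0,
    localization_precision=(0.0, 0.0),
    background_rate=0.0,
    seed=8,
)
table, truth = shell_scene(config)
by_channel = {ch: table.select_channel(ch).coords() for ch in table.channels}
profile = radial_profile(by_channel, n_bins=12)

print(f"core diameter estimate (2 r90): {profile.core_diameter:.1f} nm")
print(f"closed-form expectation:        {350.0 * 0.9 ** (1 / 3):.1f} nm")
print()
print("radial density (um^-3) by shell:")
print(f"{'r_out nm':>9} {'ch1 (core)':>12} {'ch2 (layer)':>12}")
for edge, d1, d2 in zip(profile.bin_edges[1:], profile.density["ch1"], profile.density["ch2"]):
    print(f"{edge:9.0f} {d1:12.1f} {d2:12.1f}")
# Channel 1 density is high inside ~175 nm and zero outside; channel 2 only
# populates the 175-300 nm secondary layer -- the core--shell signature.
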