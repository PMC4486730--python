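# Default tissue properties for adult female northern elephant seals.
# Densities in g/mL, depths in cm, fat fractions as proportions by mass.
# Each entry is a (mean, sd) pair; sd feeds the uncertainty module.
blubber_density: {mean: 0.89, sd: 0.03}
skin_density: {mean: 1.17, sd: 0.13}
skin_depth_cm: {mean: 1.32, sd: 0.16}
fat_in_blubber_early: {mean: 0.853, sd: 0.026}
fat_in_blubber_late: {mean: 0.823, sd: 0.031}
fat_in_skin: {mean: 0.161, sd: 0.007}
# Traditional sculp-as-blubber constants (skin not separated).
traditional_sculp_density: {mean: 0.94, sd: 0.0}
traditional_fat_fraction: {mean: 0.903, sd: 0.003}
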