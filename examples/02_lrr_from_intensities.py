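"""Compute Log R Ratio values from raw allele intensities.

One SNP's canonical clusters are given in polar coordinates (theta, R);
a sample's (X, Y) intensities are converted to (theta, R), the expected R
is interpolated between the clusters, and LRR = log2(R_obs / R_exp).
A sample with the canonical total intensity gets LRR 0; one with 50%
extra DNA (one additional copy of a diploid locus) gets LRR ~ log2(1.5).
"""

import numpy as np

from cnvnet import compute_lrr, expected_r, polar_transform

# canonical clusters: theta at 0.05 / 0.5 / 0.95, total intensity ~ 2
knot_theta = np.array([0.05, 0.5, 0.95])
knot_r = np.array([1.9, 2.0, 2.1])

for label, (x, y) in {
    "heterozygote on cluster": (1.0, 1.0),
    "homozygote AA, normal": (1.83, 0.10),
    "heterozygote, 1.5x DNA": (1.5, 1.5),
    "heterozygote, 0.5x DNA (deletion)": (0.5, 0.5),
}.items():
    theta, r_obs = polar_transform(x, y)
    r_exp = expected_r(theta, knot_theta, knot_r)
    lrr = compute_lrr(r_obs, r_exp)
    print(f"{label:36s} X={x:5.2f} Y={y:5.2f} -> theta={theta:.3f} "
          f"R={r_obs:.3f} R_exp={r_exp:.3f} LRR={lrr:+.3f}")

print("\nLRR ~ 0 marks the two-copy baseline; positive values suggest "
      "duplications, negative values deletions.")
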