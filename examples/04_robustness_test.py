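"""Where does the forced response beat internal variability?

Per cell, count the members agreeing on the trend sign and test the
split against a fair coin (two-sided binomial).  Cells with p < 0.1
are 'robust': the forced signal dominates the noise there.
"""

import numpy as np

import climspeed as cs
from climspeed.gradients import temporal_trend

weak = cs.SyntheticConfig(nlat=32, nlon=48, trend=-0.005, noise_sigma=0.25,
                          noise_rho=0.5, n_members=10, seed=0, start_year=2045)
strong = cs.SyntheticConfig(nlat=32, nlon=48, trend=-0.05, noise_sigma=0.25,
                            noise_rho=0.5, n_members=10, seed=0, start_year=2045)

for label, cfg in (("weak forcing  (-0.005 K/yr)", weak), ("strong forcing (-0.05 K/yr)", strong)):
    cubes, _, _ = cs.generate_ensemble(cfg)
    trends = [temporal_trend(c, (2045, 2064)) for c in cubes]
    rm = cs.robustness_test(trends, alpha=0.1)
    pct = 100.0 * rm.robust.mean()
    print(f"{label}: {pct:5.1f}% of cells robust (median p = {np.median(rm.p_value):.4f})")
# under weak forcing the trend sign flips from member to member and few
# cells pass; a strong forced trend aligns all 10 members nearly everywhere
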