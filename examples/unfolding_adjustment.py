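"""Unfolding-augmented survival of a long tip-link construct.

Domain unfolding dissipates interface load, so constructs with many
extracellular domains survive longer than the bare interface kinetics
predict.  This example compares bare and unfolding-adjusted mean
lifetimes for the 27-domain construct using the two dominant step classes
(~5 nm and ~12 nm) weighted by per-force unfolding counts.
"""

import numpy as np

from tipbond import mean_lifetime
from tipbond.fitting import unfolding_adjusted_mean_lifetime
from tipbond.params import UNFOLDING_CLASSES_EC1_27, VARIANT_EC1_27
from tipbond.synth import generate_unfolding_counts

c1 = UNFOLDING_CLASSES_EC1_27["5nm"]
c2 = UNFOLDING_CLASSES_EC1_27["12nm"]
forces = np.array([15.0, 40.0, 58.0, 80.0, 103.0, 120.0])
counts = generate_unfolding_counts([c1, c2], forces, exposure=200, seed=4)

print("force_pN  n_5nm  n_12nm  tau_bare_s  tau_adjusted_s")
for f, (n1, n2) in zip(forces, counts):
    bare = mean_lifetime(VARIANT_EC1_27, f)
    adj = unfolding_adjusted_mean_lifetime(VARIANT_EC1_27, f, c1, c2, n1, n2)
    print(f"{f:8.0f}  {n1:5d}  {n2:6d}  {bare:10.3f}  {adj:14.3f}")

print("\nThe adjusted lifetime always dominates the bare one: every "
      "unfolding event buys the interface extra survival time.")
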