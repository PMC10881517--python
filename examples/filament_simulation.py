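"""Coarse-grained Langevin simulation: from catch bonds to an ideal bond.

Runs small ensembles of the bead-spring filament model in the dimeric and
cross-linked tetrameric arrangements and prints mean attachment lifetimes
(time until the last breakable bond ruptures) across pulling forces, plus
the reduced-to-physical unit map.  Ensembles here are deliberately small;
see the test suite for the statistically powered version of the check.
"""

import numpy as np

from tipbond import LangevinParams, lifetime_vs_force, to_physical
from tipbond.langevin import ReducedUnits, optimal_bond_force

units = ReducedUnits()
print("reduced-unit map:")
print(f"  1 length unit  = {to_physical(1.0, 'length', units):.0f} nm")
print(f"  1 force unit   = {to_physical(1.0, 'force', units):.2f} pN")
print(f"  1 time unit    = {to_physical(1.0, 'time', units):.3g} s")
print(f"  bond rate minimum at f* = {optimal_bond_force(LangevinParams()):.1f} "
      f"kBT/sigma per bond\n")

forces = np.array([10.0, 40.0, 180.0])
for tag in ("dimer", "tetramer_crosslinked"):
    res = lifetime_vs_force(tag, forces, n_runs=6, seed=5, t_max=2000.0)
    print(f"{tag}:")
    for f, tau, sem in zip(res.forces, res.mean_lifetimes, res.sem):
        print(f"  F = {f:5.0f} kBT/sigma ({to_physical(f, 'force', units):6.1f} pN): "
              f"lifetime {tau:7.1f} tau ({to_physical(tau, 'time', units):.2f} s) "
              f"+- {sem:.1f}")
print("\nThe dimer's lifetime peaks at intermediate force (catch bond); "
      "cross-linking retains more lifetime at high force, nudging the "
      "response towards an ideal bond (see docs/methods.md for how strong "
      "this effect is at desk-scale ensembles).")
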