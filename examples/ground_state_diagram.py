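"""Exact ground-state phase diagram of the lattice mixture at J = 3.

Evaluates the per-site grand potential h* of every catalog phase from its
unit cell, reports the winning pattern at a few representative chemical
potentials, and prints the analytic coexistence lines and triple points.
"""

from fractions import Fraction

from saltmix import (
    ChemicalPotentials,
    InteractionParams,
    coexistence_line,
    minimal_phase,
    phase_h,
    triple_points,
)

params = InteractionParams(3)

print("winning phase at representative chemical potentials (J = 3):")
for mu in [(-20, -20), (-20, 0), (-20, 10), (0, 0),
           (Fraction(-19, 5), Fraction(-19, 5))]:
    mu_ = ChemicalPotentials(*mu)
    names = "/".join(sorted(minimal_phase(params, mu_)))
    h = min(phase_h(n, params, mu_) for n in minimal_phase(params, mu_))
    print(f"  mu* = ({float(mu[0]):6.1f}, {float(mu[1]):6.1f}):  {names:6s}"
          f"  h* = {float(h):8.4f} J1/site")
# Reading: v = vacuum; c2/b2 = cluster/bubble crystals of species 2;
# ls = alternating bilayers; cc/zz = degenerate alternating-cluster chains
# and zig-zag chains (they share h* identically).

print("\nselected coexistence lines (exact, symbolic in J):")
for pair in [("cc", "ls"), ("cc", "v"), ("c12", "c2")]:
    print(f"  {coexistence_line(*pair)}")

print("\ntriple points at J = 3 with mu1* <= mu2*:")
for tp in triple_points(params, include_mirrors=False):
    m1, m2 = tp.at(3)
    print(f"  {'-'.join(sorted(tp.phases)):12s} at ({float(m1):7.2f}, "
          f"{float(m2):6.2f})   [mu1* = {tp.mu1}, mu2* = {tp.mu2}]")
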