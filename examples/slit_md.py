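"""Molecular-dynamics self-assembly of a raft in a thin slit.

A desk-scale version of the continuous-model experiment: equal numbers of
the two species between two repulsive walls (Lz = 4), annealed and held at
low temperature.  The particles condense into a single thin raft.
"""

from saltmix.md import largest_cluster_fraction, run_slit

traj = run_slit(N1=50, N2=50, q=1.0, T=0.1, box=(30.0, 30.0, 4.0),
                n_steps=10**5, seed=1)
final = traj.final

print(f"final potential energy: {traj.epot[-1]:.1f} eps")
print(f"largest cluster fraction: {largest_cluster_fraction(final):.2f}")
z = final.positions[:, 2]
print(f"raft thickness in z: {z.max() - z.min():.2f} particle diameters")
# Most particles end up in one aggregate whose thickness is between one and
# two particle diameters - a quasi-two-dimensional raft in the slit centre.
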