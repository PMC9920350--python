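"""Fixed-N cluster energetics: why 4-particle rhombi beat 7-particle hexagons
for strong third-neighbour repulsion.

Places the two competing cluster motifs on an empty lattice, evaluates their
exact energies, and locates the crossover coupling where 28 particles are
indifferent between seven rhombi and four hexagons.
"""

from fractions import Fraction

from saltmix import InteractionParams, total_energy
from saltmix.catalog import fixed_n_cluster_energies
from saltmix.fixtures import HEXAGON, RHOMBUS, place_motif

for J in (Fraction(3), Fraction(2), Fraction(1)):
    params = InteractionParams(J)
    e_rh = total_energy(place_motif(12, RHOMBUS), params)
    e_hex = total_energy(place_motif(12, HEXAGON), params)
    print(f"J = {J}: rhombus (4 particles) E = {e_rh} J1, "
          f"hexagon (7 particles) E = {e_hex} J1")
# The rhombus always contributes -5 J1; the hexagon -12 + 3J J1 (its three
# cross-cluster third-neighbour pairs cost 3J).

t = fixed_n_cluster_energies(3, 28)
print(f"\n28 particles at J = 3: seven rhombi E = {t['rhombi']} J1, "
      f"four hexagons E = {t['hexagons']} J1")
print(f"energy difference (rhombi - hexagons) = {t['difference']} J1")
print(f"the tilings exchange stability at J = {t['crossover_J']}")
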