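"""Prepare a spherical-boundary system around a ligand pair.

Builds a toy protein/water droplet, centers the sphere on the two ligands,
classifies atoms, strips clashing waters, neutralizes ionizable residues in
the restrained region and solvates the rest.
"""

from dualfep import (SimulationSphere, classify_atoms, neutralize_outside,
                     remove_overlapping_waters, solvate_sphere, sphere_center)
from dualfep.sphere_prep import Structure
from dualfep.synthetic_data import gen_toy_ligand_pair, gen_toy_system

lig_a, lig_b = gen_toy_ligand_pair(5, 2, 2, seed=2)
center = sphere_center("cog_two_ligands", ligands=(lig_a, lig_b))
sphere = SimulationSphere(center, radius=12.0)
print(f"sphere center (ligand-pair centroid): "
      f"({center[0]:.2f}, {center[1]:.2f}, {center[2]:.2f}) Å, radius 12 Å")

system = gen_toy_system(10, 0, sphere=sphere, seed=2)
classified = classify_atoms(system, sphere, shell_width=3.0)
print(f"protein atoms by region: {classified.region_counts()}")

neutral, log = neutralize_outside(system, sphere, shell_width=3.0)
print(f"neutralized {len(log)} ionizable residue(s) in the restrained region:")
for rec in log:
    print(f"  {rec.old_name}{rec.resid} -> {rec.new_name}")

solvated = solvate_sphere(sphere, neutral, grid_spacing=3.1)
waters = Structure([r for r in solvated.residues if r.name == "HOH"])
kept = remove_overlapping_waters(waters, lig_a, lig_b, cutoff=2.4)
print(f"grid waters placed: {len(waters.residues)}, "
      f"kept after ligand-clash filter: {len(kept.residues)}")
# Waters clashing with either end-state ligand are removed whole, since the
# dual topology keeps both molecules present throughout the simulation.
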