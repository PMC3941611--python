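"""From structures to ΔΔG: featurise mutations and evaluate the regressor.

Part 1 featurises the interfacial mutations of the toy complex (52-element
vectors). Part 2 demonstrates the ridge/leave-one-out machinery on a seeded
dataset with a known linear feature→ΔΔG response plus noise, which is how
the regression stage is validated without any external downloads.
"""

import numpy as np

from betacv import (MutationFilterError, evaluate, featurize_mutation)
from betacv.synthetic import (FixtureSpec, linear_response_dataset,
                              toy_complex)

s = toy_complex(FixtureSpec(seed=1, water="bound"))
print("52-element contact vectors (toy complex):")
for rid, atoms in sorted(s.residues().items()):
    name = atoms[0].residue_name
    if name in ("ALA", "GLY"):
        continue
    try:
        basic = featurize_mutation(s, rid, mode="basic", n_sphere_points=240)
        asa = featurize_mutation(s, rid, mode="asa", n_sphere_points=240)
    except MutationFilterError:
        continue  # side chain does not touch the partner: not in the dataset
    print(f"  {rid[0]}/{name}{rid[1]}: |pair block| = "
          f"{np.abs(basic.pair_block).sum():6.3f} (plain 1/d²) vs "
          f"{np.abs(asa.pair_block).sum():6.4f} (burial-weighted), "
          f"{int((asa.vector != 0).sum())}/52 non-zero entries")

# The burial-weighted block is tiny here: a 6-residue mini-complex is almost
# fully solvent-exposed, so B_loc weights - the water-exclusion factor -
# suppress nearly everything. In a real protein interface the mutated
# contacts are buried and survive the weighting.

print("\nleave-one-out ridge on a planted linear response "
      "(n=400, sigma=0.5 kcal/mol):")
X, y, _ = linear_response_dataset(FixtureSpec(seed=3, n_mutations=400,
                                              noise_sd=0.5))
report = evaluate(X, y, ridge_lambda=1.0)
print(f"  R = {report.r:.3f} (Pearson, predicted vs true)")
print(f"  delta = {report.delta:.3f} kcal/mol (sqrt of mean squared error)")
print(f"  hot spots (ΔΔG >= 2): precision {report.precision:.3f}, "
      f"recall {report.recall:.3f}, F1 {report.f1:.3f}")

# With the planted signal-to-noise ratio the regression recovers the
# relation almost perfectly; shuffling y drops R to about zero.
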