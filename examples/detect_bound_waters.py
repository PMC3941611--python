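"""Classify interface waters as bound or free.

A crystallographic water is part of the interface ("bound") when it makes
at least three potential hydrogen bonds to protein N/O atoms within 3.2 Å,
or two such bonds plus at least two more contacts under 4 Å. The two toy
variants place a water satisfying or violating these rules by construction.
"""

import numpy as np

from betacv import detect_bound_waters
from betacv.synthetic import FixtureSpec, toy_complex

for variant in ("bound", "free"):
    s = toy_complex(FixtureSpec(seed=1, water=variant))
    water = s.waters[0]
    bound_ids = detect_bound_waters(s)
    polar = [a for a in s.protein_atoms if a.element in ("N", "O")]
    d = np.linalg.norm(s.coords(polar) - water.coords, axis=1)
    print(f"{variant:>5} water: {int((d < 3.2).sum())} potential H-bond "
          f"partner(s) within 3.2 Å -> "
          f"{'BOUND' if water.atom_id in bound_ids else 'not bound'}")

# Only bound waters enter the contact graph (typed as water oxygen); free
# waters are ignored entirely.
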