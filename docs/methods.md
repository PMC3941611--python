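# Methods

## Scope and model

The package predicts the binding free energy change ΔΔG (kcal/mol) of
interfacial alanine mutations in protein–protein complexes and classifies
binding hot spots (ΔΔG ≥ 2 kcal/mol). A mutation is represented purely
geometrically: by the atomic contacts it removes and creates in a
*beta-contact graph* of the complex, weighted by local solvent occlusion.
The representation is mapped to ΔΔG by ridge regression; there are no
sequence, conservation or energy-function features.

### Beta contacts

Heavy atoms are nodes; an edge is a beta contact when (i) the centre
distance is strictly below the radii sum plus T_d, (ii) the pair is
Delaunay-adjacent (equivalently, shares a Voronoi facet), and (iii) no
other atom sees the pair under an angle ≥ ∠β (empty forbidden region).
The pipeline is literally Delaunay → distance filter → beta filter, and
the three stages are provably nested. Condition (iii) scans *all* atoms,
not only Delaunay neighbours; a KD-tree ball query around the edge
midpoint bounds the scan, with radius R(1+cos β), R = d/(2 sin β), the
outermost reach of the forbidden lens (for ∠β > 90° the 90° bound is used,
which is conservative).

Strict inequalities are used at both the distance and angle boundaries:
a contact exactly at the cutoff, or a witness atom exactly at ∠β, rejects.
Ties at these boundaries have measure zero for real coordinates; the
convention only matters for constructed inputs and is pinned by tests.

### Parameters that matter

| parameter | default | units | meaning |
|---|---|---|---|
| T_d | 3.3 | Å | distance slack: water diameter 2.8 + 0.5 |
| ∠β (features) | 75 | deg | forbidden-region angle for M/N contacts |
| ∠β (neighbourhood) | 90 | deg | angle for the surrounding-atom set S |
| probe | 1.4 | Å | solvent probe for ASA |
| sphere points | 960 | — | ASA sampling resolution |
| λ | 1.0 | — | ridge penalty on z-scored columns |
| hot-spot threshold | 2.0 | kcal/mol | both true and predicted labels |

The 75° working angle is motivated by a covalent-packing worked example:
three 1.8 Å spheres with a 1.5 Å covalent bond and two touching van der
Waals contacts subtend 78° at the bonded pair, so a 75° threshold just
excludes that geometry.

### Atomic types and radii

Heavy atoms of the 20 standard residues plus the water oxygen are grouped
into 8 classes: sp3 carbon, sp2 carbon (aromatic/carbonyl/carboxylate/
guanidinium), polar nitrogen (backbone/amide/aromatic), charged nitrogen
(Lys NZ, Arg NE/NH*), polar oxygen (carbonyl/hydroxyl), carboxylate oxygen
(Asp/Glu/OXT), water oxygen (an oxygen with more than one hydrogen), and
sulfur. The grouping and the Chothia-style radii (N 1.65, O 1.40, S 1.85,
sp3 C 1.87, sp2 C 1.76 Å) are plain dictionaries in `betacv.tables` and
can be swapped wholesale; every downstream stage is parametric in them.

### ASA and burial terms

ASA is computed with a Shrake–Rupley-style numerical method on a
deterministic golden-spiral point set. Per-atom relative exposure is
E_i = ASA_i/50 (50 Å² ≈ half the free-water sphere area 4·3.14·2.8² =
98.47 Å²) and burial B_i = max(0, 1−E_i). Residue-level terms divide the
backbone (N, CA, C, O, OXT) and side-chain ASA by reference maxima
computed from ideal *extended* ALA-X-ALA tripeptides built by the
package's internal-coordinate peptide builder; the values are frozen in
`betacv.tables` (`scripts/regenerate_max_asa.py` reproduces them, and a
test asserts frozen ≈ recomputed). The exact tripeptide conformation is a
design choice — an extended backbone (φ = −120°, ψ = 130°) with all-trans
side chains — since any consistent reference makes E/B well-defined
relative quantities. The local terms multiply atom and residue factors:
E_loc = E_i·E^bb or E_i·E^sc by the atom's backbone/side-chain class, and
likewise B_loc.

The unbound state is the rigid split of the complex by binding side (no
minimisation), so unbound ASA ≥ bound ASA atom-for-atom — an invariant the
tests and the acceptance script verify. Waters are excluded from all ASA
computations.

### Feature assembly

M = beta edges of the wild type absent from the alanine mutant;
N = the converse. Pairs within three covalent-bond steps (per-residue bond
templates plus C–N peptide bonds under 2.0 Å) are excluded; common
contacts are ignored. The 36 pair-block values are signed sums of
B_loc·B_loc/d² (M positive, N negative); the unweighted variant drops the
burial factors. Contact distances and B_loc for M come from the wild-type
structure, for N from the mutant structure — each contact is weighted in
the state where it exists (the choice is not dictated by the model; it is
the package's resolution of an underdetermined point).

Bound waters (≥3 potential hydrogen-bond contacts to protein N/O under
3.2 Å, or 2 plus ≥2 other contacts under 4 Å; water–water contacts never
counted) participate in both graphs, typed as water oxygen. Since waters
are excluded from ASA runs, a bound water has no B_loc; it is weighted as
fully buried (B_loc = 1), which keeps bound-water contacts contributing
exactly as in the unweighted vector. Setting instead B = max(0, 1−98.47/50)
= 0 would silently delete bound waters from the weighted variant, which
would contradict their purpose.

The neighbourhood set S contains the atoms with a ∠β = 90° beta contact to
any mutated atom, the mutated atoms, and each member's covalent-bond
nearby atoms (≤3 steps); waters never enter S. S is built on wild-type
geometry. The 16 neighbourhood features are per-type sums of E_loc in the
bound and unbound states.

Dataset filter: a mutation enters the dataset only if its mutated atoms
(everything beyond N, CA, C, O, CB) have at least one distance-cutoff
contact with the partner *protein* — mutations of Ala (no effect by
construction) and Gly (no side chain to truncate) are rejected outright.

### Regression and evaluation

Columns are z-scored with statistics from the training rows only
(re-estimated in every cross-validation fold); constant columns get
coefficient zero. The solve is the deterministic closed form (SVD, via
scikit-learn's Ridge), exact at λ = 0 for well-posed problems. λ = 1 on
z-scored columns is the default since the penalty's original
parameterisation is not fixed by the model; results are λ-sensitive and
the CLI exposes `--ridge-lambda`. Leave-one-out is the default evaluation;
leave-one-group-out (e.g. per complex) is available via a grouping vector.

Reported: Pearson R, SE = Σ(ΔΔG_e−ΔΔG_p)²/(N−1), δ = √SE; predictions
below −3 or above 11 kcal/mol are flagged as outliers and R is reported
both with and without them (they are never dropped from SE/δ). Hot-spot
classification uses the inclusive 2 kcal/mol threshold on predictions;
precision, recall, F1 and accuracy follow the standard confusion-count
definitions, with undefined precision (no positive predictions) reported
as 0 plus an explicit flag so small fixtures evaluate without errors.

## Synthetic data: what it does and does not show

The generators are pure functions of a seeded `FixtureSpec`.

* **Point clouds** (rejection-sampled, minimum separation 3 Å in an
  18–20 Å box) match the length scales of heavy-atom packing and are used
  to prove the geometric stages against brute-force oracles (empty
  circumsphere enumeration; O(n³) forbidden-region scan).
* **Toy complexes** pose two idealised extended hexapeptides (internal-
  coordinate builder: ideal bond lengths/angles, planar rings, all-trans
  side chains) with a 3.9 Å closest heavy-atom approach and a −1.7 Å
  stagger so side chains interdigitate — typical of real interface
  geometry. An optional water is grid-placed to satisfy rule (i) of the
  bound-water criterion by construction, or placed 8 Å outside the complex
  to violate both rules. The default geometry exercises all three
  beta-contact conditions (asserted by a coverage check).
* **Linear-response datasets** draw 52 standard-normal feature columns,
  coefficients from a standard normal, and y = Xβ* + N(0, σ²) with
  σ = 0.5 kcal/mol at n = 400 by default — a deliberately well-posed
  regression that validates the ridge/LOOCV machinery (recovery,
  permutation null, consistency), not the biology.

What passing these tests shows: the geometry, ASA accounting, feature
algebra and regression plumbing are correct. What it does not show:
predictive performance on real complexes, which depends on experimental
structures and measured ΔΔG values not bundled here. Toy peptides are
almost fully solvent-exposed, so the burial-weighted pair block is nearly
zero on them — the weighting's discriminative value only manifests on
buried interfaces.

## Numerical choices and degenerate inputs

* Delaunay on degenerate (coplanar/cospherical) input: retry once with a
  deterministic seeded jitter ≤ 1e−6 Å; fewer than four points (or jitter
  failure) fall back to the complete graph. Real atomic coordinates
  essentially never need either path.
* ASA resolution: 960 points keeps the total within 1% of a doubled
  resolution on the fixtures; tests use 240 points where speed matters
  (resolution is an explicit argument everywhere). The sampled sphere is
  orientation-dependent at finite resolution, so ASA-derived features are
  rigid-motion invariant only up to sampling noise; the contact-graph
  block is exactly invariant.
* Alternate locations: the first conformer (altloc '' or 'A') is kept;
  hydrogens are never stored; waters are single oxygen atoms. Residues
  with missing heavy atoms are processed with the atoms present.
* Unknown residue/atom names fail in strict mode or are dropped with a
  warning in lenient mode.
* Zero-variance feature columns are carried with coefficient 0 rather than
  dropped, so vector shapes are stable.

## Known limitations

* No mmCIF input, no hydrogen placement, no structure repair, no
  non-alanine mutations, no repacking of the truncated side chain.
* The 8-type grouping is a documented default; the reference grouping it
  stands in for is not redistributable here, and results depend on the
  table chosen (it is swappable).
* Ridge results depend on λ; no inner-loop selection is performed by
  default.
* The unbound state is a rigid split; conformational relaxation on
  unbinding is ignored by design.
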