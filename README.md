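# betacv

Beta-contact graphs and ASA-weighted atomic contact vectors for predicting
binding free energy changes (ΔΔG) of interfacial alanine mutations and
classifying binding hot spots in protein–protein complexes.

## Who this is for

Structural bioinformaticians studying protein–protein interfaces: given a
quaternary structure (PDB) and a table of alanine mutations with measured
ΔΔG (kcal/mol), the package represents each mutation by the atomic contacts
it destroys and creates, weights those contacts by how solvent-occluded the
atoms are (the water-exclusion hypothesis), and learns a ridge-regression
map from that representation to ΔΔG. Mutations with ΔΔG ≥ 2 kcal/mol are
binding hot spots.

## The model

A **beta contact** between heavy atoms *i, j* requires three conditions:

1. *d(i,j) < r_i + r_j + T_d* with van der Waals radii *r* and slack
   *T_d = 3.3 Å* (water diameter 2.8 Å + 0.5 Å);
2. *i* and *j* share a Voronoi facet (Delaunay adjacency);
3. no third atom *k* subtends an angle ∠ikj ≥ ∠β at the pair — the
   *forbidden region* of the edge is empty. ∠β = 90° makes that region the
   sphere on *ij* as diameter; the working value ∠β = 75° is stricter
   (for three touching carbon-like spheres with a 1.5 Å covalent bond the
   subtended angle is ≈ 78°, so 75° just excludes covalent-packing
   geometry).

For a mutation, the side chain beyond CB is deleted (no repacking) and the
beta graphs of wild type *b(p)* and mutant *b(p_mut)* are compared: *M* is
the set of disappeared contacts, *N* the newly formed ones, both excluding
pairs within three covalent-bond steps. With atoms grouped into 8 atomic
types, each unordered type pair (36 in all) gets the value

v(T_i,T_j) = Σ_{(x,y)∈M} B_x^loc B_y^loc / d(x,y)² − Σ_{(x',y')∈N} B_x'^loc B_y'^loc / d(x',y')²

where the local burial B^loc is the product of the atom's burial
*B_i = max(0, 1 − ASA_i/50)* and its residue's backbone- or side-chain
burial relative to extended ALA-X-ALA maxima (setting all B^loc = 1 gives
the unweighted variant). Sixteen further elements sum the local exposure
E^loc of the atoms surrounding the mutation site (the ∠β = 90°
neighbourhood) per type, in the bound and in the rigidly-split unbound
state — 52 features in all. Crystallographic waters with ≥ 3 potential
hydrogen bonds to protein N/O atoms (< 3.2 Å), or 2 plus ≥ 2 more contacts
under 4 Å, count as bound interface waters and take part in the contact
graphs.

Ridge regression (z-scored columns, penalty λ = 1 by default) is evaluated
by leave-one-out cross-validation: Pearson *R*, δ = √(Σ(ΔΔG_e − ΔΔG_p)²/(N−1)),
and precision/recall/F1/accuracy for the hot-spot classification
(predicted ΔΔG ≥ 2).

## Worked example

```sh
python examples/featurize_and_evaluate.py
```

prints (abridged):

```
52-element contact vectors (toy complex):
  A/GLN5: |pair block| =  0.069 (plain 1/d²) vs 0.0000 (burial-weighted), 10/52 non-zero entries
  A/TYR6: |pair block| =  0.066 (plain 1/d²) vs 0.0002 (burial-weighted), 11/52 non-zero entries
  ...
leave-one-out ridge on a planted linear response (n=400, sigma=0.5 kcal/mol):
  R = 0.998 (Pearson, predicted vs true)
  delta = 0.496 kcal/mol (sqrt of mean squared error)
  hot spots (ΔΔG >= 2): precision 0.979, recall 0.979, F1 0.979
```

The pair-block magnitudes are the inverse-squared-distance mass of the
contacts each mutation rewires (the burial-weighted block is almost zero on
a 6-residue toy because everything is solvent-exposed); the regression part
shows that with the planted signal-to-noise ratio the leave-one-out
predictions track the true ΔΔG almost perfectly (R) with residual scatter δ
close to the injected noise (0.5 kcal/mol). The other example scripts show
the contact-graph stages, bound-water detection and the ASA burial terms.

A CLI wraps the same pipeline:

```sh
betacv make-fixture --kind complex --seed 1 --water bound --out toy.pdb
betacv contacts toy.pdb --sides A:B --beta 75 --out contacts.tsv
betacv predict toy.pdb --sides A:B --mutations muts.tsv --out report.json
```

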