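"""Seeded synthetic inputs for every pipeline stage.

Three generator families, all pure functions of a :class:`FixtureSpec`:

* ``random_cloud`` — rejection-sampled 3D point clouds with a minimum
  pairwise separation, for exercising the Delaunay/beta-skeleton geometry
  against brute-force oracles;
* ``toy_complex`` — a two-chain mini-complex of idealised residues posed
  with a realistic interface gap, optionally with a crystallographic water
  placed so that it satisfies (or violates) the bound-water rules by
  construction; serialisable to valid PDB text;
* ``linear_response_dataset`` — feature matrices with a known linear
  feature→ΔΔG response plus Gaussian noise, for the regression stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import N_FEATURES
from .structure import (Atom, Structure, assign_radii_and_types,
                        detect_bound_waters, infer_covalent_topology)
from .peptide import build_peptide

DEFAULT_SEQ_A = ("LYS", "SER", "ARG", "LEU", "GLN", "TYR")
DEFAULT_SEQ_B = ("GLU", "THR", "ASN", "VAL", "ARG", "SER")


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_atoms: int = 20
    min_separation: float = 3.0     # Å
    box_size: float = 20.0          # Å
    interface_gap: float = 3.9      # Å, closest heavy-atom approach
    water: str | None = None        # None | "bound" | "free"
    noise_sd: float = 0.5           # kcal/mol, ΔΔG noise
    n_mutations: int = 400
    true_coef: tuple[float, ...] | None = None  # length 52 when given


def random_cloud(spec: FixtureSpec) -> np.ndarray:
    """Points in a cube with pairwise distance ≥ min_separation (seeded)."""
    rng = np.random.default_rng(spec.seed)
    pts: list[np.ndarray] = []
    attempts = 0
    max_attempts = 2000 * spec.n_atoms
    while len(pts) < spec.n_atoms:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"cannot pack {spec.n_atoms} points at separation "
                f"{spec.min_separation} Å into a {spec.box_size} Å box")
        p = rng.uniform(0.0, spec.box_size, 3)
        if all(np.linalg.norm(p - q) >= spec.min_separation for q in pts):
            pts.append(p)
    return np.array(pts)


def _chain_atoms(sequence, chain_id: str, start_id: int,
                 transform=None) -> list[Atom]:
    atoms = []
    for num, rname, name, xyz in build_peptide(list(sequence)):
        if transform is not None:
            xyz = transform(xyz)
        atoms.append(Atom(
            atom_id=start_id + len(atoms), name=name, element=name[0],
            residue_name=rname, residue_id=(chain_id, num, ""),
            coords=np.asarray(xyz, dtype=float),
            is_water=False,
            is_backbone=name in ("N", "CA", "C", "O", "OXT"),
        ))
    return atoms


def _pose_second_chain(a_coords: np.ndarray, b_coords: np.ndarray,
                       gap: float, x_offset: float = -1.7) -> np.ndarray:
    """Flip the second chain (180° about x), stagger it along x so the side
    chains interdigitate, and slide it along +y until the closest heavy-atom
    approach equals ``gap``."""
    flipped = b_coords * np.array([1.0, -1.0, -1.0]) + np.array([x_offset, 0.0, 0.0])

    def min_dist(ty: float) -> float:
        moved = flipped + np.array([0.0, ty, 0.0])
        d = np.linalg.norm(a_coords[:, None] - moved[None, :], axis=-1)
        return float(d.min())

    lo, hi = 0.0, 60.0
    while min_dist(hi) < gap:
        hi *= 2
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < gap:
            lo = mid
        else:
            hi = mid
    return flipped + np.array([0.0, hi, 0.0])


def _place_bound_water(protein: list[Atom], rng: np.random.Generator) -> np.ndarray:
    """Grid-search a site with ≥3 protein N/O atoms within 3.0 Å and no
    clash below 2.3 Å, so the water satisfies rule (i) by construction."""
    coords = np.array([a.coords for a in protein])
    is_no = np.array([a.element in ("N", "O") for a in protein])
    no_coords = coords[is_no]
    lo, hi = coords.min(axis=0) - 1.0, coords.max(axis=0) + 1.0
    best, best_count = None, 0
    for _ in range(200000):
        p = rng.uniform(lo, hi)
        d_no = np.linalg.norm(no_coords - p, axis=1)
        n_hb = int((d_no < 3.0).sum())
        if n_hb < 3:
            continue
        d_all = np.linalg.norm(coords - p, axis=1)
        if d_all.min() < 2.3:
            continue
        if n_hb > best_count:
            best, best_count = p, n_hb
        if best_count >= 3:
            return best
    if best is None:
        raise RuntimeError("no bound-water site found in the toy complex")
    return best


def toy_complex(spec: FixtureSpec = FixtureSpec(),
                seq_a=DEFAULT_SEQ_A, seq_b=DEFAULT_SEQ_B) -> Structure:
    """Two idealised chains (A, B) posed at the requested interface gap,
    with radii, types and covalent topology assigned.

    ``spec.water`` adds one HOH: "bound" places it where it passes the
    bound-water hydrogen-bond rules (asserted), "free" far outside the
    complex where it fails them.
    """
    rng = np.random.default_rng(spec.seed)
    a_atoms = _chain_atoms(seq_a, "A", 0)
    b_atoms = _chain_atoms(seq_b, "B", len(a_atoms))
    a_xyz = np.array([a.coords for a in a_atoms])
    b_xyz = _pose_second_chain(a_xyz, np.array([a.coords for a in b_atoms]),
                               spec.interface_gap)
    for atom, xyz in zip(b_atoms, b_xyz):
        atom.coords = xyz
    atoms = a_atoms + b_atoms
    if spec.water is not None:
        if spec.water == "bound":
            w = _place_bound_water(atoms, rng)
        elif spec.water == "free":
            w = np.array([a.coords for a in atoms]).max(axis=0) + 8.0
        else:
            raise ValueError("water must be None, 'bound' or 'free'")
        atoms = atoms + [Atom(
            atom_id=len(atoms), name="O", element="O", residue_name="HOH",
            residue_id=("W", 1, ""), coords=w, is_water=True)]
    s = Structure(atoms=atoms, sides=(frozenset("A"), frozenset("B")))
    s = assign_radii_and_types(s)
    infer_covalent_topology(s)
    if spec.water == "bound":
        assert detect_bound_waters(s), "constructed water failed the bound rule"
    elif spec.water == "free":
        assert not detect_bound_waters(s), "free water unexpectedly bound"
    return s


def condition_coverage(s: Structure, t_d: float = 3.3) -> dict[str, bool]:
    """Whether a structure's contact graph exercises all three beta-contact
    conditions: a Delaunay edge failing the distance test, a distance-passing
    edge that fails ∠β = 75° but passes 90°, and a full 75° beta contact."""
    from .contacts import ContactParams, build_contact_graph
    g75 = build_contact_graph(s, ContactParams(t_d, 75.0))
    g90 = build_contact_graph(s, ContactParams(t_d, 90.0))
    b75, b90 = g75.beta_edges, g90.beta_edges
    dist = {e for e, c in g75.contacts.items() if c.passes_distance}
    return {
        "delaunay_edge_failing_distance": any(
            not c.passes_distance for c in g75.contacts.values()),
        "distance_edge_failing_75_passing_90": bool((b90 - b75) & dist),
        "full_beta_contact": bool(b75),
    }


def linear_response_dataset(spec: FixtureSpec,
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X, y, beta*): standard-normal features, y = X·beta* + N(0, sd²)."""
    rng = np.random.default_rng(spec.seed)
    if spec.true_coef is not None:
        beta = np.asarray(spec.true_coef, dtype=float)
        if len(beta) != N_FEATURES:
            raise ValueError(f"true_coef must have length {N_FEATURES}")
    else:
        beta = rng.standard_normal(N_FEATURES)
    X = rng.standard_normal((spec.n_mutations, N_FEATURES))
    y = X @ beta + spec.noise_sd * rng.standard_normal(spec.n_mutations)
    return X, y, beta
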