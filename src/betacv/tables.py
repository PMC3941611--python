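"""Chemistry lookup tables: van der Waals radii, the 8-class atomic typing
scheme, per-residue covalent-bond templates and reference maximum ASA values.

All tables are plain dictionaries keyed by (residue name, atom name) or by
residue name, so alternative parameterisations can be swapped in by passing a
different table to the functions that consume them.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Heavy-atom inventory of the 20 standard residues (PDB v3 atom names).
# Backbone atoms N, CA, C, O (and terminal OXT) are implicit and shared.

BACKBONE_ATOMS = ("N", "CA", "C", "O")
TERMINAL_ATOMS = ("OXT",)

SIDE_CHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

STANDARD_RESIDUES = tuple(sorted(SIDE_CHAIN_ATOMS))

WATER_RESIDUES = ("HOH", "WAT", "DOD")

# Atoms kept when a residue is truncated to alanine: the alanine scaffold.
ALANINE_SCAFFOLD = frozenset(BACKBONE_ATOMS) | frozenset(TERMINAL_ATOMS) | {"CB"}

# ---------------------------------------------------------------------------
# Covalent-bond templates (side chain + CA-CB); backbone N-CA, CA-C, C-O and
# C-OXT are added programmatically, as is the inter-residue peptide bond.

SIDE_CHAIN_BONDS: dict[str, tuple[tuple[str, str], ...]] = {
    "ALA": (),
    "ARG": (("CB", "CG"), ("CG", "CD"), ("CD", "NE"), ("NE", "CZ"),
            ("CZ", "NH1"), ("CZ", "NH2")),
    "ASN": (("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")),
    "ASP": (("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")),
    "CYS": (("CB", "SG"),),
    "GLN": (("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")),
    "GLU": (("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")),
    "GLY": (),
    "HIS": (("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"), ("ND1", "CE1"),
            ("CD2", "NE2"), ("CE1", "NE2")),
    "ILE": (("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")),
    "LEU": (("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")),
    "LYS": (("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")),
    "MET": (("CB", "CG"), ("CG", "SD"), ("SD", "CE")),
    "PHE": (("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")),
    "PRO": (("CB", "CG"), ("CG", "CD"), ("CD", "N")),
    "SER": (("CB", "OG"),),
    "THR": (("CB", "OG1"), ("CB", "CG2")),
    "TRP": (("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "NE1"),
            ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"), ("CE2", "CZ2"),
            ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")),
    "TYR": (("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"), ("CZ", "OH")),
    "VAL": (("CB", "CG1"), ("CB", "CG2")),
}


def residue_bond_template(residue_name: str) -> tuple[tuple[str, str], ...]:
    """Intra-residue covalent bonds of a standard residue (heavy atoms)."""
    side = SIDE_CHAIN_BONDS[residue_name]
    backbone = [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT")]
    if residue_name != "GLY":
        backbone.append(("CA", "CB"))
    return tuple(backbone) + side


# ---------------------------------------------------------------------------
# Van der Waals radii (Å), Chothia-style values as used by common ASA codes:
# N 1.65, O 1.40, S 1.85, tetrahedral C 1.87, trigonal C 1.76.

_R_N, _R_O, _R_S, _R_C_SP3, _R_C_SP2 = 1.65, 1.40, 1.85, 1.87, 1.76

# Trigonal (sp2) carbons per residue; everything else carbon is tetrahedral.
_SP2_CARBONS: dict[str, frozenset[str]] = {
    "ARG": frozenset({"CZ"}),
    "ASN": frozenset({"CG"}),
    "ASP": frozenset({"CG"}),
    "GLN": frozenset({"CD"}),
    "GLU": frozenset({"CD"}),
    "HIS": frozenset({"CG", "CD2", "CE1"}),
    "PHE": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
}


def _build_radii_table() -> dict[tuple[str, str], float]:
    table: dict[tuple[str, str], float] = {}
    for res, side_atoms in SIDE_CHAIN_ATOMS.items():
        names = BACKBONE_ATOMS + TERMINAL_ATOMS + side_atoms
        sp2 = _SP2_CARBONS.get(res, frozenset())
        for name in names:
            el = name[0]
            if el == "N":
                r = _R_N
            elif el == "O":
                r = _R_O
            elif el == "S":
                r = _R_S
            elif name == "C":  # backbone carbonyl carbon
                r = _R_C_SP2
            else:
                r = _R_C_SP2 if name in sp2 else _R_C_SP3
            table[(res, name)] = r
    for w in WATER_RESIDUES:
        table[(w, "O")] = _R_O
    return table


DEFAULT_RADII: dict[tuple[str, str], float] = _build_radii_table()

# ---------------------------------------------------------------------------
# 8-class atomic typing. Heavy atoms of the standard residues plus the water
# oxygen are grouped by element, hybridisation and polarity/charge; the water
# oxygen (an oxygen carrying more than one hydrogen) has its own class.

C_SP3, C_SP2, N_POLAR, N_CHARGED, O_POLAR, O_CHARGED, O_WATER, SULFUR = range(1, 9)
N_ATOM_TYPES = 8

ATOM_TYPE_LABELS = {
    C_SP3: "C.sp3",
    C_SP2: "C.sp2",
    N_POLAR: "N.polar",
    N_CHARGED: "N.charged",
    O_POLAR: "O.polar",
    O_CHARGED: "O.charged",
    O_WATER: "O.water",
    SULFUR: "S",
}

_CHARGED_NITROGENS = {("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"), ("LYS", "NZ")}
_CHARGED_OXYGENS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}


def _build_type_table() -> dict[tuple[str, str], int]:
    table: dict[tuple[str, str], int] = {}
    for res, side_atoms in SIDE_CHAIN_ATOMS.items():
        names = BACKBONE_ATOMS + TERMINAL_ATOMS + side_atoms
        sp2 = _SP2_CARBONS.get(res, frozenset())
        for name in names:
            el = name[0]
            if el == "N":
                t = N_CHARGED if (res, name) in _CHARGED_NITROGENS else N_POLAR
            elif el == "O":
                if name == "OXT" or (res, name) in _CHARGED_OXYGENS:
                    t = O_CHARGED
                else:
                    t = O_POLAR
            elif el == "S":
                t = SULFUR
            elif name == "C" or name in sp2:
                t = C_SP2
            else:
                t = C_SP3
            table[(res, name)] = t
    for w in WATER_RESIDUES:
        table[(w, "O")] = O_WATER
    return table


DEFAULT_ATOM_TYPES: dict[tuple[str, str], int] = _build_type_table()

# Fixed ordering of the 36 unordered type pairs used by the contact vectors.
TYPE_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (i, j) for i in range(1, N_ATOM_TYPES + 1) for j in range(i, N_ATOM_TYPES + 1)
)
TYPE_PAIR_INDEX: dict[tuple[int, int], int] = {p: k for k, p in enumerate(TYPE_PAIRS)}

# ---------------------------------------------------------------------------
# Reference maximum ASA (Å², probe 1.4 Å) of each residue type, split into
# backbone (N, CA, C, O) and side-chain contributions. Computed once from
# ideal extended ALA-X-ALA tripeptides built by betacv.peptide and the
# package's own Shrake-Rupley routine at 960 sphere points, then frozen here
# (scripts/regenerate_max_asa.py reproduces them). GLY's "side chain" is
# empty; a nominal 1.0 keeps the relative-ASA division defined.

MAX_ASA_BB: dict[str, float] = {
    "ALA": 43.64, "ARG": 41.09, "ASN": 41.35, "ASP": 41.35, "CYS": 41.3,
    "GLN": 41.09, "GLU": 41.09, "GLY": 83.8, "HIS": 38.19, "ILE": 30.72,
    "LEU": 38.15, "LYS": 41.09, "MET": 41.09, "PHE": 37.05, "PRO": 32.72,
    "SER": 43.11, "THR": 32.1, "TRP": 32.96, "TYR": 37.05, "VAL": 30.72,
}

MAX_ASA_SC: dict[str, float] = {
    "ALA": 67.75, "ARG": 203.63, "ASN": 111.85, "ASP": 104.55, "CYS": 96.66,
    "GLN": 143.27, "GLU": 134.99, "GLY": 1.0, "HIS": 149.2, "ILE": 142.91,
    "LEU": 142.49, "LYS": 168.15, "MET": 156.94, "PHE": 167.78, "PRO": 107.08,
    "SER": 77.15, "THR": 106.48, "TRP": 202.48, "TYR": 180.14, "VAL": 118.13,
}
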