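"""Ideal-geometry peptide builder.

Constructs heavy-atom coordinates for short peptides of the 20 standard
residues from fixed internal coordinates (bond lengths, bond angles,
torsions), using the natural-extension reference frame. The geometry is
idealised — an extended backbone with all side-chain torsions trans and
planar rings — which is all the contact-graph and ASA machinery needs;
no claim of physical realism is made.
"""

from __future__ import annotations

import numpy as np

# Backbone internal coordinates (Engh-Huber-like ideal values).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8

# Extended (beta-strand-like) backbone torsions; a pure 180/180 conformation
# would put the whole backbone in one plane, which needlessly stresses the
# Delaunay step, so a gentle twist is used instead.
PHI_EXT, PSI_EXT, OMEGA = -120.0, 130.0, 180.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Position atom d bonded to a, with angle d-a-b and dihedral d-a-b-c."""
    ang = np.deg2rad(angle)
    dih = np.deg2rad(dihedral)
    u = a - b
    u /= np.linalg.norm(u)
    n = np.cross(b - c, u)
    n /= np.linalg.norm(n)
    m = np.cross(n, u)
    return a + bond * (-np.cos(ang) * u
                       + np.sin(ang) * np.cos(dih) * m
                       + np.sin(ang) * np.sin(dih) * n)


def _complete_polygon(a: np.ndarray, b: np.ndarray, n: int,
                      ref: np.ndarray) -> list[np.ndarray]:
    """Vertices of the regular planar n-gon with consecutive vertices a, b,
    lying in the plane of (a, b, ref), extending away from ref."""
    side = np.linalg.norm(b - a)
    normal = np.cross(b - a, ref - a)
    normal /= np.linalg.norm(normal)
    mid = 0.5 * (a + b)
    w = np.cross(normal, (b - a) / side)  # in-plane, perpendicular to a->b
    apothem = side / (2.0 * np.tan(np.pi / n))
    c1, c2 = mid + apothem * w, mid - apothem * w
    center = c1 if np.linalg.norm(c1 - ref) > np.linalg.norm(c2 - ref) else c2
    theta = 2.0 * np.pi / n

    def rot(p: np.ndarray, ang: float) -> np.ndarray:
        v = p - center
        k = normal
        return center + (v * np.cos(ang) + np.cross(k, v) * np.sin(ang)
                         + k * np.dot(k, v) * (1 - np.cos(ang)))

    # pick rotation sign that maps a onto b in one step
    sign = 1.0 if np.linalg.norm(rot(a, theta) - b) < 1e-6 else -1.0
    return [rot(a, sign * theta * k) for k in range(n)]


# Side-chain Z-matrix rows: (atom, a, b, c, bond Å, angle deg, dihedral deg).
# Rings are finished analytically from their first two vertices.
_SIDE_ZMAT: dict[str, tuple[tuple[str, str, str, str, float, float, float], ...]] = {
    "ALA": (),
    "GLY": (),
    "SER": (("OG", "CB", "CA", "N", 1.417, 110.8, 180.0),),
    "CYS": (("SG", "CB", "CA", "N", 1.808, 113.8, 180.0),),
    "THR": (("OG1", "CB", "CA", "N", 1.433, 109.6, 180.0),
            ("CG2", "CB", "CA", "N", 1.521, 110.5, 60.0)),
    "VAL": (("CG1", "CB", "CA", "N", 1.521, 110.5, 180.0),
            ("CG2", "CB", "CA", "N", 1.521, 110.5, 60.0)),
    "ILE": (("CG1", "CB", "CA", "N", 1.530, 110.5, 180.0),
            ("CG2", "CB", "CA", "N", 1.521, 110.5, 60.0),
            ("CD1", "CG1", "CB", "CA", 1.513, 113.8, 180.0)),
    "LEU": (("CG", "CB", "CA", "N", 1.530, 116.3, 180.0),
            ("CD1", "CG", "CB", "CA", 1.521, 110.7, 180.0),
            ("CD2", "CG", "CB", "CA", 1.521, 110.7, 60.0)),
    "ASP": (("CG", "CB", "CA", "N", 1.516, 112.6, 180.0),
            ("OD1", "CG", "CB", "CA", 1.249, 118.4, 0.0),
            ("OD2", "CG", "CB", "CA", 1.249, 118.4, 180.0)),
    "ASN": (("CG", "CB", "CA", "N", 1.516, 112.6, 180.0),
            ("OD1", "CG", "CB", "CA", 1.231, 120.8, 0.0),
            ("ND2", "CG", "CB", "CA", 1.328, 116.4, 180.0)),
    "GLU": (("CG", "CB", "CA", "N", 1.530, 114.1, 180.0),
            ("CD", "CG", "CB", "CA", 1.516, 112.6, 180.0),
            ("OE1", "CD", "CG", "CB", 1.249, 118.4, 0.0),
            ("OE2", "CD", "CG", "CB", 1.249, 118.4, 180.0)),
    "GLN": (("CG", "CB", "CA", "N", 1.530, 114.1, 180.0),
            ("CD", "CG", "CB", "CA", 1.516, 112.6, 180.0),
            ("OE1", "CD", "CG", "CB", 1.231, 120.8, 0.0),
            ("NE2", "CD", "CG", "CB", 1.328, 116.4, 180.0)),
    "MET": (("CG", "CB", "CA", "N", 1.530, 114.1, 180.0),
            ("SD", "CG", "CB", "CA", 1.803, 112.7, 180.0),
            ("CE", "SD", "CG", "CB", 1.791, 100.9, 180.0)),
    "LYS": (("CG", "CB", "CA", "N", 1.530, 114.1, 180.0),
            ("CD", "CG", "CB", "CA", 1.530, 111.3, 180.0),
            ("CE", "CD", "CG", "CB", 1.530, 111.3, 180.0),
            ("NZ", "CE", "CD", "CG", 1.489, 111.9, 180.0)),
    "ARG": (("CG", "CB", "CA", "N", 1.530, 114.1, 180.0),
            ("CD", "CG", "CB", "CA", 1.530, 111.3, 180.0),
            ("NE", "CD", "CG", "CB", 1.461, 112.0, 180.0),
            ("CZ", "NE", "CD", "CG", 1.329, 124.2, 180.0),
            ("NH1", "CZ", "NE", "CD", 1.326, 120.0, 0.0),
            ("NH2", "CZ", "NE", "CD", 1.326, 120.0, 180.0)),
    "PRO": (("CG", "CB", "CA", "N", 1.492, 104.5, 30.0),
            ("CD", "CG", "CB", "CA", 1.503, 106.1, -35.0)),
}

# (first ring atom zmat row, ring size, vertex names in ring order)
_RING_SPECS: dict[str, tuple] = {
    "PHE": (("CD1", "CG", "CB", "CA", 1.390, 120.7, 90.0), 6,
            ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")),
    "TYR": (("CD1", "CG", "CB", "CA", 1.390, 120.7, 90.0), 6,
            ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")),
    "HIS": (("ND1", "CG", "CB", "CA", 1.378, 122.7, 90.0), 5,
            ("CG", "ND1", "CE1", "NE2", "CD2")),
    "TRP": (("CD1", "CG", "CB", "CA", 1.365, 127.0, 90.0), 5,
            ("CG", "CD1", "NE1", "CE2", "CD2")),
}
_RING_STEM = {"PHE": 1.506, "TYR": 1.506, "HIS": 1.497, "TRP": 1.498}


def _build_side_chain(res: str, pos: dict[str, np.ndarray]) -> None:
    """Extend pos (containing at least N, CA, C, CB) with side-chain atoms."""
    if res in _RING_SPECS:
        pos["CG"] = place_atom(pos["CB"], pos["CA"], pos["N"],
                               _RING_STEM[res], 113.8, 180.0)
        row, nring, names = _RING_SPECS[res]
        name1, a, b, c, bond, ang, dih = row
        pos[name1] = place_atom(pos[a], pos[b], pos[c], bond, ang, dih)
        verts = _complete_polygon(pos["CG"], pos[name1], nring, pos["CB"])
        for name, v in zip(names, verts):
            pos[name] = v
        if res == "TYR":
            center = sum(verts) / len(verts)
            cz = pos["CZ"]
            pos["OH"] = cz + 1.376 * (cz - center) / np.linalg.norm(cz - center)
        if res == "TRP":
            hexv = _complete_polygon(pos["CD2"], pos["CE2"], 6, pos["CG"])
            for name, v in zip(("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"), hexv):
                if name not in ("CD2", "CE2"):
                    pos[name] = v
        return
    for name, a, b, c, bond, ang, dih in _SIDE_ZMAT[res]:
        pos[name] = place_atom(pos[a], pos[b], pos[c], bond, ang, dih)


def build_peptide(sequence: list[str], phi: float = PHI_EXT, psi: float = PSI_EXT,
                  ) -> list[tuple[int, str, str, np.ndarray]]:
    """Build an idealised peptide; residues named by 3-letter code.

    Returns a flat list of (residue number starting at 1, residue name,
    atom name, coordinates), backbone first within each residue.
    """
    out: list[tuple[int, str, str, np.ndarray]] = []
    prev: dict[str, np.ndarray] | None = None
    for i, res in enumerate(sequence):
        res = res.upper()
        pos: dict[str, np.ndarray] = {}
        if prev is None:
            pos["N"] = np.zeros(3)
            pos["CA"] = np.array([_B_N_CA, 0.0, 0.0])
            ang = np.deg2rad(180.0 - _A_N_CA_C)
            pos["C"] = pos["CA"] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
        else:
            pos["N"] = place_atom(prev["C"], prev["CA"], prev["N"],
                                  _B_C_N, _A_CA_C_N, psi)
            pos["CA"] = place_atom(pos["N"], prev["C"], prev["CA"],
                                   _B_N_CA, _A_C_N_CA, OMEGA)
            pos["C"] = place_atom(pos["CA"], pos["N"], prev["C"],
                                  _B_CA_C, _A_N_CA_C, phi)
        # carbonyl O anti to the next amide N (dihedral psi+180 about CA-C)
        pos["O"] = place_atom(pos["C"], pos["CA"], pos["N"],
                              _B_C_O, _A_CA_C_O, psi + 180.0)
        if res != "GLY":
            pos["CB"] = place_atom(pos["CA"], pos["N"], pos["C"],
                                   1.530, 110.5, -122.6)
        _build_side_chain(res, pos)
        from .tables import BACKBONE_ATOMS, SIDE_CHAIN_ATOMS
        for name in BACKBONE_ATOMS + SIDE_CHAIN_ATOMS[res]:
            out.append((i + 1, res, name, pos[name].copy()))
        prev = pos
    return out
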