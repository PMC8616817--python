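"""Ideal amino-acid geometry: topology, internal coordinates, proton specs.

This is the geometry table shipped with the package (version
:data:`GEOMETRY_TABLE_VERSION`).  Three kinds of information are encoded per
residue type:

* ``HEAVY_BONDS`` — covalent bonds between heavy atoms (backbone included),
  used for hydrogen frames, attached-heavy-atom lookup and counting covalent
  bonds between protons.
* ``SIDECHAIN_ICOORDS`` — NeRF internal coordinates (bond length, bond angle,
  dihedral) for building sidechain heavy atoms from backbone frames; entries
  whose dihedral is ``("chi", k, offset)`` rotate with the k-th sidechain
  torsion.
* ``PROTON_SPECS`` — how each hydrogen is placed on its parent heavy atom
  (tetrahedral methine, methylene pair, staggered methyl rotor, sp2, amide
  NH2, staggered hydroxyl/thiol rotor).

Bond lengths/angles are generic ideal values; ring closure for HIS/TRP is
approximate (adequate for toy structures, and irrelevant when reading real
coordinates, where heavy atoms are taken as given).
"""
from __future__ import annotations

import math
import warnings
from typing import Iterable, Optional

import numpy as np

from .errors import ProtonPlacementWarning, UnknownResidueError
from .types import AtomRef, Conformer, STANDARD_RESIDUES

GEOMETRY_TABLE_VERSION = "1.0"

# ---------------------------------------------------------------------------
# vector helpers
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ZeroDivisionError("zero-length vector in geometry frame")
    return v / n


def nerf(a, b, c, length: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D given chain A-B-C-D (natural extension reference frame).

    ``angle_deg`` is the B-C-D bond angle, ``dihedral_deg`` the A-B-C-D
    torsion.
    """
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg)
    bc = _unit(c - b)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-8:
        raise ZeroDivisionError("collinear frame atoms")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [-math.cos(theta), math.sin(theta) * math.cos(chi), math.sin(theta) * math.sin(chi)]
    )
    return c + length * (d_local[0] * bc + d_local[1] * m + d_local[2] * n)


# ---------------------------------------------------------------------------
# heavy-atom topology (sidechain bonds; backbone N-CA, CA-C, C-O implied)
# ---------------------------------------------------------------------------

_BACKBONE_BONDS = [("N", "CA"), ("CA", "C"), ("C", "O")]

_SIDECHAIN_BONDS: dict[str, list[tuple[str, str]]] = {
    "ALA": [("CA", "CB")],
    "ARG": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"), ("NE", "CZ"),
            ("CZ", "NH1"), ("CZ", "NH2")],
    "ASN": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "CYS": [("CA", "CB"), ("CB", "SG")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")],
    "GLY": [],
    "HIS": [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"), ("ND1", "CE1"),
            ("CD2", "NE2"), ("CE1", "NE2")],
    "ILE": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")],
    "MET": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PHE": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "PRO": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "THR": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "TRP": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "NE1"),
            ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"), ("CE2", "CZ2"),
            ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")],
    "TYR": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"), ("CZ", "OH")],
    "VAL": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
}

HEAVY_BONDS: dict[str, list[tuple[str, str]]] = {
    res: _BACKBONE_BONDS + bonds for res, bonds in _SIDECHAIN_BONDS.items()
}

HEAVY_ATOMS: dict[str, list[str]] = {
    res: ["N", "CA", "C", "O"]
    + sorted({a for b in bonds for a in b} - {"N", "CA", "C", "O"},
             key=lambda s: (len(s), s))
    for res, bonds in _SIDECHAIN_BONDS.items()
}

# ---------------------------------------------------------------------------
# sidechain heavy-atom internal coordinates
# entry: (atom, (frameA, frameB, frameC), length, angle, dihedral)
# dihedral: float | ("chi", k, offset_deg)
# ---------------------------------------------------------------------------

def _chi(k: int, off: float = 0.0):
    return ("chi", k, off)


SIDECHAIN_ICOORDS: dict[str, list[tuple]] = {
    "ALA": [],
    "ARG": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, _chi(1)),
        ("CD", ("CA", "CB", "CG"), 1.52, 111.3, _chi(2)),
        ("NE", ("CB", "CG", "CD"), 1.46, 112.0, _chi(3)),
        ("CZ", ("CG", "CD", "NE"), 1.33, 124.2, _chi(4)),
        ("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
        ("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0),
    ],
    "ASN": [
        ("CG", ("N", "CA", "CB"), 1.52, 112.6, _chi(1)),
        ("OD1", ("CA", "CB", "CG"), 1.23, 120.8, _chi(2)),
        ("ND2", ("CA", "CB", "CG"), 1.33, 116.7, _chi(2, 180.0)),
    ],
    "ASP": [
        ("CG", ("N", "CA", "CB"), 1.52, 112.6, _chi(1)),
        ("OD1", ("CA", "CB", "CG"), 1.25, 118.4, _chi(2)),
        ("OD2", ("CA", "CB", "CG"), 1.25, 118.4, _chi(2, 180.0)),
    ],
    "CYS": [("SG", ("N", "CA", "CB"), 1.81, 114.4, _chi(1))],
    "GLN": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, _chi(1)),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.6, _chi(2)),
        ("OE1", ("CB", "CG", "CD"), 1.23, 120.8, _chi(3)),
        ("NE2", ("CB", "CG", "CD"), 1.33, 116.7, _chi(3, 180.0)),
    ],
    "GLU": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, _chi(1)),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.6, _chi(2)),
        ("OE1", ("CB", "CG", "CD"), 1.25, 118.4, _chi(3)),
        ("OE2", ("CB", "CG", "CD"), 1.25, 118.4, _chi(3, 180.0)),
    ],
    "GLY": [],
    "HIS": [
        ("CG", ("N", "CA", "CB"), 1.49, 113.8, _chi(1)),
        ("ND1", ("CA", "CB", "CG"), 1.38, 122.7, _chi(2)),
        ("CD2", ("CA", "CB", "CG"), 1.36, 131.1, _chi(2, 180.0)),
        ("CE1", ("CB", "CG", "ND1"), 1.32, 109.3, 180.0),
        ("NE2", ("CB", "CG", "CD2"), 1.37, 107.2, 180.0),
    ],
    "ILE": [
        ("CG1", ("N", "CA", "CB"), 1.53, 110.4, _chi(1)),
        ("CG2", ("N", "CA", "CB"), 1.53, 110.5, _chi(1, -122.3)),
        ("CD1", ("CA", "CB", "CG1"), 1.52, 113.8, _chi(2)),
    ],
    "LEU": [
        ("CG", ("N", "CA", "CB"), 1.53, 116.3, _chi(1)),
        ("CD1", ("CA", "CB", "CG"), 1.52, 110.7, _chi(2)),
        ("CD2", ("CA", "CB", "CG"), 1.52, 110.7, _chi(2, 122.3)),
    ],
    "LYS": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, _chi(1)),
        ("CD", ("CA", "CB", "CG"), 1.52, 111.3, _chi(2)),
        ("CE", ("CB", "CG", "CD"), 1.52, 111.3, _chi(3)),
        ("NZ", ("CG", "CD", "CE"), 1.49, 112.0, _chi(4)),
    ],
    "MET": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, _chi(1)),
        ("SD", ("CA", "CB", "CG"), 1.80, 112.7, _chi(2)),
        ("CE", ("CB", "CG", "SD"), 1.79, 100.9, _chi(3)),
    ],
    "PHE": [
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, _chi(1)),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, _chi(2)),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, _chi(2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 120.8, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 120.8, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
    ],
    "PRO": [
        ("CG", ("N", "CA", "CB"), 1.50, 104.5, 32.0),
        ("CD", ("CA", "CB", "CG"), 1.51, 105.5, -35.0),
    ],
    "SER": [("OG", ("N", "CA", "CB"), 1.42, 111.1, _chi(1))],
    "THR": [
        ("OG1", ("N", "CA", "CB"), 1.43, 109.6, _chi(1)),
        ("CG2", ("N", "CA", "CB"), 1.52, 111.5, _chi(1, -120.0)),
    ],
    "TRP": [
        ("CG", ("N", "CA", "CB"), 1.50, 113.6, _chi(1)),
        ("CD1", ("CA", "CB", "CG"), 1.37, 126.9, _chi(2)),
        ("CD2", ("CA", "CB", "CG"), 1.43, 126.6, _chi(2, 180.0)),
        ("NE1", ("CB", "CG", "CD1"), 1.38, 110.2, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.41, 107.2, 180.0),
        ("CE3", ("CB", "CG", "CD2"), 1.40, 133.9, 0.0),
        ("CZ2", ("CG", "CD2", "CE2"), 1.40, 122.4, 180.0),
        ("CZ3", ("CG", "CD2", "CE3"), 1.39, 118.6, 180.0),
        ("CH2", ("CD2", "CE2", "CZ2"), 1.37, 117.5, 0.0),
    ],
    "TYR": [
        ("CG", ("N", "CA", "CB"), 1.51, 113.9, _chi(1)),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, _chi(2)),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, _chi(2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 121.2, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 121.2, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.38, 119.6, 0.0),
        ("OH", ("CD1", "CE1", "CZ"), 1.38, 119.9, 180.0),
    ],
    "VAL": [
        ("CG1", ("N", "CA", "CB"), 1.53, 110.5, _chi(1)),
        ("CG2", ("N", "CA", "CB"), 1.53, 110.5, _chi(1, 122.3)),
    ],
}

N_CHI: dict[str, int] = {
    res: max(
        [ic[4][1] for ic in icoords if isinstance(ic[4], tuple)] or [0]
    )
    for res, icoords in SIDECHAIN_ICOORDS.items()
}

# ---------------------------------------------------------------------------
# proton placement specs
# kinds:
#   methine  : 1 H on sp3 X with 3 heavy neighbours         (name, X, (n1,n2,n3))
#   methylene: 2 H on sp3 X with 2 heavy neighbours         ((h2,h3), X, (n1,n2))
#   methyl   : 3 staggered H on X bonded to A, ref R        ((h1,h2,h3), X, A, R)
#   sp2      : 1 in-plane H on X with 2 neighbours          (name, X, (n1,n2))
#   amide2   : 2 H on planar N bonded to C, cis ref O       ((hE,hZ), N, C, O)
#   rotor1   : 1 staggered H on X bonded to A, ref R        (name, X, A, R)
# ---------------------------------------------------------------------------

_X_H_LEN = {"C": 1.09, "N": 1.01, "O": 0.96, "S": 1.34}

_SIDECHAIN_PROTONS: dict[str, list[tuple]] = {
    "ALA": [("methyl", ("HB1", "HB2", "HB3"), "CB", "CA", "N")],
    "ARG": [
        ("methylene", ("HB2", "HB3"), "CB", ("CA", "CG")),
        ("methylene", ("HG2", "HG3"), "CG", ("CB", "CD")),
        ("methylene", ("HD2", "HD3"), "CD", ("CG", "NE")),
        ("sp2", "HE", "NE", ("CD", "CZ")),
        ("amide2", ("HH11", "HH12"), "NH1", "CZ", "NE"),
        ("amide2", ("HH21", "HH22"), "NH2", "CZ", "NE"),
    ],
    "ASN": [
        ("methylene", ("HB2", "HB3"), "CB", ("CA", "CG")),
        ("amide2", ("HD21", "HD22"), "ND2", "CG", "OD1"),
    ],
    "ASP": [("methylene", ("HB2", "HB3"), "CB", ("CA", "CG"))],
    "CYS": [
        ("methylene", ("HB2", "HB3"), "CB", ("CA", "SG")),
        ("rotor1", "HG", "SG", "CB", "CA"),
    ],
    "GLN": [
        ("methylene", ("HB2", "HB3"), "CB", ("CA", "CG")),
        ("methylene", ("HG2", "HG3"), "CG", ("CB", "CD")),
        ("amide2", ("HE21", "HE22"), "NE2", "CD", "OE1"),
    ],
    "GLU": [
        ("methylene", ("HB2", "HB3"), "CB", ("CA", "CG")),
        ("methylene", ("HG2", "HG3"), "CG", ("CB", "CD")),
    ],
    "GLY": [],
    "HIS": [
        ("methylene", ("HB2", "HB3"), "CB", ("CA", "CG")),
        ("sp2", "HD1", "ND1", ("CG", "CE1")),
        ("sp2", "HD2", "CD2", ("CG", "NE2")),
        ("sp2", "HE1", "CE1", ("ND1", "NE2")),
        ("sp2", "HE2", "NE2", ("CD2", "CE1")),
    ],
    "ILE": [
        ("methine", "HB", "CB", ("CA", "CG1", "CG2")),
        ("methylene", ("HG12", "HG13"), "CG1", ("CB", "CD1")),
        ("methyl", ("HG21", "HG22", "HG23"), "CG2", "CB", "CA"),
        ("methyl", ("HD11", "HD12", "HD13"), "CD1", "CG1", "CB"),
    ],
    "LEU": [
        ("methylene", ("HB2", "HB3"), "CB", ("CA", "CG")),
        ("methine", "HG", "CG", ("CB", "CD1", "CD2")),
        ("methyl", ("HD11", "HD12", "HD13"), "CD1", "CG", "CB"),
        ("methyl", ("HD21", "HD22", "HD23"), "CD2", "CG", "CB"),
    ],
    "LYS": [
        ("methylene", ("HB2", "HB3"), "CB", ("CA", "CG")),
        ("methylene", ("HG2", "HG3"), "CG", ("CB", "CD")),
        ("methylene", ("HD2", "HD3"), "CD", ("CG", "CE")),
        ("methylene", ("HE2", "HE3"), "CE", ("CD", "NZ")),
        ("methyl", ("HZ1", "HZ2", "HZ3"), "NZ", "CE", "CD"),
    ],
    "MET": [
        ("methylene", ("HB2", "HB3"), "CB", ("CA", "CG")),
        ("methylene", ("HG2", "HG3"), "CG", ("CB", "SD")),
        ("methyl", ("HE1", "HE2", "HE3"), "CE", "SD", "CG"),
    ],
    "PHE": [
        ("methylene", ("HB2", "HB3"), "CB", ("CA", "CG")),
        ("sp2", "HD1", "CD1", ("CG", "CE1")),
        ("sp2", "HD2", "CD2", ("CG", "CE2")),
        ("sp2", "HE1", "CE1", ("CD1", "CZ")),
        ("sp2", "HE2", "CE2", ("CD2", "CZ")),
        ("sp2", "HZ", "CZ", ("CE1", "CE2")),
    ],
    "PRO": [
        ("methylene", ("HB2", "HB3"), "CB", ("CA", "CG")),
        ("methylene", ("HG2", "HG3"), "CG", ("CB", "CD")),
        ("methylene", ("HD2", "HD3"), "CD", ("CG", "N")),
    ],
    "SER": [
        ("methylene", ("HB2", "HB3"), "CB", ("CA", "OG")),
        ("rotor1", "HG", "OG", "CB", "CA"),
    ],
    "THR": [
        ("methine", "HB", "CB", ("CA", "OG1", "CG2")),
        ("rotor1", "HG1", "OG1", "CB", "CA"),
        ("methyl", ("HG21", "HG22", "HG23"), "CG2", "CB", "CA"),
    ],
    "TRP": [
        ("methylene", ("HB2", "HB3"), "CB", ("CA", "CG")),
        ("sp2", "HD1", "CD1", ("CG", "NE1")),
        ("sp2", "HE1", "NE1", ("CD1", "CE2")),
        ("sp2", "HE3", "CE3", ("CD2", "CZ3")),
        ("sp2", "HZ2", "CZ2", ("CE2", "CH2")),
        ("sp2", "HZ3", "CZ3", ("CE3", "CH2")),
        ("sp2", "HH2", "CH2", ("CZ2", "CZ3")),
    ],
    "TYR": [
        ("methylene", ("HB2", "HB3"), "CB", ("CA", "CG")),
        ("sp2", "HD1", "CD1", ("CG", "CE1")),
        ("sp2", "HD2", "CD2", ("CG", "CE2")),
        ("sp2", "HE1", "CE1", ("CD1", "CZ")),
        ("sp2", "HE2", "CE2", ("CD2", "CZ")),
        ("rotor1", "HH", "OH", "CZ", "CE1"),
    ],
    "VAL": [
        ("methine", "HB", "CB", ("CA", "CG1", "CG2")),
        ("methyl", ("HG11", "HG12", "HG13"), "CG1", "CB", "CA"),
        ("methyl", ("HG21", "HG22", "HG23"), "CG2", "CB", "CA"),
    ],
}


def proton_specs(residue_name: str, *, n_terminal: bool = False) -> list[tuple]:
    """Full proton spec list for one residue (backbone + sidechain)."""
    if residue_name not in STANDARD_RESIDUES:
        raise UnknownResidueError(f"no geometry for residue {residue_name!r}")
    specs: list[tuple] = []
    if residue_name != "PRO" and not n_terminal:
        specs.append(("amide_h", "H", "N", ("C-", "CA")))  # C- = previous residue C
    if residue_name == "GLY":
        specs.append(("methylene", ("HA2", "HA3"), "CA", ("N", "C")))
    else:
        specs.append(("methine", "HA", "CA", ("N", "C", "CB")))
    specs.extend(_SIDECHAIN_PROTONS[residue_name])
    return specs


def proton_names(residue_name: str) -> list[str]:
    """All hydrogen names this table can place for one residue type."""
    names: list[str] = []
    for spec in proton_specs(residue_name):
        h = spec[1]
        if isinstance(h, tuple):
            names.extend(h)
        else:
            names.append(h)
    return names


def attached_heavy_atom(residue_name: str, proton_name: str) -> Optional[str]:
    """Heavy atom covalently bonded to the named proton (None if unknown)."""
    for spec in proton_specs(residue_name):
        h, parent = spec[1], spec[2]
        if isinstance(h, tuple):
            if proton_name in h:
                return parent
        elif proton_name == h:
            return parent
    return None


# ---------------------------------------------------------------------------
# hydrogen construction
# ---------------------------------------------------------------------------

_TET_HALF = 54.75  # half of ideal H-X-H tetrahedral angle


def _sp3_one(x, n1, n2, n3, length):
    u = _unit(n1 - x) + _unit(n2 - x) + _unit(n3 - x)
    return x + length * -_unit(u)


def _sp3_two(x, n1, n2, length):
    b = -(_unit(n1 - x) + _unit(n2 - x))
    b = _unit(b)
    perp = np.cross(_unit(n1 - x), _unit(n2 - x))
    perp = _unit(perp)
    c, s = math.cos(math.radians(_TET_HALF)), math.sin(math.radians(_TET_HALF))
    return x + length * (c * b + s * perp), x + length * (c * b - s * perp)


def _sp2_one(x, n1, n2, length):
    u = -(_unit(n1 - x) + _unit(n2 - x))
    return x + length * _unit(u)


def _methyl(x, a, r, length):
    out = []
    for dih in (180.0, -60.0, 60.0):
        out.append(nerf(r, a, x, length, 109.5, dih))
    return out


def place_protons_on_residue(
    conf: Conformer,
    chain: str,
    resnum: int,
    resname: str,
    prev_c: Optional[np.ndarray],
) -> list[tuple[AtomRef, np.ndarray]]:
    """Compute missing hydrogen positions for one residue.

    Protons whose frame heavy atoms are missing or degenerate are skipped
    with a :class:`ProtonPlacementWarning`.
    """
    placed: list[tuple[AtomRef, np.ndarray]] = []

    def xyz(name: str) -> Optional[np.ndarray]:
        if name == "C-":
            return prev_c
        return conf.get(AtomRef(chain, resnum, resname, name))

    def skip(hname: str, why: str) -> None:
        warnings.warn(
            f"{chain}{resnum} {resname} {hname}: {why}; proton skipped",
            ProtonPlacementWarning,
            stacklevel=3,
        )

    for spec in proton_specs(resname, n_terminal=prev_c is None):
        kind = spec[0]
        try:
            if kind in ("methine",):
                h, parent, (n1, n2, n3) = spec[1], spec[2], spec[3]
                frame = [xyz(parent), xyz(n1), xyz(n2), xyz(n3)]
                if any(v is None for v in frame):
                    skip(h, "missing frame atom")
                    continue
                placed.append(
                    (AtomRef(chain, resnum, resname, h),
                     _sp3_one(*frame, _X_H_LEN[parent[0]]))
                )
            elif kind == "methylene":
                (h2, h3), parent, (n1, n2) = spec[1], spec[2], spec[3]
                frame = [xyz(parent), xyz(n1), xyz(n2)]
                if any(v is None for v in frame):
                    skip(h2, "missing frame atom")
                    continue
                p2, p3 = _sp3_two(*frame, _X_H_LEN[parent[0]])
                placed.append((AtomRef(chain, resnum, resname, h2), p2))
                placed.append((AtomRef(chain, resnum, resname, h3), p3))
            elif kind == "methyl":
                hs, parent, axis, ref = spec[1], spec[2], spec[3], spec[4]
                frame = [xyz(parent), xyz(axis), xyz(ref)]
                if any(v is None for v in frame):
                    skip(hs[0], "missing frame atom")
                    continue
                for hname, pos in zip(
                    hs, _methyl(frame[0], frame[1], frame[2], _X_H_LEN[parent[0]])
                ):
                    placed.append((AtomRef(chain, resnum, resname, hname), pos))
            elif kind in ("sp2", "amide_h"):
                h, parent, (n1, n2) = spec[1], spec[2], spec[3]
                frame = [xyz(parent), xyz(n1), xyz(n2)]
                if any(v is None for v in frame):
                    skip(h, "missing frame atom")
                    continue
                placed.append(
                    (AtomRef(chain, resnum, resname, h),
                     _sp2_one(*frame, _X_H_LEN[parent[0]]))
                )
            elif kind == "amide2":
                (h_e, h_z), parent, c, ref = spec[1], spec[2], spec[3], spec[4]
                frame = [xyz(ref), xyz(c), xyz(parent)]
                if any(v is None for v in frame):
                    skip(h_e, "missing frame atom")
                    continue
                ln = _X_H_LEN[parent[0]]
                placed.append(
                    (AtomRef(chain, resnum, resname, h_e),
                     nerf(frame[0], frame[1], frame[2], ln, 120.0, 180.0))
                )
                placed.append(
                    (AtomRef(chain, resnum, resname, h_z),
                     nerf(frame[0], frame[1], frame[2], ln, 120.0, 0.0))
                )
            elif kind == "rotor1":
                h, parent, axis, ref = spec[1], spec[2], spec[3], spec[4]
                frame = [xyz(ref), xyz(axis), xyz(parent)]
                if any(v is None for v in frame):
                    skip(h, "missing frame atom")
                    continue
                placed.append(
                    (AtomRef(chain, resnum, resname, h),
                     nerf(frame[0], frame[1], frame[2], _X_H_LEN[parent[0]], 109.5, 180.0))
                )
            else:  # pragma: no cover - table integrity
                raise ValueError(f"unknown proton spec kind {kind!r}")
        except ZeroDivisionError:
            hname = spec[1][0] if isinstance(spec[1], tuple) else spec[1]
            skip(hname, "degenerate (collinear) frame geometry")
    return placed


# ---------------------------------------------------------------------------
# covalent proton-pair analysis (geminal / vicinal pairs for G_local)
# ---------------------------------------------------------------------------

def local_proton_pairs(
    residues: Iterable[tuple[str, int, str]],
) -> set[frozenset[AtomRef]]:
    """All proton pairs separated by 2 or 3 covalent bonds.

    ``residues`` is an ordered (chain, number, name) sequence; consecutive
    residues in the same chain are treated as peptide bonded.
    """
    import networkx as nx

    g = nx.Graph()
    prev: Optional[tuple[str, int, str]] = None
    for chain, num, name in residues:
        for a, b in HEAVY_BONDS[name]:
            g.add_edge((chain, num, name, a), (chain, num, name, b))
        for spec in proton_specs(name, n_terminal=prev is None or prev[0] != chain):
            hs = spec[1] if isinstance(spec[1], tuple) else (spec[1],)
            parent = spec[2]
            for h in hs:
                g.add_edge((chain, num, name, h), (chain, num, name, parent))
        if prev is not None and prev[0] == chain:
            g.add_edge((prev[0], prev[1], prev[2], "C"), (chain, num, name, "N"))
        prev = (chain, num, name)

    pairs: set[frozenset[AtomRef]] = set()
    protons = [n for n in g if n[3].startswith("H")]
    for h in protons:
        lengths = nx.single_source_shortest_path_length(g, h, cutoff=3)
        for other, dist in lengths.items():
            if other[3].startswith("H") and other != h and dist in (2, 3):
                pairs.add(
                    frozenset(
                        (AtomRef(*h), AtomRef(*other))
                    )
                )
    return pairs
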