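"""Build all-atom polypeptide conformers from internal coordinates.

Backbone atoms are grown by natural-extension-reference-frame steps from
phi/psi torsions (omega fixed trans); sidechains follow the ideal internal
coordinates in :mod:`rpfdp.geometry`; hydrogens are then placed with the same
machinery used for protonating external models.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .errors import UnknownResidueError
from .geometry import (
    N_CHI,
    SIDECHAIN_ICOORDS,
    nerf,
    place_protons_on_residue,
)
from .types import AtomRef, Conformer, STANDARD_RESIDUES

# backbone ideal values
_N_CA, _CA_C, _C_N, _C_O = 1.458, 1.525, 1.329, 1.231
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA, _ANG_CA_C_O = 111.0, 116.2, 121.7, 120.5
_CB_LEN, _ANG_C_CA_CB, _DIH_N_C_CA_CB = 1.53, 110.5, 122.6

AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def to_three_letter(sequence: Sequence[str]) -> list[str]:
    """Accept one-letter string or iterable of 3-letter codes."""
    out = []
    for s in sequence:
        if len(s) == 1:
            if s not in AA1TO3:
                raise UnknownResidueError(f"unknown one-letter code {s!r}")
            out.append(AA1TO3[s])
        else:
            if s not in STANDARD_RESIDUES:
                raise UnknownResidueError(f"unknown residue {s!r}")
            out.append(s)
    return out


def build_conformer(
    sequence: Sequence[str],
    phi: Sequence[float],
    psi: Sequence[float],
    chi: Optional[Sequence[Sequence[float]]] = None,
    *,
    chain_id: str = "A",
    first_residue_number: int = 1,
    residue_numbers: Optional[Sequence[int]] = None,
    add_protons: bool = True,
) -> Conformer:
    """All-atom conformer from torsions (angles in degrees).

    ``phi[0]`` is unused (no preceding carbonyl); ``chi[i]`` supplies the
    sidechain torsions of residue i (missing values default to 180 deg,
    i.e. extended).  ``residue_numbers`` overrides the default contiguous
    numbering (author numbering may have gaps).
    """
    seq = to_three_letter(sequence)
    n = len(seq)
    if not (len(phi) == len(psi) == n):
        raise ValueError("phi/psi length must match sequence length")
    if residue_numbers is None:
        residue_numbers = [first_residue_number + i for i in range(n)]
    elif len(residue_numbers) != n:
        raise ValueError("residue_numbers length must match sequence length")
    conf = Conformer()

    # seed backbone of residue 0 in a canonical frame
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_N_CA, 0.0, 0.0])
    theta = np.radians(180.0 - _ANG_N_CA_C)
    c0 = ca0 + _CA_C * np.array([np.cos(theta), np.sin(theta), 0.0])

    bb_n, bb_ca, bb_c = [n0], [ca0], [c0]
    for i in range(1, n):
        ni = nerf(bb_n[i - 1], bb_ca[i - 1], bb_c[i - 1], _C_N, _ANG_CA_C_N, psi[i - 1])
        cai = nerf(bb_ca[i - 1], bb_c[i - 1], ni, _N_CA, _ANG_C_N_CA, 180.0)
        ci = nerf(bb_c[i - 1], ni, cai, _CA_C, _ANG_N_CA_C, phi[i])
        bb_n.append(ni)
        bb_ca.append(cai)
        bb_c.append(ci)

    for i, resname in enumerate(seq):
        resnum = residue_numbers[i]
        conf.add(AtomRef(chain_id, resnum, resname, "N"), bb_n[i])
        conf.add(AtomRef(chain_id, resnum, resname, "CA"), bb_ca[i])
        conf.add(AtomRef(chain_id, resnum, resname, "C"), bb_c[i])
        # carbonyl O: trans to the next N (psi + 180)
        conf.add(
            AtomRef(chain_id, resnum, resname, "O"),
            nerf(bb_n[i], bb_ca[i], bb_c[i], _C_O, _ANG_CA_C_O, psi[i] + 180.0),
        )
        if resname != "GLY":
            conf.add(
                AtomRef(chain_id, resnum, resname, "CB"),
                nerf(bb_c[i], bb_n[i], bb_ca[i], _CB_LEN, _ANG_C_CA_CB, _DIH_N_C_CA_CB),
            )
        chis = list(chi[i]) if chi is not None and i < len(chi) else []
        for atom, frame, length, angle, dih in SIDECHAIN_ICOORDS[resname]:
            if isinstance(dih, tuple):
                _, k, off = dih
                base = chis[k - 1] if k <= len(chis) else 180.0
                dih_val = base + off
            else:
                dih_val = dih
            a, b, c = (
                conf[AtomRef(chain_id, resnum, resname, nm)] for nm in frame
            )
            conf.add(
                AtomRef(chain_id, resnum, resname, atom),
                nerf(a, b, c, length, angle, dih_val),
            )

    if add_protons:
        prev_c = None
        for i, resname in enumerate(seq):
            resnum = residue_numbers[i]
            for ref, pos in place_protons_on_residue(
                conf, chain_id, resnum, resname, prev_c
            ):
                conf.add(ref, pos)
            prev_c = bb_c[i]
    return conf


def sample_free_chain(
    sequence: Sequence[str],
    rng: np.random.Generator,
    *,
    chain_id: str = "A",
    first_residue_number: int = 1,
    residue_numbers: Optional[Sequence[int]] = None,
) -> Conformer:
    """One freely rotating chain conformer: uniform phi/psi/chi torsions.

    Bond lengths and angles are fixed at ideal values; torsions are drawn
    uniformly, with no excluded-volume term — the null model behind the
    lower bound of the F-measure.
    """
    seq = to_three_letter(sequence)
    n = len(seq)
    phi = rng.uniform(-180.0, 180.0, size=n)
    psi = rng.uniform(-180.0, 180.0, size=n)
    chis = [rng.uniform(-180.0, 180.0, size=N_CHI[r]) for r in seq]
    return build_conformer(
        seq, phi, psi, chis,
        chain_id=chain_id, first_residue_number=first_residue_number,
        residue_numbers=residue_numbers,
    )
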