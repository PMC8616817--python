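"""Self-contained synthetic NMR test worlds.

Generates, as pure functions of a seeded configuration: a folded toy
structure (antiparallel helical hairpin with mixed residue types), a
random-coil-style chemical-shift table, NOESY peak lists derived from the
structure's short-distance network (with configurable dropout, artifact
peaks and shift jitter), coordinate-noise decoy models, and forward-
calculated RDC sets.  Together these close the loop around every scoring
operation without any external data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .chain import build_conformer, sample_free_chain
from .errors import RpfError
from .proton_model import (
    DEFAULT_D_MAX,
    add_hydrogens,
    build_distance_graph,
    build_proton_sites,
    site_heavy_elements,
)
from .rdc_fit import AlignmentTensor, calc_coupling
from .types import AssignedShift, AtomRef, Conformer, NoesyPeak, PeakList, RdcRecord

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthConfig:
    """Everything the generators need; all randomness derives from ``seed``."""

    n_residues: int = 40
    seed: int = 17
    d_max: float = DEFAULT_D_MAX
    peak_dropout: float = 0.0
    artifact_peak_rate: float = 0.0
    shift_jitter: float = 0.0
    coordinate_noise_levels: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0)
    collapse_prochiral: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.peak_dropout < 1):
            raise ValueError("peak_dropout must be in [0, 1)")
        if self.artifact_peak_rate < 0:
            raise ValueError("artifact_peak_rate must be >= 0")
        if self.shift_jitter < 0:
            raise ValueError("shift_jitter must be >= 0")


# ---------------------------------------------------------------------------
# random-coil chemical-shift table (1H by pseudoatom stem; 13C/15N for
# proton-bearing heavy atoms).  Approximate random-coil values, ppm.
# ---------------------------------------------------------------------------

RANDOM_COIL_H: dict[str, dict[str, float]] = {
    "ALA": {"H": 8.24, "HA": 4.32, "HB": 1.39},
    "ARG": {"H": 8.23, "HA": 4.34, "HB2": 1.86, "HB3": 1.76, "HG2": 1.63,
            "HG3": 1.54, "HD2": 3.20, "HD3": 3.20, "HE": 7.17},
    "ASN": {"H": 8.40, "HA": 4.74, "HB2": 2.83, "HB3": 2.75, "HD21": 7.59,
            "HD22": 6.91},
    "ASP": {"H": 8.34, "HA": 4.64, "HB2": 2.72, "HB3": 2.65},
    "CYS": {"H": 8.32, "HA": 4.55, "HB2": 3.18, "HB3": 2.95},
    "GLN": {"H": 8.32, "HA": 4.34, "HB2": 2.12, "HB3": 1.99, "HG2": 2.36,
            "HG3": 2.36, "HE21": 7.52, "HE22": 6.85},
    "GLU": {"H": 8.42, "HA": 4.35, "HB2": 2.09, "HB3": 1.97, "HG2": 2.31,
            "HG3": 2.28},
    "GLY": {"H": 8.33, "HA2": 3.96, "HA3": 3.90},
    "HIS": {"H": 8.42, "HA": 4.73, "HB2": 3.26, "HB3": 3.10, "HD2": 7.14,
            "HE1": 8.12},
    "ILE": {"H": 8.00, "HA": 4.17, "HB": 1.87, "HG12": 1.45, "HG13": 1.16,
            "HG2": 0.91, "HD1": 0.86},
    "LEU": {"H": 8.16, "HA": 4.34, "HB2": 1.62, "HB3": 1.52, "HG": 1.59,
            "HD1": 0.92, "HD2": 0.87},
    "LYS": {"H": 8.29, "HA": 4.32, "HB2": 1.84, "HB3": 1.75, "HG2": 1.44,
            "HG3": 1.35, "HD2": 1.68, "HD3": 1.68, "HE2": 2.99, "HE3": 2.99},
    "MET": {"H": 8.28, "HA": 4.48, "HB2": 2.11, "HB3": 2.01, "HG2": 2.60,
            "HG3": 2.54, "HE": 2.10},
    "PHE": {"H": 8.30, "HA": 4.62, "HB2": 3.14, "HB3": 3.04, "HD1": 7.28,
            "HD2": 7.28, "HE1": 7.38, "HE2": 7.38, "HZ": 7.32},
    "PRO": {"HA": 4.42, "HB2": 2.29, "HB3": 1.94, "HG2": 2.02, "HG3": 2.02,
            "HD2": 3.63, "HD3": 3.63},
    "SER": {"H": 8.31, "HA": 4.47, "HB2": 3.89, "HB3": 3.87},
    "THR": {"H": 8.15, "HA": 4.35, "HB": 4.24, "HG2": 1.21},
    "TRP": {"H": 8.25, "HA": 4.66, "HB2": 3.29, "HB3": 3.27, "HD1": 7.27,
            "HE1": 10.22, "HE3": 7.65, "HZ2": 7.50, "HZ3": 7.17, "HH2": 7.24},
    "TYR": {"H": 8.12, "HA": 4.55, "HB2": 3.03, "HB3": 2.98, "HD1": 7.14,
            "HD2": 7.14, "HE1": 6.84, "HE2": 6.84},
    "VAL": {"H": 8.03, "HA": 4.12, "HB": 2.08, "HG1": 0.94, "HG2": 0.93},
}

RANDOM_COIL_N: dict[str, float] = {
    "ALA": 123.8, "ARG": 120.5, "ASN": 118.7, "ASP": 120.4, "CYS": 118.8,
    "GLN": 119.8, "GLU": 120.2, "GLY": 108.8, "HIS": 118.2, "ILE": 119.9,
    "LEU": 121.8, "LYS": 120.4, "MET": 119.6, "PHE": 120.3, "SER": 115.7,
    "THR": 113.6, "TRP": 121.3, "TYR": 120.3, "VAL": 119.2,
}

RANDOM_COIL_CA: dict[str, float] = {
    "ALA": 52.5, "ARG": 56.0, "ASN": 53.1, "ASP": 54.2, "CYS": 58.2,
    "GLN": 55.7, "GLU": 56.6, "GLY": 45.1, "HIS": 55.0, "ILE": 61.1,
    "LEU": 55.1, "LYS": 56.2, "MET": 55.4, "PHE": 57.7, "PRO": 63.3,
    "SER": 58.3, "THR": 61.8, "TRP": 57.5, "TYR": 57.9, "VAL": 62.2,
}

RANDOM_COIL_CB: dict[str, float] = {
    "ALA": 19.1, "ARG": 30.9, "ASN": 38.9, "ASP": 41.1, "CYS": 28.0,
    "GLN": 29.4, "GLU": 29.9, "HIS": 29.0, "ILE": 38.8, "LEU": 42.4,
    "LYS": 33.1, "MET": 32.9, "PHE": 39.6, "PRO": 32.1, "SER": 63.8,
    "THR": 69.8, "TRP": 29.6, "TYR": 38.8, "VAL": 32.9,
}

# sidechain proton-bearing heavy atoms
RANDOM_COIL_SIDECHAIN_HEAVY: dict[tuple[str, str], float] = {
    ("ARG", "CG"): 27.3, ("ARG", "CD"): 43.2, ("ARG", "NE"): 84.7,
    ("ARG", "NH1"): 72.5, ("ARG", "NH2"): 72.5,
    ("ASN", "ND2"): 112.8,
    ("GLN", "CG"): 33.8, ("GLN", "NE2"): 111.9,
    ("GLU", "CG"): 36.1,
    ("HIS", "CD2"): 120.0, ("HIS", "CE1"): 136.0,
    ("ILE", "CG1"): 27.7, ("ILE", "CG2"): 17.5, ("ILE", "CD1"): 13.4,
    ("LEU", "CG"): 26.9, ("LEU", "CD1"): 24.9, ("LEU", "CD2"): 24.3,
    ("LYS", "CG"): 24.9, ("LYS", "CD"): 29.0, ("LYS", "CE"): 41.9,
    ("MET", "CG"): 32.0, ("MET", "CE"): 17.0,
    ("PHE", "CD1"): 131.5, ("PHE", "CD2"): 131.5, ("PHE", "CE1"): 130.8,
    ("PHE", "CE2"): 130.8, ("PHE", "CZ"): 129.5,
    ("PRO", "CG"): 27.2, ("PRO", "CD"): 50.3,
    ("THR", "CG2"): 21.6,
    ("TRP", "CD1"): 126.4, ("TRP", "NE1"): 129.3, ("TRP", "CE3"): 120.4,
    ("TRP", "CZ2"): 114.2, ("TRP", "CZ3"): 121.4, ("TRP", "CH2"): 123.9,
    ("TYR", "CD1"): 132.8, ("TYR", "CD2"): 132.8, ("TYR", "CE1"): 118.0,
    ("TYR", "CE2"): 118.0,
    ("VAL", "CG1"): 21.1, ("VAL", "CG2"): 20.3,
}


def heavy_shift(resname: str, atom: str) -> Optional[float]:
    if atom == "N":
        return RANDOM_COIL_N.get(resname)
    if atom == "CA":
        return RANDOM_COIL_CA.get(resname)
    if atom == "CB":
        return RANDOM_COIL_CB.get(resname)
    return RANDOM_COIL_SIDECHAIN_HEAVY.get((resname, atom))


# ---------------------------------------------------------------------------
# structure generation
# ---------------------------------------------------------------------------

# helix torsions and the optimized 3-residue turn that folds two ideal
# helices into a packed antiparallel hairpin without steric clashes
_HELIX = (-57.0, -47.0)
_TURN: tuple[tuple[float, float], ...] = ((129.7, -86.7), (68.8, 111.6), (-67.8, -126.3))

# residue palette: guarantees methyls, prochiral pairs and aromatics
_MANDATORY = ["VAL", "PHE", "LEU", "ILE", "TYR", "THR"]
_PALETTE = [
    "ALA", "VAL", "LEU", "ILE", "PHE", "TYR", "THR", "SER", "GLU", "GLN",
    "LYS", "ARG", "ASP", "ASN", "MET", "GLY", "HIS", "TRP", "CYS",
]


def make_sequence(config: SynthConfig) -> list[str]:
    """Deterministic mixed-type sequence with all pseudoatom classes."""
    rng = np.random.default_rng(config.seed)
    n = config.n_residues
    seq = [str(rng.choice(_PALETTE)) for _ in range(n)]
    positions = rng.choice(n, size=min(len(_MANDATORY), n), replace=False)
    for pos, res in zip(positions, _MANDATORY):
        seq[int(pos)] = res
    return seq


_ROTAMER_CHI1 = (-60.0, 180.0, 60.0)
_ROTAMER_CHI2 = (180.0, 60.0, -60.0, 90.0, -90.0)


def _pack_sidechains(
    seq: Sequence[str],
    phi: Sequence[float],
    psi: Sequence[float],
    chis: list[np.ndarray],
    rng: np.random.Generator,
    n_passes: int = 3,
) -> Conformer:
    """Greedy rotamer packing: per residue, keep the least-clashing combo."""
    from .geometry import SIDECHAIN_ICOORDS, nerf

    conf = build_conformer(seq, phi, psi, chis, add_protons=False)
    atoms = list(conf.atoms)
    coords = np.array(conf.coords)
    resnum = np.array([a.residue_number for a in atoms])
    residues = conf.residues()
    # indices of the mobile sidechain atoms (beyond CB) per residue
    index = {a: i for i, a in enumerate(atoms)}

    def sidechain_positions(resident, chi_set):
        chain, num, name = resident
        local: dict[str, np.ndarray] = {}

        def get(nm):
            if nm in local:
                return local[nm]
            return coords[index[AtomRef(chain, num, name, nm)]]

        out = []
        for atom, frame, length, angle, dih in SIDECHAIN_ICOORDS[name]:
            if isinstance(dih, tuple):
                _, k, off = dih
                base = chi_set[k - 1] if k <= len(chi_set) else 180.0
                dih_val = base + off
            else:
                dih_val = dih
            pos = nerf(get(frame[0]), get(frame[1]), get(frame[2]),
                       length, angle, dih_val)
            local[atom] = pos
            out.append((AtomRef(chain, num, name, atom), pos))
        return out

    for _pass in range(n_passes):
        for resident in residues:
            chain, num, name = resident
            if not SIDECHAIN_ICOORDS[name]:
                continue
            own = resnum == num
            near = ~own & (np.abs(resnum - num) >= 1)
            best = None
            from .geometry import N_CHI

            chi1_opts = _ROTAMER_CHI1 + ((90.0, -90.0) if _pass else ())
            chi3_opts = (180.0, -60.0, 60.0) if N_CHI[name] >= 3 else (180.0,)
            combos = [
                (c1, c2, c3, 180.0)
                for c1 in chi1_opts
                for c2 in _ROTAMER_CHI2
                for c3 in chi3_opts
            ]
            for chi_set in combos:
                placed = sidechain_positions(resident, chi_set)
                if not placed:
                    break
                pos = np.array([p for _, p in placed])
                d = np.linalg.norm(
                    pos[:, None, :] - coords[near][None, :, :], axis=-1
                )
                n_hard = int((d < 1.9).sum())
                n_soft = int((d < 2.7).sum())
                min_d = float(d.min())
                key = (n_hard, n_soft, -min_d)
                if best is None or key < best[0]:
                    best = (key, placed)
            if best is not None:
                for ref, pos in best[1]:
                    coords[index[ref]] = pos
    packed = conf.with_coords(coords)
    return packed


def make_structure(config: SynthConfig) -> Conformer:
    """Helical-hairpin toy fold, all atoms including hydrogens."""
    if not (10 <= config.n_residues <= 200):
        raise RpfError(
            f"n_residues must be in [10, 200], got {config.n_residues}"
        )
    seq = make_sequence(config)
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_residues
    n_turn = len(_TURN)
    n1 = (n - n_turn) // 2
    phi, psi = [], []
    for i in range(n):
        if i < n1:
            p, q = _HELIX
        elif i < n1 + n_turn:
            p, q = _TURN[i - n1]
        else:
            p, q = _HELIX
        phi.append(p)
        psi.append(q)
    chis = [
        np.array([rng.choice(_ROTAMER_CHI1), rng.choice(_ROTAMER_CHI2), 180.0, 180.0])
        for _ in seq
    ]
    packed = _pack_sidechains(seq, phi, psi, chis, rng)
    return add_hydrogens(packed)


# ---------------------------------------------------------------------------
# shifts
# ---------------------------------------------------------------------------

def _stem_of(resname: str, proton: str) -> Optional[str]:
    table = RANDOM_COIL_H[resname]
    if proton in table:
        return proton
    # methyl members: strip the trailing rotor index
    if proton[:-1] in table:
        return proton[:-1]
    return None


# prochiral stems that may be collapsed to a shared shift (ambiguity 2)
_PROCHIRAL_STEMS: dict[str, list[tuple[str, str]]] = {
    "ARG": [("HB2", "HB3"), ("HG2", "HG3")],
    "ASN": [("HB2", "HB3")],
    "ASP": [("HB2", "HB3")],
    "CYS": [("HB2", "HB3")],
    "GLN": [("HB2", "HB3")],
    "GLU": [("HB2", "HB3"), ("HG2", "HG3")],
    "GLY": [("HA2", "HA3")],
    "ILE": [("HG12", "HG13")],
    "LEU": [("HB2", "HB3"), ("HD1", "HD2")],
    "VAL": [("HG1", "HG2")],
    "SER": [("HB2", "HB3")],
    "TYR": [("HB2", "HB3")],
    "PHE": [("HB2", "HB3")],
    "TRP": [("HB2", "HB3")],
    "HIS": [("HB2", "HB3")],
    "LYS": [("HB2", "HB3"), ("HG2", "HG3")],
    "MET": [("HB2", "HB3")],
}


def make_shifts(conformer: Conformer, config: SynthConfig) -> list[AssignedShift]:
    """Assignment table for every placeable proton plus attached heavies.

    Values are the random-coil table entries plus seeded Gaussian jitter of
    ``shift_jitter`` ppm (one draw per resonance, shared by degenerate
    group members).  With ``collapse_prochiral`` the prochiral pairs share
    their mean shift and carry ambiguity code 2.
    """
    rng = np.random.default_rng(config.seed + 2)
    shifts: list[AssignedShift] = []
    for chain, resnum, resname in conformer.residues():
        table = dict(RANDOM_COIL_H[resname])
        amb: dict[str, int] = {}
        if config.collapse_prochiral:
            for a, b in _PROCHIRAL_STEMS.get(resname, []):
                mean = 0.5 * (table[a] + table[b])
                table[a] = table[b] = mean
                amb[a] = amb[b] = 2
        jitter: dict[str, float] = {}
        emitted: set[str] = set()
        for atom in conformer:
            if atom.residue_key != (chain, resnum) or not atom.atom_name.startswith("H"):
                continue
            stem = _stem_of(resname, atom.atom_name)
            if stem is None:
                continue
            if stem not in jitter:
                jitter[stem] = (
                    float(rng.normal(0.0, config.shift_jitter))
                    if config.shift_jitter > 0
                    else 0.0
                )
            # collapsed pairs resonate together: share one jitter draw
            if config.collapse_prochiral and amb.get(stem) == 2:
                partner = next(
                    (p for pair in _PROCHIRAL_STEMS.get(resname, []) for p in pair
                     if stem in pair and p != stem),
                    None,
                )
                if partner is not None and partner in jitter:
                    jitter[stem] = jitter[partner]
            shifts.append(
                AssignedShift(atom, table[stem] + jitter[stem], amb.get(stem, 1))
            )
            emitted.add(atom.atom_name)
        # heavy atoms carrying the emitted protons, plus backbone N/CA
        for atom in conformer:
            if atom.residue_key != (chain, resnum) or atom.atom_name.startswith("H"):
                continue
            val = heavy_shift(resname, atom.atom_name)
            if val is None:
                continue
            j = float(rng.normal(0.0, config.shift_jitter)) if config.shift_jitter else 0.0
            shifts.append(AssignedShift(atom, val + j, 1))
    return shifts


# ---------------------------------------------------------------------------
# NOESY peaks
# ---------------------------------------------------------------------------

def make_noesy(
    conformer: Conformer,
    shifts: Sequence[AssignedShift],
    config: SynthConfig,
    *,
    kind: str = "2d",
    spectrum_label: Optional[str] = None,
) -> PeakList:
    """NOESY peak list from the structure's short-distance network.

    One peak per site pair with summation distance <= ``d_max`` (for the
    edited 3D variants, only pairs whose acquisition-side proton sits on the
    edited nucleus), positions at the assigned shifts (+/- jitter), minus
    seeded dropout, plus seeded artifact peaks at random frequencies;
    intensities scale with d^-6.
    """
    if kind not in ("2d", "c13", "n15"):
        raise ValueError(f"unknown NOESY kind {kind!r}")
    rng = np.random.default_rng(config.seed + 3)
    shift_map = {s.atom: s for s in shifts}
    sites = build_proton_sites(conformer, shifts)
    graph = build_distance_graph(sites, conformer, config.d_max)

    def heavy_of(i: int) -> Optional[tuple[str, float]]:
        site = sites[i]
        m = site.members[0]
        from .geometry import attached_heavy_atom

        heavy = attached_heavy_atom(m.residue_name, m.atom_name)
        if heavy is None:
            return None
        ref = AtomRef(m.chain_id, m.residue_number, m.residue_name, heavy)
        s = shift_map.get(ref)
        return None if s is None else (heavy[0], s.shift)

    peaks: list[NoesyPeak] = []
    peak_id = 0
    edit_elem = {"c13": "C", "n15": "N"}.get(kind)
    for gid_a, gid_b, d_sum in graph.edges():
        i, j = graph.site_index[gid_a], graph.site_index[gid_b]
        # acquisition side must carry the edited nucleus (3D variants)
        if edit_elem is not None:
            if edit_elem in site_heavy_elements(sites[j]) and heavy_of(j):
                pass
            elif edit_elem in site_heavy_elements(sites[i]) and heavy_of(i):
                i, j = j, i
            else:
                continue
        if rng.uniform() < config.peak_dropout:
            continue
        peak_id += 1
        w_ind = sites[i].shifts[0]
        w_acq = sites[j].shifts[0]
        jit = (
            rng.normal(0.0, config.shift_jitter, size=3)
            if config.shift_jitter
            else np.zeros(3)
        )
        intensity = float(d_sum**-6 * 1e9)
        if edit_elem is None:
            peaks.append(
                NoesyPeak(
                    peak_id,
                    (w_ind + jit[0], w_acq + jit[1]),
                    ("H_indirect", "H_acq"),
                    intensity,
                )
            )
        else:
            _, hv = heavy_of(j)
            peaks.append(
                NoesyPeak(
                    peak_id,
                    (w_ind + jit[0], hv + jit[2], w_acq + jit[1]),
                    ("H_indirect", f"{edit_elem}_edit", "H_acq"),
                    intensity,
                )
            )

    n_artifacts = int(round(config.artifact_peak_rate * len(peaks)))
    if n_artifacts:
        h_vals = [s.shift for s in shifts if s.atom.atom_name.startswith("H")]
        lo, hi = min(h_vals), max(h_vals)
        heavy_vals = [
            s.shift
            for s in shifts
            if not s.atom.atom_name.startswith("H")
            and (edit_elem is None or s.atom.atom_name.startswith(edit_elem))
        ]
        for _ in range(n_artifacts):
            peak_id += 1
            w1, w2 = rng.uniform(lo, hi, size=2)
            if edit_elem is None:
                peaks.append(
                    NoesyPeak(
                        peak_id, (w1, w2), ("H_indirect", "H_acq"),
                        float(rng.uniform(0.5, 2.0) * 1e6),
                    )
                )
            else:
                hv = rng.uniform(min(heavy_vals), max(heavy_vals))
                peaks.append(
                    NoesyPeak(
                        peak_id, (w1, hv, w2),
                        ("H_indirect", f"{edit_elem}_edit", "H_acq"),
                        float(rng.uniform(0.5, 2.0) * 1e6),
                    )
                )

    label = spectrum_label or f"synth_{kind}"
    return PeakList(peaks, spectrum_label=label, dialect="tsv")


# ---------------------------------------------------------------------------
# decoys
# ---------------------------------------------------------------------------

_BACKBONE_NAMES = ("N", "CA", "C")


def backbone_rmsd(a: Conformer, b: Conformer) -> float:
    """Superposed backbone (N, CA, C) RMSD between two conformers (A)."""
    refs = [r for r in a.atoms if r.atom_name in _BACKBONE_NAMES and r in b]
    pa = np.array([a[r] for r in refs])
    pb = np.array([b[r] for r in refs])
    pa -= pa.mean(axis=0)
    pb -= pb.mean(axis=0)
    rot, _ = Rotation.align_vectors(pa, pb)
    pb = rot.apply(pb)
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


@dataclass
class Decoy:
    """One decoy model; the random-coil decoy is a chain ensemble."""

    label: str
    conformers: list[Conformer]
    noise_level: Optional[float]
    rmsd: float

    @property
    def conformer(self) -> Conformer:
        return self.conformers[0]


def make_decoys(
    conformer: Conformer, config: SynthConfig, *, chain_ensemble_size: int = 200
) -> list[Decoy]:
    """Gaussian coordinate-noise decoys plus a freely-rotating-chain decoy.

    Per-axis sigma is level / sqrt(3) so the expected all-atom displacement
    RMS matches the stated level.  The chain decoy is an ensemble of
    ``chain_ensemble_size`` conformers (a single random chain has an
    essentially arbitrary compactness; the ensemble is the meaningful
    random-coil null model and is scored with r^-6 conformer averaging).
    """
    rng = np.random.default_rng(config.seed + 4)
    decoys: list[Decoy] = []
    for level in config.coordinate_noise_levels:
        coords = conformer.coords + rng.normal(
            0.0, level / np.sqrt(3.0), size=conformer.coords.shape
        )
        decoy = conformer.with_coords(coords)
        decoys.append(
            Decoy(f"noise_{level:g}", [decoy], level, backbone_rmsd(conformer, decoy))
        )
    residues = conformer.residues()
    chain_confs = [
        sample_free_chain(
            [r[2] for r in residues],
            rng,
            chain_id=residues[0][0],
            residue_numbers=[r[1] for r in residues],
        )
        for _ in range(chain_ensemble_size)
    ]
    decoys.append(
        Decoy(
            "free_chain",
            chain_confs,
            None,
            float(np.median([backbone_rmsd(conformer, c) for c in chain_confs[:10]])),
        )
    )
    return decoys


# ---------------------------------------------------------------------------
# RDCs
# ---------------------------------------------------------------------------

def make_rdcs(
    conformer: Conformer,
    tensor: AlignmentTensor,
    *,
    noise: float = 0.0,
    seed: int = 0,
    vector: tuple[str, str] = ("N", "H"),
) -> list[RdcRecord]:
    """Forward-calculated couplings for one bond-vector type + noise (Hz)."""
    rng = np.random.default_rng(seed)
    records: list[RdcRecord] = []
    for chain, resnum, resname in conformer.residues():
        a = AtomRef(chain, resnum, resname, vector[0])
        try:
            b = AtomRef(chain, resnum, resname, vector[1])
        except Exception:
            continue
        if a not in conformer or b not in conformer:
            continue
        probe = RdcRecord(a, b, 1.0)
        d = calc_coupling(conformer, probe, tensor)
        d += float(rng.normal(0.0, noise)) if noise > 0 else 0.0
        records.append(RdcRecord(a, b, d))
    return records


# ---------------------------------------------------------------------------
# one-call world
# ---------------------------------------------------------------------------

@dataclass
class SynthWorld:
    """A full closed-loop benchmark instance."""

    config: SynthConfig
    structure: Conformer
    shifts: list[AssignedShift]
    peaks_2d: PeakList
    decoys: list[Decoy] = field(default_factory=list)


def make_world(config: SynthConfig, *, with_decoys: bool = False) -> SynthWorld:
    structure = make_structure(config)
    shifts = make_shifts(structure, config)
    peaks = make_noesy(structure, shifts, config, kind="2d")
    decoys = make_decoys(structure, config) if with_decoys else []
    return SynthWorld(
        config=config,
        structure=structure,
        shifts=shifts,
        peaks_2d=peaks,
        decoys=decoys,
    )
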