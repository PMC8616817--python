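"""Model-side distance network: protons, pseudoatom groups, summation
distances and the short-distance graph.

The central quantity is the summation distance between two proton groups,

    d_sum = ( sum_i sum_j r_ij^-6 )^(-1/6)

over all member pairs (i in group a, j in group b).  For an ensemble the
per-pair r^-6 terms are first averaged across conformers, then summed over
member pairs, then raised to the -1/6 power.  Pair distances below
``CLASH_FLOOR`` are floored (with a warning) so that physically unreasonable
models still receive a score instead of an error.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import (
    ClashError,
    ClashWarning,
    OverlappingSitesError,
    UnknownResidueError,
    UnmappedAssignmentWarning,
)
from .geometry import attached_heavy_atom, place_protons_on_residue, proton_names
from .types import AssignedShift, AtomRef, Conformer

DEFAULT_D_MAX = 5.0  # Angstrom; 7.0 recommended for perdeuterated samples
CLASH_FLOOR = 0.5  # Angstrom


# ---------------------------------------------------------------------------
# hydrogen addition
# ---------------------------------------------------------------------------

def add_hydrogens(conformer: Conformer) -> Conformer:
    """Return a conformer with ideal-geometry protons added.

    Existing hydrogens are preserved; only missing ones are built.  Residues
    with missing heavy frame atoms lose the dependent protons (with a
    :class:`ProtonPlacementWarning`).
    """
    out = Conformer((a, conformer[a]) for a in conformer)
    prev_c: Optional[np.ndarray] = None
    prev_chain: Optional[str] = None
    for chain, resnum, resname in conformer.residues():
        if prev_chain is not None and prev_chain != chain:
            prev_c = None
        for ref, pos in place_protons_on_residue(
            out, chain, resnum, resname, prev_c if prev_chain == chain else None
        ):
            if ref not in out:
                out.add(ref, pos)
        c_ref = AtomRef(chain, resnum, resname, "C")
        prev_c = conformer.get(c_ref)
        prev_chain = chain
    return out


# ---------------------------------------------------------------------------
# pseudoatom grouping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtonSite:
    """A proton or degenerate proton group, the node unit of both graphs."""

    group_id: str
    members: tuple[AtomRef, ...]
    representative_name: str
    shifts: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not (1 <= len(self.members) <= 6):
            raise ValueError(f"site {self.group_id}: {len(self.members)} members")
        res_keys = {m.residue_key for m in self.members}
        if len(res_keys) != 1:
            raise ValueError(f"site {self.group_id} spans residues")

    @property
    def residue_key(self) -> tuple[str, int]:
        return self.members[0].residue_key

    @property
    def residue_name(self) -> str:
        return self.members[0].residue_name


_METHYL_SUFFIXES = ("1", "2", "3")


def _stem_groups(resname: str) -> dict[str, list[str]]:
    """Group this residue's proton names by their degenerate-group stem.

    Methyl HX1/HX2/HX3 share stem HX; everything else is its own stem.
    """
    names = proton_names(resname)
    groups: dict[str, list[str]] = {}
    for nm in names:
        stem = nm
        if len(nm) > 2 and nm[-1] in _METHYL_SUFFIXES:
            cand = nm[:-1]
            trio = [cand + s for s in _METHYL_SUFFIXES]
            if all(t in names for t in trio):
                stem = cand
        groups.setdefault(stem, []).append(nm)
    return groups


# prochiral / aromatic pairs that merge when shifts coincide or are flagged
# ambiguous (NMR-STAR ambiguity code 2): pairs of stems -> merged pseudoatom
_MERGEABLE_PAIRS: dict[str, list[tuple[str, str, str]]] = {
    "LEU": [("HD1", "HD2", "QQD")],
    "VAL": [("HG1", "HG2", "QQG")],
    "PHE": [("HD1", "HD2", "QD"), ("HE1", "HE2", "QE")],
    "TYR": [("HD1", "HD2", "QD"), ("HE1", "HE2", "QE")],
}

# methylene (and NH2) prochiral pairs: geminal protons HX2/HX3 (or HX1/HX2)
# sharing one parent heavy atom
def _prochiral_pairs(
    resname: str, stems: dict[str, list[str]]
) -> list[tuple[str, str, str]]:
    pairs = []
    for a in sorted(stems):
        if len(stems[a]) != 1:
            continue
        for suf_a, suf_b in (("2", "3"), ("1", "2")):
            if not a.endswith(suf_a):
                continue
            b = a[:-1] + suf_b
            if b not in stems or len(stems[b]) != 1 or b == a:
                continue
            parent_a = attached_heavy_atom(resname, a)
            parent_b = attached_heavy_atom(resname, b)
            if parent_a is None or parent_a != parent_b:
                continue
            pairs.append((a, b, "Q" + a[1:-1]))
    # dedupe keeping first occurrence
    seen, out = set(), []
    for a, b, q in pairs:
        if (a, b) not in seen and (b, a) not in seen:
            seen.add((a, b))
            out.append((a, b, q))
    return out


def build_proton_sites(
    conformer: Conformer,
    shifts: Iterable[AssignedShift],
) -> list[ProtonSite]:
    """Group assigned protons of a (protonated) conformer into sites.

    Rules: methyls always merge; prochiral pairs merge when their two shifts
    are identical or either carries ambiguity code 2; Leu/Val isopropyl and
    Phe/Tyr ring pairs merge the same way (giving up-to-6-member sites);
    everything else is a singleton.  Assignments with no matching proton in
    the model are reported via :class:`UnmappedAssignmentWarning`.
    """
    shift_list = list(shifts)
    by_atom: dict[AtomRef, AssignedShift] = {s.atom: s for s in shift_list}

    # keep only 1H assignments present in the model
    proton_shifts: dict[AtomRef, AssignedShift] = {}
    for ref, s in by_atom.items():
        if not ref.atom_name.startswith("H"):
            continue
        if ref in conformer:
            proton_shifts[ref] = s
        else:
            warnings.warn(
                f"assignment for {ref} has no matching proton in the model",
                UnmappedAssignmentWarning,
                stacklevel=2,
            )

    # organize per residue
    per_res: dict[tuple[str, int, str], dict[str, AssignedShift]] = {}
    for ref, s in proton_shifts.items():
        per_res.setdefault(
            (ref.chain_id, ref.residue_number, ref.residue_name), {}
        )[ref.atom_name] = s

    sites: list[ProtonSite] = []
    for (chain, resnum, resname), assigned in sorted(per_res.items()):
        try:
            stems = _stem_groups(resname)
        except UnknownResidueError:
            continue
        # stem -> (members present&assigned, shifts, ambiguity)
        stem_info: dict[str, tuple[list[AtomRef], list[float], set[int]]] = {}
        for stem, names in stems.items():
            members, vals, ambs = [], [], set()
            for nm in names:
                if nm in assigned:
                    ref = AtomRef(chain, resnum, resname, nm)
                    members.append(ref)
                    vals.append(assigned[nm].shift)
                    ambs.add(assigned[nm].ambiguity_code)
            if members:
                stem_info[stem] = (members, sorted(set(round(v, 6) for v in vals)), ambs)

        merged: set[str] = set()
        pair_rules = _prochiral_pairs(resname, stems) + _MERGEABLE_PAIRS.get(resname, [])
        for stem_a, stem_b, qname in pair_rules:
            ia, ib = stem_info.get(stem_a), stem_info.get(stem_b)
            if ia is None or ib is None or stem_a in merged or stem_b in merged:
                continue
            same_shift = ia[1] == ib[1]
            ambiguous = 2 in ia[2] or 2 in ib[2]
            if same_shift or ambiguous:
                members = tuple(ia[0] + ib[0])
                if len(members) > 6:
                    continue
                shifts_merged = tuple(sorted(set(ia[1] + ib[1])))
                sites.append(
                    ProtonSite(
                        group_id=f"{chain}.{resnum}.{qname}",
                        members=members,
                        representative_name=qname,
                        shifts=shifts_merged,
                    )
                )
                merged.update((stem_a, stem_b))
        for stem, (members, vals, _ambs) in sorted(stem_info.items()):
            if stem in merged:
                continue
            rep = stem if len(members) == 1 else "Q" + stem[1:]
            sites.append(
                ProtonSite(
                    group_id=f"{chain}.{resnum}.{rep}",
                    members=tuple(members),
                    representative_name=rep,
                    shifts=tuple(vals),
                )
            )
    return sites


def site_heavy_shifts(
    site: ProtonSite, shifts: Iterable[AssignedShift] | Mapping[AtomRef, AssignedShift]
) -> tuple[float, ...]:
    """Shifts of the heavy atoms attached to a site's protons (if assigned)."""
    if not isinstance(shifts, Mapping):
        shifts = {s.atom: s for s in shifts}
    vals = []
    for m in site.members:
        heavy = attached_heavy_atom(m.residue_name, m.atom_name)
        if heavy is None:
            continue
        ref = AtomRef(m.chain_id, m.residue_number, m.residue_name, heavy)
        s = shifts.get(ref)
        if s is not None:
            vals.append(s.shift)
    return tuple(sorted(set(vals)))


def site_heavy_elements(site: ProtonSite) -> set[str]:
    """Element letters (C/N/O/S) of the heavy atoms bonded to site protons."""
    out = set()
    for m in site.members:
        heavy = attached_heavy_atom(m.residue_name, m.atom_name)
        if heavy:
            out.add(heavy[0])
    return out


# ---------------------------------------------------------------------------
# summation distances and the distance graph
# ---------------------------------------------------------------------------

def _conformer_list(conformers) -> list[Conformer]:
    if isinstance(conformers, Conformer):
        return [conformers]
    return list(conformers)


def summation_distance(
    site_a: ProtonSite,
    site_b: ProtonSite,
    conformers,
    *,
    clash_floor: float = CLASH_FLOOR,
) -> float:
    """r^-6 summation distance between two disjoint sites (Angstrom)."""
    if set(site_a.members) & set(site_b.members):
        raise OverlappingSitesError(
            f"sites {site_a.group_id} and {site_b.group_id} share protons"
        )
    confs = _conformer_list(conformers)
    terms = []
    for ma in site_a.members:
        for mb in site_b.members:
            r6_over_confs = []
            for conf in confs:
                r = float(np.linalg.norm(conf[ma] - conf[mb]))
                if r == 0.0:
                    raise ClashError(f"zero distance between {ma} and {mb}")
                if r < clash_floor:
                    warnings.warn(
                        f"distance {r:.2f} A between {ma} and {mb} floored to "
                        f"{clash_floor} A",
                        ClashWarning,
                        stacklevel=2,
                    )
                    r = clash_floor
                r6_over_confs.append(r ** -6)
            terms.append(float(np.mean(r6_over_confs)))
    return float(sum(terms) ** (-1.0 / 6.0))


@dataclass
class ModelDistanceGraph:
    """Short-interproton-distance network of one model (or ensemble).

    ``r6_sum[i, j]`` holds the conformer-averaged, member-summed r^-6 value
    for site pair (i, j); the summation distance is ``r6_sum ** (-1/6)`` and
    an edge exists where that distance is <= ``d_max``.
    """

    sites: list[ProtonSite]
    r6_sum: np.ndarray
    d_max: float
    site_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.site_index = {s.group_id: i for i, s in enumerate(self.sites)}

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def distances(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            d = np.where(self.r6_sum > 0, self.r6_sum ** (-1.0 / 6.0), np.inf)
        return d

    @property
    def edge_mask(self) -> np.ndarray:
        """Boolean (n, n) matrix, True where an edge exists (i != j)."""
        thresh = self.d_max ** -6.0
        mask = self.r6_sum >= thresh
        np.fill_diagonal(mask, False)
        return mask

    def edges(self) -> list[tuple[str, str, float]]:
        """(group_id_a, group_id_b, d_sum) for every edge, a < b."""
        mask = self.edge_mask
        d = self.distances
        out = []
        idx = np.argwhere(np.triu(mask, k=1))
        for i, j in idx:
            out.append((self.sites[i].group_id, self.sites[j].group_id, float(d[i, j])))
        return out

    def distance(self, gid_a: str, gid_b: str) -> float:
        return float(self.distances[self.site_index[gid_a], self.site_index[gid_b]])


def r6_matrix(
    sites: Sequence[ProtonSite],
    conformers,
    *,
    clash_floor: float = CLASH_FLOOR,
) -> np.ndarray:
    """Site-by-site matrix of conformer-averaged summed r^-6 terms.

    Computed via a membership matrix so the double sum over member pairs is
    a single matrix product per conformer.
    """
    confs = _conformer_list(conformers)
    protons = sorted({m for s in sites for m in s.members})
    p_index = {p: k for k, p in enumerate(protons)}
    a_mat = np.zeros((len(sites), len(protons)))
    for i, s in enumerate(sites):
        for m in s.members:
            a_mat[i, p_index[m]] = 1.0

    r6_accum = np.zeros((len(sites), len(sites)))
    floor6 = clash_floor ** -6.0
    n_floored = 0
    for conf in confs:
        coords = np.array([conf[p] for p in protons])
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        np.fill_diagonal(dist, np.inf)
        with np.errstate(divide="ignore"):
            r6 = dist ** -6.0
        over = r6 > floor6
        n_floored += int(np.count_nonzero(over) // 2)
        r6 = np.minimum(r6, floor6)
        r6_accum += a_mat @ r6 @ a_mat.T
    if n_floored:
        warnings.warn(
            f"{n_floored} interproton distances below {clash_floor} A floored",
            ClashWarning,
            stacklevel=2,
        )
    r6_accum /= len(confs)
    np.fill_diagonal(r6_accum, 0.0)
    return r6_accum


def build_distance_graph(
    sites: Sequence[ProtonSite],
    conformers,
    d_max: float = DEFAULT_D_MAX,
    *,
    clash_floor: float = CLASH_FLOOR,
) -> ModelDistanceGraph:
    """Distance network over ``sites`` for one conformer or an ensemble."""
    if not (d_max > 0):
        raise ValueError("d_max must be positive")
    return ModelDistanceGraph(
        sites=list(sites),
        r6_sum=r6_matrix(sites, conformers, clash_floor=clash_floor),
        d_max=d_max,
    )
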