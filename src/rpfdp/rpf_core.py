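"""Recall / precision / F-measure / DP scoring of models against NOESY data.

The data side is the ambiguous NOE graph: every cross peak is mapped, under
chemical-shift match tolerances, to the set of proton-site pairs that could
have produced it.  The model side is the short-summation-distance network
from :mod:`rpfdp.proton_model`.  A peak is a true positive when at least one
of its candidate pairs is short in the model; a model edge is a false
positive when no peak lists it among its candidates.  Precision is d^-6
weighted so weak long-distance contacts do not dominate.  The F-measure is
normalized between a freely-rotating-chain lower bound (DP = 0) and a
data-completeness upper bound estimated from 2-/3-bond proton pairs
(DP = 1).

Peaks whose two proton positions coincide within the 1H tolerance are
diagonal artifacts and are excluded; symmetrically, model edges between
sites whose reported shifts are everywhere within the 1H tolerance could
only produce diagonal peaks and are excluded from precision.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .chain import sample_free_chain
from .errors import EmptyPeakListError, EmptyShiftTableError
from .geometry import local_proton_pairs
from .nmr_io import ContactRecord
from .proton_model import (
    DEFAULT_D_MAX,
    ModelDistanceGraph,
    ProtonSite,
    build_distance_graph,
    build_proton_sites,
    r6_matrix,
    site_heavy_elements,
    site_heavy_shifts,
)
from .types import AssignedShift, AtomRef, Conformer, PeakList

PeakKey = tuple[str, int]


@dataclass(frozen=True)
class MatchTolerance:
    """Chemical-shift match tolerances (ppm) for 1H / 13C / 15N dimensions."""

    tol_h: float = 0.03
    tol_c: float = 0.4
    tol_n: float = 0.4

    def __post_init__(self) -> None:
        if not (self.tol_h >= 0 and self.tol_c >= 0 and self.tol_n >= 0):
            raise ValueError("tolerances must be non-negative")


@dataclass
class AmbiguousNoeGraph:
    """All possible assignments for every NOESY cross peak.

    ``candidates`` maps (spectrum_label, peak_id) to canonical (i, j) site
    index pairs (i < j) into ``sites``.
    """

    sites: list[ProtonSite]
    candidates: dict[PeakKey, tuple[tuple[int, int], ...]]
    unmatched_peaks: list[PeakKey]
    diagonal_peaks: list[PeakKey]
    peak_positions: dict[PeakKey, tuple[float, ...]] = field(default_factory=dict)

    @property
    def n_usable(self) -> int:
        return len(self.candidates)

    def candidate_pair_set(self) -> set[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for pairs in self.candidates.values():
            out.update(pairs)
        return out


def _edited_dim_pairing(dimension_types: Sequence[str]) -> dict[int, int]:
    """Map each edited-dimension index to the 1H dimension it filters.

    Each C/N-edited dimension constrains the nearest 1H dimension (ties go
    to the later, acquisition-side dimension).
    """
    h_dims = [i for i, t in enumerate(dimension_types) if t in ("H_acq", "H_indirect")]
    pairing: dict[int, int] = {}
    for k, t in enumerate(dimension_types):
        if t in ("C_edit", "N_edit"):
            pairing[k] = min(h_dims, key=lambda j: (abs(j - k), -j))
    return pairing


def match_peaks(
    peaklists: PeakList | Iterable[PeakList],
    shifts: Iterable[AssignedShift],
    sites: Sequence[ProtonSite],
    tol: MatchTolerance = MatchTolerance(),
) -> AmbiguousNoeGraph:
    """Build the ambiguous NOE graph by shift matching.

    A candidate pair (a, b) is kept when each 1H position matches a site
    shift within ``tol_h`` and, for edited dimensions, the heavy atom
    attached to the corresponding proton matches in element type and (when
    its shift is assigned) in frequency.  Self pairs and symmetric
    duplicates are collapsed; peaks whose 1H positions coincide within
    ``tol_h`` are set aside as diagonal artifacts.
    """
    if isinstance(peaklists, PeakList):
        peaklists = [peaklists]
    shift_list = list(shifts)
    if not shift_list:
        raise EmptyShiftTableError("cannot match peaks against an empty shift table")
    shift_map = {s.atom: s for s in shift_list}

    # flat arrays for 1H matching
    h_vals: list[float] = []
    h_site: list[int] = []
    for i, site in enumerate(sites):
        for v in site.shifts:
            h_vals.append(v)
            h_site.append(i)
    h_vals_arr = np.array(h_vals)
    h_site_arr = np.array(h_site, dtype=int)

    heavy_shifts = [site_heavy_shifts(s, shift_map) for s in sites]
    heavy_elems = [site_heavy_elements(s) for s in sites]

    def h_matches(pos: float) -> np.ndarray:
        if h_vals_arr.size == 0:
            return np.empty(0, dtype=int)
        hit = np.abs(h_vals_arr - pos) <= tol.tol_h
        return np.unique(h_site_arr[hit])

    def heavy_ok(site_idx: int, pos: float, dim_type: str) -> bool:
        elem = "C" if dim_type == "C_edit" else "N"
        if elem not in heavy_elems[site_idx]:
            return False
        vals = heavy_shifts[site_idx]
        if not vals:  # attached heavy atom unassigned: be permissive
            return True
        heavy_tol = tol.tol_c if dim_type == "C_edit" else tol.tol_n
        return min(abs(v - pos) for v in vals) <= heavy_tol

    candidates: dict[PeakKey, tuple[tuple[int, int], ...]] = {}
    unmatched: list[PeakKey] = []
    diagonal: list[PeakKey] = []
    positions: dict[PeakKey, tuple[float, ...]] = {}

    for plist in peaklists:
        for peak in plist:
            key = (plist.spectrum_label, peak.peak_id)
            positions[key] = peak.positions
            d1, d2 = peak.h_dims
            pos1, pos2 = peak.positions[d1], peak.positions[d2]
            if abs(pos1 - pos2) < tol.tol_h:
                diagonal.append(key)
                continue
            pairing = _edited_dim_pairing(peak.dimension_types)
            cand1 = h_matches(pos1)
            cand2 = h_matches(pos2)
            for edit_dim, h_dim in pairing.items():
                pool = cand1 if h_dim == d1 else cand2
                kept = np.array(
                    [
                        s
                        for s in pool
                        if heavy_ok(
                            int(s),
                            peak.positions[edit_dim],
                            peak.dimension_types[edit_dim],
                        )
                    ],
                    dtype=int,
                )
                if h_dim == d1:
                    cand1 = kept
                else:
                    cand2 = kept
            pairs = {
                (min(int(i), int(j)), max(int(i), int(j)))
                for i in cand1
                for j in cand2
                if i != j
            }
            if pairs:
                candidates[key] = tuple(sorted(pairs))
            else:
                unmatched.append(key)

    return AmbiguousNoeGraph(
        sites=list(sites),
        candidates=candidates,
        unmatched_peaks=unmatched,
        diagonal_peaks=diagonal,
        peak_positions=positions,
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class Classification:
    """TP/FN per peak and TP/FP per model edge for one model graph."""

    tp_peaks: list[PeakKey]
    fn_peaks: list[PeakKey]
    supported_edges: list[tuple[int, int]]  # model edges with >= 1 peak
    unsupported_edges: list[tuple[int, int]]  # FP
    excluded_edges: list[tuple[int, int]]  # shift-degenerate, unobservable
    tn: int

    @property
    def tp(self) -> int:
        return len(self.tp_peaks)

    @property
    def fn(self) -> int:
        return len(self.fn_peaks)

    @property
    def fp(self) -> int:
        return len(self.unsupported_edges)


def _observable_edge_mask(
    sites: Sequence[ProtonSite], tol_h: float
) -> Optional[np.ndarray]:
    """True where some shift combination of the two sites is >= tol_h apart.

    Edges failing this could only produce diagonal peaks; returns None when
    every pair is observable (tol_h == 0).
    """
    if tol_h <= 0:
        return None
    n = len(sites)
    lo = np.array([min(s.shifts) if s.shifts else np.nan for s in sites])
    hi = np.array([max(s.shifts) if s.shifts else np.nan for s in sites])
    # max |sa - sb| over combinations = max(hi_a - lo_b, hi_b - lo_a)
    spread = np.maximum(hi[:, None] - lo[None, :], hi[None, :] - lo[:, None])
    mask = spread >= tol_h
    mask &= ~np.isnan(spread)
    np.fill_diagonal(mask, False)
    return mask


def classify(
    graph_model: ModelDistanceGraph,
    graph_anoe: AmbiguousNoeGraph,
    tol: MatchTolerance = MatchTolerance(),
) -> Classification:
    """Classify peaks (TP/FN) and model edges (TP/FP) against each other."""
    if [s.group_id for s in graph_model.sites] != [
        s.group_id for s in graph_anoe.sites
    ]:
        raise ValueError("model graph and NOE graph use different site universes")

    edge_mask = graph_model.edge_mask
    observable = _observable_edge_mask(graph_model.sites, tol.tol_h)
    if observable is not None:
        scored_mask = edge_mask & observable
    else:
        scored_mask = edge_mask

    tp_peaks: list[PeakKey] = []
    fn_peaks: list[PeakKey] = []
    for key, pairs in graph_anoe.candidates.items():
        if any(edge_mask[i, j] for i, j in pairs):
            tp_peaks.append(key)
        else:
            fn_peaks.append(key)

    cand_set = graph_anoe.candidate_pair_set()
    supported: list[tuple[int, int]] = []
    unsupported: list[tuple[int, int]] = []
    excluded: list[tuple[int, int]] = []
    for i, j in map(tuple, np.argwhere(np.triu(edge_mask, k=1))):
        i, j = int(i), int(j)
        if observable is not None and not observable[i, j]:
            excluded.append((i, j))
        elif (i, j) in cand_set:
            supported.append((i, j))
        else:
            unsupported.append((i, j))

    n = graph_model.n_sites
    total_pairs = n * (n - 1) // 2
    n_edges = int(np.count_nonzero(np.triu(edge_mask, k=1)))
    non_edge_cands = len({p for p in cand_set if not edge_mask[p[0], p[1]]})
    tn = total_pairs - n_edges - non_edge_cands

    return Classification(
        tp_peaks=tp_peaks,
        fn_peaks=fn_peaks,
        supported_edges=supported,
        unsupported_edges=unsupported,
        excluded_edges=excluded,
        tn=tn,
    )


def precision_weighted(
    cls: Classification, graph_model: ModelDistanceGraph
) -> float:
    """d^-6-weighted precision over the model's scored edges."""
    w_tp = sum(graph_model.r6_sum[i, j] for i, j in cls.supported_edges)
    w_fp = sum(graph_model.r6_sum[i, j] for i, j in cls.unsupported_edges)
    if w_tp + w_fp == 0:
        return 0.0
    return float(w_tp / (w_tp + w_fp))


def _f_measure(recall: float, precision: float) -> float:
    if recall + precision == 0:
        return 0.0
    return 2.0 * recall * precision / (recall + precision)


def _score_one(
    graph_model: ModelDistanceGraph,
    graph_anoe: AmbiguousNoeGraph,
    tol: MatchTolerance,
) -> tuple[Classification, float, float, float]:
    cls = classify(graph_model, graph_anoe, tol)
    denom = cls.tp + cls.fn
    recall = cls.tp / denom if denom else 0.0
    precision = precision_weighted(cls, graph_model)
    return cls, recall, precision, _f_measure(recall, precision)


# ---------------------------------------------------------------------------
# F bounds
# ---------------------------------------------------------------------------

def f_free(
    graph_anoe: AmbiguousNoeGraph,
    tol: MatchTolerance = MatchTolerance(),
    d_max: float = DEFAULT_D_MAX,
    *,
    seed: int = 0,
    n_conformers: int = 200,
) -> float:
    """Lower bound of F: the freely-rotating-chain network scored against
    the same ambiguous NOE graph.

    The chain model keeps ideal bond geometry and draws all torsions
    uniformly (no excluded volume).  Its distance network uses r^-6
    distances averaged over ``n_conformers`` seeded chain samples — a single
    graph, like the model-ensemble scoring path — which makes the estimate
    deterministic for a fixed seed and stable in M (single-chain F values
    fluctuate wildly with chain compactness; the averaged network does not).
    """
    sites = graph_anoe.sites
    residues: dict[tuple[str, int], str] = {}
    for s in sites:
        residues[s.residue_key] = s.residue_name
    ordered = sorted(residues)
    if not ordered:
        return 0.0
    chain_id = ordered[0][0]
    numbers = [num for _, num in ordered]
    seq = [residues[k] for k in ordered]

    rng = np.random.default_rng(seed)
    conformers = [
        sample_free_chain(seq, rng, chain_id=chain_id, residue_numbers=numbers)
        for _ in range(n_conformers)
    ]
    graph = build_distance_graph(sites, conformers, d_max)
    _, _, _, f = _score_one(graph, graph_anoe, tol)
    return float(f)


def f_ideal(
    graph_anoe: AmbiguousNoeGraph,
    reference_r6: np.ndarray,
    tol: MatchTolerance = MatchTolerance(),
) -> float:
    """Upper bound of F from NOESY completeness over local proton pairs.

    recall(ideal) = 1; precision(ideal) is the d^-6-weighted fraction of
    observable 2-/3-bond proton pairs that have a supporting peak;
    ``reference_r6`` supplies the weights (local distances are fixed by
    covalent geometry, so any reasonable model serves as reference).
    """
    sites = graph_anoe.sites
    site_of: dict[AtomRef, int] = {}
    for i, s in enumerate(sites):
        for m in s.members:
            site_of[m] = i

    residues: dict[tuple[str, int], str] = {}
    for s in sites:
        residues[s.residue_key] = s.residue_name
    res_list = [(chain, num, residues[(chain, num)]) for chain, num in sorted(residues)]

    local_pairs: set[tuple[int, int]] = set()
    for pair in local_proton_pairs(res_list):
        a, b = tuple(pair)
        ia, ib = site_of.get(a), site_of.get(b)
        if ia is None or ib is None or ia == ib:
            continue
        local_pairs.add((min(ia, ib), max(ia, ib)))

    observable = _observable_edge_mask(sites, tol.tol_h)
    if observable is not None:
        local_pairs = {p for p in local_pairs if observable[p[0], p[1]]}
    if not local_pairs:
        return 0.0

    cand_set = graph_anoe.candidate_pair_set()
    w_all = sum(reference_r6[i, j] for i, j in local_pairs)
    w_hit = sum(reference_r6[i, j] for i, j in local_pairs if (i, j) in cand_set)
    p_local = w_hit / w_all if w_all > 0 else 0.0
    return _f_measure(1.0, p_local)


# ---------------------------------------------------------------------------
# composite scoring
# ---------------------------------------------------------------------------

@dataclass
class RpfResult:
    """Scores for one model (or the conformer-averaged ensemble)."""

    label: str
    tp: int
    fp: int
    fn: int
    tn: int
    recall: float
    precision_w: float
    f_measure: float
    f_free: float
    f_ideal: float
    dp: float
    n_unmatched: int
    n_diagonal: int
    per_residue_recall_viol: dict[tuple[str, int], float]
    per_residue_precision_viol: dict[tuple[str, int], float]

    def as_dict(self) -> dict:
        d = {
            "label": self.label,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "recall": self.recall,
            "precision_w": self.precision_w,
            "f_measure": self.f_measure,
            "f_free": self.f_free,
            "f_ideal": self.f_ideal,
            "dp": self.dp,
            "n_unmatched": self.n_unmatched,
            "n_diagonal": self.n_diagonal,
        }
        return d


@dataclass
class RpfReport:
    """Full scoring output: per-conformer results plus ensemble result."""

    per_conformer: list[RpfResult]
    ensemble: Optional[RpfResult]
    f_free: float
    f_ideal: float
    n_sites: int
    n_peaks_usable: int

    def as_dict(self) -> dict:
        return {
            "f_free": self.f_free,
            "f_ideal": self.f_ideal,
            "n_sites": self.n_sites,
            "n_peaks_usable": self.n_peaks_usable,
            "per_conformer": [r.as_dict() for r in self.per_conformer],
            "ensemble": self.ensemble.as_dict() if self.ensemble else None,
        }


def _dp(f: float, f_free_val: float, f_ideal_val: float) -> float:
    denom = f_ideal_val - f_free_val
    if abs(denom) < 1e-12:
        return math.nan
    return (f - f_free_val) / denom


def _violation_maps(
    cls: Classification, graph_anoe: AmbiguousNoeGraph
) -> tuple[dict, dict]:
    recall_map: dict[tuple[str, int], float] = {}
    sites = graph_anoe.sites
    for key in cls.fn_peaks:
        pairs = graph_anoe.candidates[key]
        frac = 1.0 / len(pairs)
        for i, j in pairs:
            for idx in (i, j):
                rk = sites[idx].residue_key
                recall_map[rk] = recall_map.get(rk, 0.0) + frac
    precision_map: dict[tuple[str, int], float] = {}
    for i, j in cls.unsupported_edges:
        for idx in (i, j):
            rk = sites[idx].residue_key
            precision_map[rk] = precision_map.get(rk, 0.0) + 1.0
    return recall_map, precision_map


def _result_from(
    label: str,
    graph_model: ModelDistanceGraph,
    graph_anoe: AmbiguousNoeGraph,
    tol: MatchTolerance,
    f_free_val: float,
    f_ideal_val: float,
) -> RpfResult:
    cls, recall, precision, f = _score_one(graph_model, graph_anoe, tol)
    rmap, pmap = _violation_maps(cls, graph_anoe)
    return RpfResult(
        label=label,
        tp=cls.tp,
        fp=cls.fp,
        fn=cls.fn,
        tn=cls.tn,
        recall=recall,
        precision_w=precision,
        f_measure=f,
        f_free=f_free_val,
        f_ideal=f_ideal_val,
        dp=_dp(f, f_free_val, f_ideal_val),
        n_unmatched=len(graph_anoe.unmatched_peaks),
        n_diagonal=len(graph_anoe.diagonal_peaks),
        per_residue_recall_viol=rmap,
        per_residue_precision_viol=pmap,
    )


def score_rpf(
    conformers: Conformer | Sequence[Conformer],
    shifts: Iterable[AssignedShift],
    peaklists: PeakList | Iterable[PeakList],
    *,
    tol: MatchTolerance = MatchTolerance(),
    d_max: float = DEFAULT_D_MAX,
    mode: str = "ensemble",
    free_chain_size: int = 200,
    seed: int = 0,
    protonate: bool = True,
) -> RpfReport:
    """Score one model or an ensemble against NOESY peak and shift data.

    ``mode``: ``single`` (per-conformer results only) or ``ensemble``
    (additionally score with r^-6 distances averaged across conformers).
    Raises :class:`EmptyPeakListError` when no peak has any candidate
    assignment (recall undefined).
    """
    if isinstance(conformers, Conformer):
        conformers = [conformers]
    conformers = list(conformers)
    if mode not in ("single", "ensemble"):
        raise ValueError(f"unknown mode {mode!r}")
    shift_list = list(shifts)
    if protonate:
        from .proton_model import add_hydrogens

        conformers = [add_hydrogens(c) for c in conformers]

    sites = build_proton_sites(conformers[0], shift_list)
    graph_anoe = match_peaks(peaklists, shift_list, sites, tol)
    if graph_anoe.n_usable == 0:
        raise EmptyPeakListError(
            "no NOESY peak has a candidate assignment within tolerance; "
            "recall is undefined"
        )

    ref_r6 = r6_matrix(sites, conformers[0])
    f_ideal_val = f_ideal(graph_anoe, ref_r6, tol)
    f_free_val = f_free(
        graph_anoe, tol, d_max, seed=seed, n_conformers=free_chain_size
    )

    per_conformer = []
    for k, conf in enumerate(conformers):
        graph = build_distance_graph(sites, conf, d_max)
        per_conformer.append(
            _result_from(f"model_{k + 1}", graph, graph_anoe, tol, f_free_val, f_ideal_val)
        )

    ensemble = None
    if mode == "ensemble" and len(conformers) >= 1:
        graph_ens = build_distance_graph(sites, conformers, d_max)
        ensemble = _result_from(
            "ensemble", graph_ens, graph_anoe, tol, f_free_val, f_ideal_val
        )

    return RpfReport(
        per_conformer=per_conformer,
        ensemble=ensemble,
        f_free=f_free_val,
        f_ideal=f_ideal_val,
        n_sites=len(sites),
        n_peaks_usable=graph_anoe.n_usable,
    )


# ---------------------------------------------------------------------------
# ambiguous contact lists
# ---------------------------------------------------------------------------

def contact_records(graph_anoe: AmbiguousNoeGraph) -> list[ContactRecord]:
    """Flatten the ambiguous NOE graph into contact-list records."""
    records: list[ContactRecord] = []
    sites = graph_anoe.sites
    for (label, peak_id), pairs in sorted(graph_anoe.candidates.items()):
        pos = graph_anoe.peak_positions.get((label, peak_id), ())
        for i, j in pairs:
            sa, sb = sites[i], sites[j]
            records.append(
                ContactRecord(
                    peak_id=peak_id,
                    dim_positions=pos,
                    candidate_rank=0,  # assigned on write
                    atom_a=f"{sa.residue_key[0]}.{sa.residue_key[1]}."
                    f"{sa.residue_name}.{sa.representative_name}",
                    atom_b=f"{sb.residue_key[0]}.{sb.residue_key[1]}."
                    f"{sb.residue_name}.{sb.representative_name}",
                )
            )
    return records
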