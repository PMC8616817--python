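"""Readers and writers for every external format the toolkit touches.

Coordinates are read with Biopython's PDB parser (alternate locations
resolved to the highest-occupancy conformer, ties broken toward altloc 'A');
everything else is small columnar text: an in-house TSV for shifts, peaks,
RDCs and contact lists, a minimal NMR-STAR v3 chemical-shift-loop reader,
and the XEASY ``.peaks`` / Sparky ``.list`` NOESY dialects.

Proton nomenclature is normalized on input to the IUPAC/BMRB convention
(HB2/HB3, not 1HB/2HB; amide proton ``H``, not ``HN``).
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import (
    ConflictingShiftError,
    DimensionMismatchError,
    FileFormatError,
    InconsistentEnsembleWarning,
    MissingModelError,
    SkippedResidueWarning,
)
from .types import (
    AssignedShift,
    AtomRef,
    Conformer,
    NoesyPeak,
    PeakList,
    RdcRecord,
    STANDARD_RESIDUES,
)

# ---------------------------------------------------------------------------
# atom-name normalization
# ---------------------------------------------------------------------------

def normalize_atom_name(name: str) -> str:
    """Translate PDB v2/v3 hydrogen-name variants to IUPAC/BMRB form."""
    name = name.strip()
    if name == "HN":
        return "H"
    # PDB v2 style: leading digit rotates to the end (1HB -> HB1)
    if name and name[0].isdigit():
        name = name[1:] + name[0]
    return name


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def read_coordinates(
    path: str | Path, model_index: Optional[int] = None
) -> list[Conformer]:
    """Read a PDB file into one conformer per MODEL block.

    Hydrogens are retained when present; non-standard residues (waters,
    ligands) are skipped with a :class:`SkippedResidueWarning`.  When
    ``model_index`` is given (zero-based) only that conformer is returned.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    path = Path(path)
    if not path.exists():
        raise FileFormatError(f"no such coordinate file: {path}")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            structure = parser.get_structure(path.stem, str(path))
        except Exception as exc:  # Bio raises assorted types on garbage
            raise FileFormatError(f"cannot parse PDB file {path}: {exc}") from exc

    conformers: list[Conformer] = []
    skipped: set[str] = set()
    for model in structure:
        conf = Conformer()
        for pdb_chain in model:
            for residue in pdb_chain:
                hetflag, resseq, _icode = residue.id
                resname = residue.get_resname().strip()
                if hetflag.strip() or resname not in STANDARD_RESIDUES:
                    skipped.add(resname)
                    continue
                for atom in residue:
                    if atom.is_disordered():
                        children = sorted(
                            atom.disordered_get_list(),
                            key=lambda a: (-a.get_occupancy(), a.get_altloc()),
                        )
                        atom = children[0]
                    ref = AtomRef(
                        pdb_chain.id.strip() or "A",
                        resseq,
                        resname,
                        normalize_atom_name(atom.get_name()),
                    )
                    if ref not in conf:
                        conf.add(ref, atom.get_coord())
        if len(conf):
            conformers.append(conf)
    if skipped:
        warnings.warn(
            f"skipped non-standard residues in {path.name}: {sorted(skipped)}",
            SkippedResidueWarning,
            stacklevel=2,
        )
    if not conformers:
        raise MissingModelError(f"no protein atoms found in {path}")

    atom_sets = [frozenset(c.atoms) for c in conformers]
    if len(set(atom_sets)) > 1:
        warnings.warn(
            f"conformers of {path.name} do not share an identical atom set",
            InconsistentEnsembleWarning,
            stacklevel=2,
        )
    if model_index is not None:
        if not (0 <= model_index < len(conformers)):
            raise MissingModelError(
                f"model index {model_index} absent ({len(conformers)} models in {path})"
            )
        return [conformers[model_index]]
    return conformers


def write_coordinates(
    conformers: Conformer | Sequence[Conformer], path: str | Path
) -> None:
    """Write conformers as a (multi-MODEL) PDB file."""
    if isinstance(conformers, Conformer):
        conformers = [conformers]
    lines: list[str] = []
    multi = len(conformers) > 1
    for m, conf in enumerate(conformers, start=1):
        if multi:
            lines.append(f"MODEL     {m:4d}")
        serial = 1
        for ref in conf:
            x, y, z = conf[ref]
            name = ref.atom_name
            # PDB column rules: 4-char names start in column 13
            field = f" {name:<3s}" if len(name) < 4 else name
            element = name[0]
            lines.append(
                f"ATOM  {serial:5d} {field:<4s} {ref.residue_name:<3s} "
                f"{ref.chain_id[:1]}{ref.residue_number:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# chemical shifts
# ---------------------------------------------------------------------------

_SHIFT_COLUMNS = ["chain", "residue_number", "residue_name", "atom_name", "shift",
                  "ambiguity"]


def _collapse_shifts(rows: Iterable[AssignedShift]) -> list[AssignedShift]:
    by_atom: dict[AtomRef, AssignedShift] = {}
    for s in rows:
        prev = by_atom.get(s.atom)
        if prev is None:
            by_atom[s.atom] = s
        elif abs(prev.shift - s.shift) > 1e-9:
            raise ConflictingShiftError(
                f"{s.atom}: conflicting shifts {prev.shift} vs {s.shift}"
            )
    return sorted(by_atom.values(), key=lambda s: s.atom)


def read_shift_table(path: str | Path, dialect: str = "tsv") -> list[AssignedShift]:
    """Read a chemical-shift table (``tsv`` or ``nmrstar`` dialect)."""
    path = Path(path)
    if dialect == "tsv":
        return _read_shift_tsv(path)
    if dialect == "nmrstar":
        return _read_shift_star(path)
    raise FileFormatError(f"unknown shift-table dialect {dialect!r}")


def _read_shift_tsv(path: Path) -> list[AssignedShift]:
    rows: list[AssignedShift] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("chain\t"):
            continue
        parts = line.split("\t")
        if len(parts) not in (5, 6):
            raise FileFormatError(f"{path}:{lineno}: expected 5 or 6 columns")
        chain, num, res, atom, shift = parts[:5]
        amb = int(parts[5]) if len(parts) == 6 else 1
        rows.append(
            AssignedShift(
                AtomRef(chain, int(num), res, normalize_atom_name(atom)),
                float(shift),
                amb,
            )
        )
    return _collapse_shifts(rows)


def write_shift_table(shifts: Iterable[AssignedShift], path: str | Path) -> None:
    lines = ["\t".join(_SHIFT_COLUMNS)]
    for s in sorted(shifts, key=lambda s: s.atom):
        a = s.atom
        lines.append(
            f"{a.chain_id}\t{a.residue_number}\t{a.residue_name}\t{a.atom_name}"
            f"\t{s.shift:.4f}\t{s.ambiguity_code}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _read_shift_star(path: Path) -> list[AssignedShift]:
    """Minimal NMR-STAR v3 Atom_chem_shift loop reader.

    Understands exactly one construct: a ``loop_`` whose tags include
    ``_Atom_chem_shift.Comp_index_ID``, ``Comp_ID``, ``Atom_ID``, ``Val``
    and optionally ``Ambiguity_code`` / ``Auth_asym_ID``.
    """
    text = path.read_text()
    rows: list[AssignedShift] = []
    for loop_match in re.finditer(r"loop_(.*?)(?:stop_|\Z)", text, flags=re.S):
        body = loop_match.group(1)
        tags = re.findall(r"^\s*(_\S+)\s*$", body, flags=re.M)
        if not any(t.startswith("_Atom_chem_shift.") for t in tags):
            continue
        cols = {t.split(".", 1)[1]: i for i, t in enumerate(tags)}
        required = {"Comp_index_ID", "Comp_ID", "Atom_ID", "Val"}
        if not required <= cols.keys():
            raise FileFormatError(
                f"{path}: Atom_chem_shift loop lacks required tags {required - cols.keys()}"
            )
        data_part = re.split(r"^\s*_\S+\s*$", body, flags=re.M)[-1]
        tokens_per_row = len(tags)
        for line in data_part.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != tokens_per_row:
                raise FileFormatError(
                    f"{path}: shift-loop row has {len(tokens)} tokens, "
                    f"expected {tokens_per_row}: {line!r}"
                )
            resname = tokens[cols["Comp_ID"]].upper()
            chain = tokens[cols["Auth_asym_ID"]] if "Auth_asym_ID" in cols else "A"
            if chain == ".":
                chain = "A"
            amb_tok = tokens[cols["Ambiguity_code"]] if "Ambiguity_code" in cols else "1"
            amb = 1 if amb_tok in (".", "?") else int(amb_tok)
            rows.append(
                AssignedShift(
                    AtomRef(
                        chain,
                        int(tokens[cols["Comp_index_ID"]]),
                        resname,
                        normalize_atom_name(tokens[cols["Atom_ID"]]),
                    ),
                    float(tokens[cols["Val"]]),
                    amb,
                )
            )
        break
    if not rows:
        raise FileFormatError(f"{path}: no Atom_chem_shift loop found")
    return _collapse_shifts(rows)


# ---------------------------------------------------------------------------
# NOESY peak lists
# ---------------------------------------------------------------------------

def _validate_dimension_types(dimension_types: Sequence[str]) -> tuple[str, ...]:
    return tuple(dimension_types)


def read_peaklist(
    path: str | Path,
    dialect: Optional[str] = None,
    dimension_types: Optional[Sequence[str]] = None,
    spectrum_label: Optional[str] = None,
) -> PeakList:
    """Read a NOESY peak list (``xeasy``, ``sparky`` or ``tsv`` dialect).

    When ``dialect`` is omitted it is sniffed from the file extension and
    first line.  ``dimension_types`` must be supplied for the header-poor
    XEASY/Sparky dialects unless the file carries an in-house header line.
    """
    path = Path(path)
    if dialect is None:
        dialect = _sniff_peak_dialect(path)
    label = spectrum_label if spectrum_label is not None else path.stem
    if dialect == "tsv":
        return _read_peak_tsv(path, label)
    if dialect == "xeasy":
        return _read_peak_xeasy(path, dimension_types, label)
    if dialect == "sparky":
        return _read_peak_sparky(path, dimension_types, label)
    raise FileFormatError(f"unknown peak-list dialect {dialect!r}")


def _sniff_peak_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".peaks":
        return "xeasy"
    if suffix == ".list":
        return "sparky"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    first = ""
    for line in path.read_text().splitlines():
        if line.strip():
            first = line.strip()
            break
    if first.startswith("# Number of dimensions"):
        return "xeasy"
    if first.lower().startswith("assignment"):
        return "sparky"
    return "tsv"


def _read_peak_tsv(path: Path, label: str) -> PeakList:
    dimension_types: Optional[tuple[str, ...]] = None
    peaks: list[NoesyPeak] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#dimension_types:"):
            dimension_types = tuple(
                t.strip() for t in line.split(":", 1)[1].split(",") if t.strip()
            )
            continue
        if line.startswith("#") or line.startswith("peak_id\t"):
            continue
        if dimension_types is None:
            raise FileFormatError(f"{path}: missing '#dimension_types:' header")
        parts = line.split("\t")
        ndim = len(dimension_types)
        if len(parts) not in (1 + ndim, 2 + ndim):
            raise DimensionMismatchError(
                f"{path}:{lineno}: {len(parts)} columns for {ndim} dimensions"
            )
        intensity = float(parts[1 + ndim]) if len(parts) == 2 + ndim else None
        peaks.append(
            NoesyPeak(
                int(parts[0]),
                tuple(float(p) for p in parts[1 : 1 + ndim]),
                dimension_types,
                intensity,
            )
        )
    if dimension_types is None:
        raise FileFormatError(f"{path}: missing '#dimension_types:' header")
    return PeakList(peaks, spectrum_label=label, dialect="tsv")


def write_peaklist(peaklist: PeakList, path: str | Path) -> None:
    """Write a peak list in the in-house TSV dialect (round-trippable)."""
    if peaklist.peaks:
        dims = peaklist.peaks[0].dimension_types
    else:
        dims = ("H_indirect", "H_acq")
    lines = ["#dimension_types: " + ", ".join(dims)]
    lines.append(
        "peak_id\t" + "\t".join(f"w{i+1}" for i in range(len(dims))) + "\tintensity"
    )
    for p in peaklist:
        pos = "\t".join(f"{x:.4f}" for x in p.positions)
        inten = "" if p.intensity is None else f"{p.intensity:.6g}"
        lines.append(f"{p.peak_id}\t{pos}\t{inten}".rstrip("\t"))
    Path(path).write_text("\n".join(lines) + "\n")


_XEASY_INAME = {"H": "H_indirect", "HN": "H_acq", "C": "C_edit", "N": "N_edit"}


def _read_peak_xeasy(
    path: Path, dimension_types: Optional[Sequence[str]], label: str
) -> PeakList:
    """XEASY ``.peaks``: ``id w1..wN color type intensity err method ...``.

    Assignment columns (atom numbers trailing each row) are ignored;
    positions and intensity are kept.
    """
    ndim: Optional[int] = None
    iname: dict[int, str] = {}
    peaks: list[NoesyPeak] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*Number of dimensions\s+(\d+)", line)
            if m:
                ndim = int(m.group(1))
            m = re.match(r"#INAME\s+(\d+)\s+(\S+)", line)
            if m:
                iname[int(m.group(1))] = m.group(2)
            continue
        if ndim is None:
            raise FileFormatError(f"{path}: missing '# Number of dimensions' header")
        tokens = line.split()
        if len(tokens) < ndim + 1:
            raise FileFormatError(f"{path}:{lineno}: truncated peak row")
        peak_id = int(tokens[0])
        positions = tuple(float(t) for t in tokens[1 : 1 + ndim])
        intensity: Optional[float] = None
        if len(tokens) > ndim + 3:
            try:
                intensity = float(tokens[ndim + 3])
            except ValueError:
                intensity = None
        if dimension_types is None:
            if len(iname) == ndim:
                try:
                    dimension_types = tuple(
                        _XEASY_INAME[iname[i + 1]] for i in range(ndim)
                    )
                except KeyError as exc:
                    raise FileFormatError(
                        f"{path}: cannot map INAME label {exc} to a dimension type; "
                        "pass dimension_types explicitly"
                    ) from exc
            else:
                raise FileFormatError(
                    f"{path}: dimension types not declared; pass dimension_types"
                )
        if len(dimension_types) != ndim:
            raise DimensionMismatchError(
                f"{path}: {ndim} dimensions but {len(dimension_types)} types declared"
            )
        peaks.append(NoesyPeak(peak_id, positions, tuple(dimension_types), intensity))
    return PeakList(peaks, spectrum_label=label, dialect="xeasy")


def _read_peak_sparky(
    path: Path, dimension_types: Optional[Sequence[str]], label: str
) -> PeakList:
    """Sparky ``.list``: header ``Assignment w1 .. wN [Data Height]``."""
    peaks: list[NoesyPeak] = []
    header_dims = 0
    has_height = False
    next_id = 1
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.lower().startswith("assignment"):
            header_dims = len(re.findall(r"w\d+", line))
            has_height = "height" in line.lower() or "data" in line.lower()
            continue
        tokens = line.split()
        floats = []
        for t in tokens[1:]:
            try:
                floats.append(float(t))
            except ValueError:
                break
        ndim = header_dims or (len(floats) - (1 if has_height else 0)) or len(floats)
        if dimension_types is None:
            raise FileFormatError(
                f"{path}: Sparky lists carry no dimension typing; pass dimension_types"
            )
        if ndim and len(dimension_types) != ndim:
            raise DimensionMismatchError(
                f"{path}:{lineno}: {ndim} position columns but "
                f"{len(dimension_types)} types declared"
            )
        positions = tuple(floats[: len(dimension_types)])
        if len(positions) != len(dimension_types):
            raise FileFormatError(f"{path}:{lineno}: truncated peak row")
        intensity = (
            floats[len(dimension_types)] if len(floats) > len(dimension_types) else None
        )
        peaks.append(NoesyPeak(next_id, positions, tuple(dimension_types), intensity))
        next_id += 1
    return PeakList(peaks, spectrum_label=label, dialect="sparky")


# ---------------------------------------------------------------------------
# RDC tables
# ---------------------------------------------------------------------------

_RDC_COLUMNS = [
    "chain", "residue_a", "residue_name_a", "atom_a",
    "residue_b", "residue_name_b", "atom_b", "d_obs", "weight",
]


def read_rdc_table(path: str | Path) -> list[RdcRecord]:
    """Read the in-house RDC TSV (see :data:`_RDC_COLUMNS`)."""
    path = Path(path)
    records: list[RdcRecord] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("chain\t"):
            continue
        parts = line.split("\t")
        if len(parts) not in (8, 9):
            raise FileFormatError(f"{path}:{lineno}: expected 8 or 9 columns")
        chain = parts[0]
        rec = RdcRecord(
            AtomRef(chain, int(parts[1]), parts[2], normalize_atom_name(parts[3])),
            AtomRef(chain, int(parts[4]), parts[5], normalize_atom_name(parts[6])),
            float(parts[7]),
            float(parts[8]) if len(parts) == 9 else 1.0,
        )
        records.append(rec)
    return records


def write_rdc_table(records: Iterable[RdcRecord], path: str | Path) -> None:
    lines = ["\t".join(_RDC_COLUMNS)]
    for r in records:
        a, b = r.atom_a, r.atom_b
        lines.append(
            f"{a.chain_id}\t{a.residue_number}\t{a.residue_name}\t{a.atom_name}"
            f"\t{b.residue_number}\t{b.residue_name}\t{b.atom_name}"
            f"\t{r.d_obs:.4f}\t{r.weight:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ambiguous contact lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactRecord:
    """One candidate proton-pair assignment for one NOESY peak."""

    peak_id: int
    dim_positions: tuple[float, ...]
    candidate_rank: int
    atom_a: str  # site identity: chain.resnum.resname.representative
    atom_b: str


_CONTACT_COLUMNS = ["peak_id", "dim_positions", "candidate_rank", "atom_a", "atom_b"]


def contact_sort_key(rec: ContactRecord):
    def atom_key(text: str):
        chain, num, res, atom = text.split(".")
        return (chain, int(num), atom)

    return (rec.peak_id, atom_key(rec.atom_a), atom_key(rec.atom_b))


def write_contact_list(contacts: Sequence[ContactRecord], path: str | Path) -> None:
    """Write the ambiguous contact list TSV (stable ordering, round-trips)."""
    if not contacts:
        raise ValueError("contact list is empty")
    ordered = sorted(contacts, key=contact_sort_key)
    lines = ["\t".join(_CONTACT_COLUMNS)]
    rank = 0
    last_peak = None
    for rec in ordered:
        rank = 1 if rec.peak_id != last_peak else rank + 1
        last_peak = rec.peak_id
        pos = ",".join(f"{p:.4f}" for p in rec.dim_positions)
        lines.append(f"{rec.peak_id}\t{pos}\t{rank}\t{rec.atom_a}\t{rec.atom_b}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_contact_list(path: str | Path) -> list[ContactRecord]:
    path = Path(path)
    records: list[ContactRecord] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("peak_id\t") or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise FileFormatError(f"{path}:{lineno}: expected 5 columns")
        records.append(
            ContactRecord(
                int(parts[0]),
                tuple(float(x) for x in parts[1].split(",")),
                int(parts[2]),
                parts[3],
                parts[4],
            )
        )
    return records
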