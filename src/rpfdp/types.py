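"""Core domain types shared by every module.

All residue/atom identity flows through :class:`AtomRef`; coordinates live in
:class:`Conformer` (a thin ordered mapping from ``AtomRef`` to xyz in
Angstrom).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .errors import (
    DimensionMismatchError,
    DuplicatePeakIdError,
    UnknownResidueError,
)

STANDARD_RESIDUES = frozenset(
    [
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    ]
)

H_DIMENSION_TYPES = ("H_acq", "H_indirect")
DIMENSION_TYPES = ("H_acq", "H_indirect", "C_edit", "N_edit")


@dataclass(frozen=True, order=True)
class AtomRef:
    """One atom in author numbering, with IUPAC/BMRB proton nomenclature."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str

    def __post_init__(self) -> None:
        if self.residue_name not in STANDARD_RESIDUES:
            raise UnknownResidueError(
                f"residue {self.residue_name!r} at "
                f"{self.chain_id}{self.residue_number} is not a standard amino acid"
            )
        if not self.atom_name:
            raise ValueError("atom_name must be nonempty")

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)

    def __str__(self) -> str:  # e.g. A.15.ALA.HB1
        return f"{self.chain_id}.{self.residue_number}.{self.residue_name}.{self.atom_name}"

    @classmethod
    def parse(cls, text: str) -> "AtomRef":
        chain, num, res, atom = text.split(".")
        return cls(chain, int(num), res, atom)


@dataclass(frozen=True)
class AssignedShift:
    """One assigned nucleus: atom identity plus chemical shift in ppm."""

    atom: AtomRef
    shift: float
    ambiguity_code: int = 1

    def __post_init__(self) -> None:
        if not math.isfinite(self.shift):
            raise ValueError(f"non-finite shift for {self.atom}")


class Conformer:
    """Ordered atom collection with coordinates (Angstrom)."""

    def __init__(self, atoms: Iterable[tuple[AtomRef, Sequence[float]]] = ()):
        self._atoms: list[AtomRef] = []
        self._index: dict[AtomRef, int] = {}
        coords: list[Sequence[float]] = []
        for ref, xyz in atoms:
            self._index[ref] = len(self._atoms)
            self._atoms.append(ref)
            coords.append(xyz)
        self._coords = np.asarray(coords, dtype=float).reshape(len(self._atoms), 3)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._atoms)

    def __contains__(self, ref: AtomRef) -> bool:
        return ref in self._index

    def __iter__(self) -> Iterator[AtomRef]:
        return iter(self._atoms)

    def __getitem__(self, ref: AtomRef) -> np.ndarray:
        return self._coords[self._index[ref]]

    # -- accessors ----------------------------------------------------------
    @property
    def atoms(self) -> tuple[AtomRef, ...]:
        return tuple(self._atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array, ordered like :attr:`atoms`."""
        return self._coords

    def index_of(self, ref: AtomRef) -> int:
        return self._index[ref]

    def get(self, ref: AtomRef) -> Optional[np.ndarray]:
        i = self._index.get(ref)
        return None if i is None else self._coords[i]

    def add(self, ref: AtomRef, xyz: Sequence[float]) -> None:
        if ref in self._index:
            raise ValueError(f"duplicate atom {ref}")
        self._index[ref] = len(self._atoms)
        self._atoms.append(ref)
        self._coords = np.vstack([self._coords, np.asarray(xyz, dtype=float)])

    def with_coords(self, coords: np.ndarray) -> "Conformer":
        """Same atoms, new coordinate array."""
        if coords.shape != self._coords.shape:
            raise ValueError("coordinate array shape mismatch")
        out = Conformer()
        out._atoms = list(self._atoms)
        out._index = dict(self._index)
        out._coords = np.array(coords, dtype=float)
        return out

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, number, name) triples."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self._atoms:
            seen.setdefault((a.chain_id, a.residue_number, a.residue_name))
        return list(seen)

    def subset(self, predicate) -> "Conformer":
        return Conformer(
            (a, self._coords[i]) for i, a in enumerate(self._atoms) if predicate(a)
        )

    def protons(self) -> "Conformer":
        return self.subset(lambda a: a.atom_name.startswith("H"))


@dataclass(frozen=True)
class NoesyPeak:
    """One NOESY cross peak: per-dimension ppm positions and typing."""

    peak_id: int
    positions: tuple[float, ...]
    dimension_types: tuple[str, ...]
    intensity: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", tuple(float(p) for p in self.positions))
        object.__setattr__(self, "dimension_types", tuple(self.dimension_types))
        if len(self.positions) != len(self.dimension_types):
            raise DimensionMismatchError(
                f"peak {self.peak_id}: {len(self.positions)} positions vs "
                f"{len(self.dimension_types)} dimension types"
            )
        for t in self.dimension_types:
            if t not in DIMENSION_TYPES:
                raise DimensionMismatchError(
                    f"peak {self.peak_id}: unknown dimension type {t!r}"
                )
        n_h = sum(t in H_DIMENSION_TYPES for t in self.dimension_types)
        if n_h != 2:
            raise DimensionMismatchError(
                f"peak {self.peak_id}: need exactly two 1H dimensions, got {n_h}"
            )
        if not all(math.isfinite(p) for p in self.positions):
            raise ValueError(f"peak {self.peak_id}: non-finite position")

    @property
    def h_dims(self) -> tuple[int, int]:
        """Indices of the two proton dimensions (indirect first if typed)."""
        idx = [i for i, t in enumerate(self.dimension_types) if t in H_DIMENSION_TYPES]
        idx.sort(key=lambda i: (self.dimension_types[i] == "H_acq", i))
        return (idx[0], idx[1])


@dataclass
class PeakList:
    """An ordered NOESY peak collection from one spectrum."""

    peaks: list[NoesyPeak] = field(default_factory=list)
    spectrum_label: str = ""
    dialect: str = "tsv"

    def __post_init__(self) -> None:
        ids = [p.peak_id for p in self.peaks]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicatePeakIdError(
                f"peak list {self.spectrum_label!r}: duplicate peak ids {dup[:5]}"
            )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[NoesyPeak]:
        return iter(self.peaks)


@dataclass(frozen=True)
class RdcRecord:
    """One observed residual dipolar coupling between two atoms."""

    atom_a: AtomRef
    atom_b: AtomRef
    d_obs: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.atom_a == self.atom_b:
            raise ValueError(f"RDC record with identical atoms: {self.atom_a}")
        if not math.isfinite(self.d_obs):
            raise ValueError(f"non-finite coupling for {self.atom_a}-{self.atom_b}")
        if not (self.weight > 0):
            raise ValueError(f"non-positive weight for {self.atom_a}-{self.atom_b}")
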