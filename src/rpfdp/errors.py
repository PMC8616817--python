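"""Named exceptions and warnings used across the toolkit.

Data-level problems raise subclasses of :class:`RpfError` so the CLI can map
them to a distinct exit code; recoverable oddities are emitted as subclasses
of :class:`RpfWarning`.
"""


class RpfError(Exception):
    """Base class for all data / usage errors raised by this package."""


class FileFormatError(RpfError):
    """A file could not be parsed in its declared dialect."""


class UnknownResidueError(RpfError):
    """A residue name outside the 20 standard amino acids was encountered."""


class ConflictingShiftError(RpfError):
    """The same atom appears twice in a shift table with different values."""


class DuplicatePeakIdError(RpfError):
    """Two peaks in one list share a peak id."""


class DimensionMismatchError(RpfError):
    """Peak dimensionality does not match the declared dimension types."""


class EmptyPeakListError(RpfError):
    """No usable (matchable, non-diagonal) peaks: recall is undefined."""


class EmptyShiftTableError(RpfError):
    """A shift table with zero entries was supplied where one is required."""


class MissingModelError(RpfError):
    """Requested model index absent, or no protein atoms found."""


class OverlappingSitesError(RpfError):
    """Summation distance requested between sites that share a proton."""


class ClashError(RpfError):
    """Two protons coincide exactly; r^-6 summation is undefined."""


class RankDeficiencyError(RpfError):
    """RDC design matrix is rank deficient (degenerate bond-vector set)."""


class InsufficientRdcError(RpfError):
    """Fewer than five usable RDC records."""


class UnalignableError(RpfError):
    """Fitted alignment tensor has Da == 0; Q score undefined."""


class MissingHydrogenError(RpfError):
    """RDC type requires hydrogen positions absent from the model."""


class ConfigError(RpfError):
    """Bad key or value in a run-configuration file."""


class RpfWarning(UserWarning):
    """Base class for warnings emitted by this package."""


class InconsistentEnsembleWarning(RpfWarning):
    """Conformers of one ensemble do not share an identical atom set."""


class ProtonPlacementWarning(RpfWarning):
    """A hydrogen could not be placed (missing or degenerate frame atoms)."""


class UnmappedAssignmentWarning(RpfWarning):
    """A shift-table entry references a proton absent from the model."""


class ClashWarning(RpfWarning):
    """An interproton distance below 0.5 A was floored for scoring."""


class SkippedResidueWarning(RpfWarning):
    """A non-standard residue in a coordinate file was skipped."""
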