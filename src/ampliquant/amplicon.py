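"""Domain types for flank-anchored amplicon editing quantification.

An amplicon is described by two short flank anchors (10 bp by default)
that delimit an *editing window* — the stretch of reference sequence in
which nuclease-induced indels and donor-programmed base changes are
expected. Reads are located by mismatch-tolerant matches to the two
flanks; everything between the matched flanks is the observed window.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "DNA_ALPHABET",
    "BASE_COLUMNS",
    "revcomp",
    "DonorEdit",
    "AmpliconSpec",
    "ReadRecord",
    "Orientation",
    "FlankMatch",
    "Category",
    "ReadClassification",
    "EditingSummary",
]

DNA_ALPHABET = frozenset("ACGT")
#: column order of base-frequency matrices (N tallies ambiguous calls)
BASE_COLUMNS = ("A", "C", "G", "T", "N")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DonorEdit:
    """A programmed single-base substitution inside the editing window.

    Positions are 0-based indices into the reference window.
    """

    window_pos: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.ref_base not in DNA_ALPHABET or self.alt_base not in DNA_ALPHABET:
            raise ValueError(
                f"donor edit bases must be A/C/G/T, got {self.ref_base}>{self.alt_base}"
            )
        if self.ref_base == self.alt_base:
            raise ValueError(f"donor edit at {self.window_pos} does not change the base")
        if self.window_pos < 0:
            raise ValueError("window_pos must be >= 0")


@dataclass(frozen=True)
class AmpliconSpec:
    """Reference amplicon with two flank anchors delimiting the editing window.

    Parameters
    ----------
    amplicon_id : str
        Label for the locus (e.g. ``"TIE2"``).
    amplicon_seq : str
        Full reference amplicon, uppercase ACGT.
    left_flank, right_flank : str
        Anchor sequences; each must occur exactly once in ``amplicon_seq``,
        left before right and non-overlapping. 10 bp is the conventional
        length.
    donor_edits : tuple of DonorEdit
        The programmed substitutions (may be empty for a pure indel assay).

    The reference window ``window_ref`` is derived: the subsequence strictly
    between the end of the left flank and the start of the right flank.
    """

    amplicon_id: str
    amplicon_seq: str
    left_flank: str
    right_flank: str
    donor_edits: tuple[DonorEdit, ...] = ()
    window_ref: str = field(init=False)

    def __post_init__(self) -> None:
        seq = self.amplicon_seq.upper()
        object.__setattr__(self, "amplicon_seq", seq)
        object.__setattr__(self, "left_flank", self.left_flank.upper())
        object.__setattr__(self, "right_flank", self.right_flank.upper())
        object.__setattr__(self, "donor_edits", tuple(self.donor_edits))
        for name in ("amplicon_seq", "left_flank", "right_flank"):
            s = getattr(self, name)
            if not s or set(s) - DNA_ALPHABET:
                raise ValueError(f"{name} must be a non-empty uppercase ACGT string")
        for name in ("left_flank", "right_flank"):
            f = getattr(self, name)
            if seq.count(f) != 1:
                raise ValueError(
                    f"{name} {f!r} occurs {seq.count(f)} times in the amplicon; "
                    "each anchor must occur exactly once"
                )
        lstart = seq.index(self.left_flank)
        rstart = seq.index(self.right_flank)
        if lstart + len(self.left_flank) > rstart:
            raise ValueError("left flank must end before the right flank starts")
        window = seq[lstart + len(self.left_flank) : rstart]
        object.__setattr__(self, "window_ref", window)
        for e in self.donor_edits:
            if e.window_pos >= len(window):
                raise ValueError(
                    f"donor edit position {e.window_pos} outside window of length {len(window)}"
                )
            if window[e.window_pos] != e.ref_base:
                raise ValueError(
                    f"donor edit ref base {e.ref_base} does not match window base "
                    f"{window[e.window_pos]} at position {e.window_pos}"
                )

    @property
    def hdr_window(self) -> str:
        """The window sequence carrying every donor edit (the precise-edit allele)."""
        w = list(self.window_ref)
        for e in self.donor_edits:
            w[e.window_pos] = e.alt_base
        return "".join(w)


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read (FASTQ record).

    ``qual`` holds Phred scores; qualities are carried through but the
    default pipeline does not filter on them.
    """

    read_id: str
    seq: str
    qual: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.read_id!r} has an empty sequence")
        if self.qual and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )

    @property
    def mean_quality(self) -> float:
        return sum(self.qual) / len(self.qual) if self.qual else math.nan


class Orientation(str, enum.Enum):
    FORWARD = "forward"
    REVERSE_COMPLEMENT = "reverse_complement"


@dataclass(frozen=True)
class FlankMatch:
    """Placement of the two flank anchors within a read.

    Indices are 0-based into the read *in the matched orientation* (i.e.
    into the reverse complement of the read when ``orientation`` is
    ``REVERSE_COMPLEMENT``).
    """

    left_start: int
    right_start: int
    left_mismatches: int
    right_mismatches: int
    orientation: Orientation

    @property
    def total_mismatches(self) -> int:
        return self.left_mismatches + self.right_mismatches


class Category(str, enum.Enum):
    EXCLUDED = "excluded"
    INDEL = "indel"
    INTACT = "intact"


@dataclass(frozen=True)
class ReadClassification:
    """Per-read editing outcome.

    ``length_delta`` = observed window length − reference window length
    (nonzero only for INDEL: positive = insertion, negative = deletion).
    ``observed_window`` is None for excluded reads.
    """

    category: Category
    length_delta: int | None = None
    observed_window: str | None = None
    match: FlankMatch | None = None


@dataclass(frozen=True)
class EditingSummary:
    """Pool-level editing-outcome summary.

    Frequencies use the number of *analyzed* reads (those with both flanks
    matched) as the denominator; base frequencies are computed over intact
    reads only. All frequencies are NaN when no read could be analyzed.
    """

    n_total: int
    n_excluded: int
    n_indel: int
    n_insertion: int
    n_deletion: int
    n_intact: int
    indel_freq: float
    insertion_freq: float
    deletion_freq: float
    base_freq: "object"  # numpy array, shape (len(window_ref), 5)
    programmed_edit_freq: float
    programmed_edit_freq_intact: float
    per_position_edit_freq: dict[int, float]
    window_ref: str

    @property
    def n_analyzed(self) -> int:
        return self.n_indel + self.n_intact
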