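"""Flank-anchored classification of amplicon reads and pool-level summaries.

The algorithm locates each read's editing window by scanning for the two
flank anchors with a per-flank Hamming-distance tolerance (1 bp by
default), trying the read as given and then its reverse complement. Reads
in which no valid flank pair exists are excluded. For the rest, the
*length* of the observed window decides the call: a deviation from the
reference window length is an insertion (+) or deletion (−); an exact
length match is "intact", and base changes inside intact windows are
tallied as per-locus base frequencies — the base-edit readout.

Frequencies are fractions of *analyzed* (non-excluded) reads. The
programmed-edit (knock-in) frequency is the fraction of analyzed reads
whose window is intact and carries the donor base at every programmed
position.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence

import numpy as np

from .amplicon import (
    BASE_COLUMNS,
    AmpliconSpec,
    Category,
    EditingSummary,
    FlankMatch,
    Orientation,
    ReadClassification,
    ReadRecord,
    revcomp,
)

__all__ = [
    "find_flanks",
    "classify_read",
    "classify_reads",
    "quantify_pool",
    "base_frequency_matrix",
    "programmed_edit_frequency",
]


def _mismatch_profile(seq: str, flank: str) -> np.ndarray:
    """Hamming distance of ``flank`` against every placement in ``seq``.

    Returns an array of length ``len(seq) - len(flank) + 1`` (empty when the
    read is shorter than the flank). Any character differing from the flank
    base — including N — counts as a mismatch.
    """
    s = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    f = np.frombuffer(flank.encode("ascii"), dtype=np.uint8)
    if s.size < f.size:
        return np.empty(0, dtype=np.intp)
    windows = np.lib.stride_tricks.sliding_window_view(s, f.size)
    return (windows != f).sum(axis=1)


def _best_pair(
    seq: str, left: str, right: str, max_mismatch: int
) -> tuple[int, int, int, int] | None:
    """Best (left_start, right_start, left_mm, right_mm) placement in ``seq``.

    Optimal = minimal total mismatches subject to per-flank mismatches
    ≤ ``max_mismatch`` and the left flank ending at or before the right
    flank's start; ties broken by leftmost left_start, then leftmost
    right_start (the scan visits pairs in that order and keeps the first
    strict improvement).
    """
    lmm = _mismatch_profile(seq, left)
    rmm = _mismatch_profile(seq, right)
    lpos = np.flatnonzero(lmm <= max_mismatch)
    rpos = np.flatnonzero(rmm <= max_mismatch)
    if lpos.size == 0 or rpos.size == 0:
        return None
    best: tuple[int, int, int, int] | None = None
    k = len(left)
    for i in lpos:
        for j in rpos[rpos >= i + k]:
            total = int(lmm[i]) + int(rmm[j])
            if best is None or total < best[2] + best[3]:
                best = (int(i), int(j), int(lmm[i]), int(rmm[j]))
            if best[2] + best[3] == 0:
                return best  # cannot improve; earliest zero-mismatch pair
    return best


def find_flanks(
    read: ReadRecord | str,
    spec: AmpliconSpec,
    max_mismatch: int = 1,
    try_rc: bool = True,
) -> FlankMatch | None:
    """Locate the flank anchor pair in a read, or return None.

    The forward read is searched first, then (unless ``try_rc`` is False)
    its reverse complement; the orientation with fewer total mismatches
    wins, with the forward orientation preferred on ties. Returned indices
    refer to the read in the matched orientation.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    seq = read if isinstance(read, str) else read.seq
    if not seq:
        raise ValueError("cannot search an empty read sequence")
    seq = seq.upper()
    fwd = _best_pair(seq, spec.left_flank, spec.right_flank, max_mismatch)
    rc = (
        _best_pair(revcomp(seq), spec.left_flank, spec.right_flank, max_mismatch)
        if try_rc
        else None
    )
    if fwd is None and rc is None:
        return None
    if rc is None or (fwd is not None and fwd[2] + fwd[3] <= rc[2] + rc[3]):
        i, j, ml, mr = fwd
        return FlankMatch(i, j, ml, mr, Orientation.FORWARD)
    i, j, ml, mr = rc
    return FlankMatch(i, j, ml, mr, Orientation.REVERSE_COMPLEMENT)


def classify_read(
    read: ReadRecord | str,
    spec: AmpliconSpec,
    max_mismatch: int = 1,
    try_rc: bool = True,
) -> ReadClassification:
    """Classify one read as excluded, indel (signed length delta) or intact."""
    match = find_flanks(read, spec, max_mismatch, try_rc=try_rc)
    if match is None:
        return ReadClassification(Category.EXCLUDED)
    seq = (read if isinstance(read, str) else read.seq).upper()
    if match.orientation is Orientation.REVERSE_COMPLEMENT:
        seq = revcomp(seq)
    window = seq[match.left_start + len(spec.left_flank) : match.right_start]
    delta = len(window) - len(spec.window_ref)
    if delta != 0:
        return ReadClassification(Category.INDEL, delta, window, match)
    return ReadClassification(Category.INTACT, 0, window, match)


def classify_reads(
    reads: Iterable[ReadRecord],
    spec: AmpliconSpec,
    max_mismatch: int = 1,
    try_rc: bool = True,
    min_mean_q: float | None = None,
) -> list[ReadClassification]:
    """Classify every read; reads failing the optional mean-quality filter
    are excluded (they still count toward the pool total)."""
    out = []
    for read in reads:
        if (
            min_mean_q is not None
            and read.qual
            and read.mean_quality < min_mean_q
        ):
            out.append(ReadClassification(Category.EXCLUDED))
            continue
        out.append(classify_read(read, spec, max_mismatch, try_rc=try_rc))
    return out


_BASE_INDEX = np.full(128, BASE_COLUMNS.index("N"), dtype=np.intp)
for _i, _b in enumerate(BASE_COLUMNS[:4]):
    _BASE_INDEX[ord(_b)] = _i


def base_frequency_matrix(
    intact_windows: Sequence[str], window_ref: str
) -> np.ndarray:
    """Per-locus base frequencies across intact windows.

    Row ``i`` is the empirical distribution over (A, C, G, T, N) at window
    position ``i``; any non-ACGT character is tallied as N. Rows sum to 1;
    with no windows the matrix is all zeros.
    """
    n_pos = len(window_ref)
    counts = np.zeros((n_pos, len(BASE_COLUMNS)), dtype=np.int64)
    for w in intact_windows:
        if len(w) != n_pos:
            raise ValueError(
                f"window length {len(w)} != reference window length {n_pos}"
            )
        idx = _BASE_INDEX[np.frombuffer(w.encode("ascii"), dtype=np.uint8)]
        counts[np.arange(n_pos), idx] += 1
    if not intact_windows:
        return counts.astype(float)
    return counts / len(intact_windows)


def programmed_edit_frequency(
    intact_windows: Sequence[str],
    n_analyzed: int,
    spec: AmpliconSpec,
) -> tuple[float, float, dict[int, float]]:
    """Knock-in frequency: analyzed reads intact *and* edited at all donor positions.

    Returns ``(freq, freq_intact, per_position)`` where ``freq`` uses the
    analyzed-read denominator, ``freq_intact`` the intact-read denominator,
    and ``per_position`` maps each donor position to the fraction of
    analyzed reads carrying its alt base (in an intact window).
    """
    if not spec.donor_edits:
        raise ValueError("amplicon spec declares no donor edits")
    n_all = 0
    per_pos_counts = {e.window_pos: 0 for e in spec.donor_edits}
    for w in intact_windows:
        hit_all = True
        for e in spec.donor_edits:
            if w[e.window_pos] == e.alt_base:
                per_pos_counts[e.window_pos] += 1
            else:
                hit_all = False
        n_all += hit_all
    nan = float("nan")
    freq = n_all / n_analyzed if n_analyzed else nan
    freq_intact = n_all / len(intact_windows) if intact_windows else nan
    per_pos = {
        p: (c / n_analyzed if n_analyzed else nan)
        for p, c in per_pos_counts.items()
    }
    return freq, freq_intact, per_pos


def quantify_pool(
    reads: Iterable[ReadRecord],
    spec: AmpliconSpec,
    max_mismatch: int = 1,
    try_rc: bool = True,
    min_mean_q: float | None = None,
) -> EditingSummary:
    """Classify a read pool and summarise editing outcomes.

    Every read lands in exactly one category (excluded / indel / intact).
    Indel, insertion, deletion and programmed-edit frequencies are
    fractions of analyzed reads; the base-frequency matrix is computed
    over intact reads only. With zero analyzed reads all frequencies are
    NaN and a warning is issued.
    """
    n_total = n_excluded = n_ins = n_del = 0
    intact_windows: list[str] = []
    for cls in classify_reads(reads, spec, max_mismatch, try_rc, min_mean_q):
        n_total += 1
        if cls.category is Category.EXCLUDED:
            n_excluded += 1
        elif cls.category is Category.INDEL:
            if cls.length_delta > 0:
                n_ins += 1
            else:
                n_del += 1
        else:
            intact_windows.append(cls.observed_window)
    n_indel = n_ins + n_del
    n_intact = len(intact_windows)
    n_analyzed = n_indel + n_intact
    nan = float("nan")
    if n_analyzed == 0:
        if n_total:
            warnings.warn(
                "no read passed flank matching; frequencies are undefined",
                stacklevel=2,
            )
        indel_f = ins_f = del_f = nan
    else:
        indel_f = n_indel / n_analyzed
        ins_f = n_ins / n_analyzed
        del_f = n_del / n_analyzed
    base_freq = base_frequency_matrix(intact_windows, spec.window_ref)
    if spec.donor_edits:
        pe, pe_intact, per_pos = programmed_edit_frequency(
            intact_windows, n_analyzed, spec
        )
    else:
        pe, pe_intact, per_pos = nan, nan, {}
    return EditingSummary(
        n_total=n_total,
        n_excluded=n_excluded,
        n_indel=n_indel,
        n_insertion=n_ins,
        n_deletion=n_del,
        n_intact=n_intact,
        indel_freq=indel_f,
        insertion_freq=ins_f,
        deletion_freq=del_f,
        base_freq=base_freq,
        programmed_edit_freq=pe,
        programmed_edit_freq_intact=pe_intact,
        per_position_edit_freq=per_pos,
        window_ref=spec.window_ref,
    )
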