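"""Shared fixtures: a small toy amplicon, the bundled TIE2 fixture, and an
independent brute-force flank-placement oracle used to cross-check the
scanning implementation."""

from __future__ import annotations

import numpy as np
import pytest

from ampliquant import AmpliconSpec, DonorEdit, revcomp
from ampliquant.tie2 import tie2_l914f_spec

LEFT = "ACGTACCTGA"
WINDOW = "TTGCAGGA"
RIGHT = "CCTAGGATCA"


@pytest.fixture(scope="session")
def toy_spec() -> AmpliconSpec:
    """Small amplicon: 10-bp flanks around an 8-bp window, one donor edit."""
    return AmpliconSpec(
        amplicon_id="toy",
        amplicon_seq="GG" + LEFT + WINDOW + RIGHT + "TT",
        left_flank=LEFT,
        right_flank=RIGHT,
        donor_edits=(DonorEdit(2, "G", "A"),),
    )


@pytest.fixture(scope="session")
def tie2_spec() -> AmpliconSpec:
    return tie2_l914f_spec()


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b, strict=True))


def brute_force_find_flanks(seq, spec, max_mismatch, try_rc=True):
    """Exhaustive enumeration of all (left, right, orientation) placements.

    Returns (left_start, right_start, left_mm, right_mm, orientation) or
    None, applying the published selection rule: minimal total mismatches,
    ties broken by orientation (forward first), then leftmost left start,
    then leftmost right start.
    """
    seq = seq.upper()

    def best_in(s):
        k1, k2 = len(spec.left_flank), len(spec.right_flank)
        best = None
        for i in range(len(s) - k1 + 1):
            ml = hamming(s[i : i + k1], spec.left_flank)
            if ml > max_mismatch:
                continue
            for j in range(i + k1, len(s) - k2 + 1):
                mr = hamming(s[j : j + k2], spec.right_flank)
                if mr > max_mismatch:
                    continue
                if best is None or ml + mr < best[2] + best[3]:
                    best = (i, j, ml, mr)
        return best

    fwd = best_in(seq)
    rc = best_in(revcomp(seq)) if try_rc else None
    if fwd is None and rc is None:
        return None
    if rc is None or (fwd is not None and fwd[2] + fwd[3] <= rc[2] + rc[3]):
        return (*fwd, "forward")
    return (*rc, "reverse_complement")


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def plant_mismatches(rng: np.random.Generator, seq: str, k: int) -> str:
    """Substitute k distinct positions of seq with a different base."""
    s = list(seq)
    for pos in rng.choice(len(s), size=k, replace=False):
        s[pos] = rng.choice([b for b in "ACGT" if b != s[pos]])
    return "".join(s)
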