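"""Seeded simulation of amplicon read pools with known editing composition.

The generator emulates deep sequencing of a short PCR product from an
edited cell pool: each read is a full-length copy of the amplicon whose
editing window is replaced by the window of a randomly drawn allele
(wild-type, precise edit, or a programmed indel), then perturbed by
i.i.d. per-base substitution errors. The allele of every read is recorded
in a truth table, so the quantifier can be validated by parameter
recovery. Identical spec + seed give byte-identical output.

Substitution errors only, by default: the classifier reads any window
length change as a biological indel, so indel-type sequencing errors are
a distinct (optional) stressor, off by default.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .amplicon import AmpliconSpec, ReadRecord

__all__ = [
    "AlleleKind",
    "IndelOp",
    "AlleleSpec",
    "PoolSpec",
    "apply_errors",
    "simulate_pool",
    "enriched_pool_spec",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class AlleleKind(str, enum.Enum):
    WT = "WT"
    HDR = "HDR"
    INDEL = "INDEL"


@dataclass(frozen=True)
class IndelOp:
    """An indel applied to the reference window.

    ``delta`` < 0 deletes ``|delta|`` bases starting at ``position``;
    ``delta`` > 0 inserts ``inserted_seq`` (length ``delta``) before
    ``position``.
    """

    position: int
    delta: int
    inserted_seq: str = ""

    def __post_init__(self) -> None:
        if self.delta == 0:
            raise ValueError("an indel must change the window length")
        if self.delta > 0 and len(self.inserted_seq) != self.delta:
            raise ValueError("inserted_seq length must equal delta for insertions")

    def apply(self, window_ref: str) -> str:
        if self.position < 0 or self.position > len(window_ref):
            raise ValueError("indel position outside the window")
        if self.delta < 0:
            if self.position - self.delta > len(window_ref):
                raise ValueError("deletion extends past the window end")
            return window_ref[: self.position] + window_ref[self.position - self.delta :]
        return (
            window_ref[: self.position]
            + self.inserted_seq
            + window_ref[self.position :]
        )


@dataclass(frozen=True)
class AlleleSpec:
    """One allele class in the simulated pool, with its sampling proportion."""

    label: str
    kind: AlleleKind
    proportion: float
    window_seq: str | None = None  # explicit window (WT/HDR); derived if None
    indel_op: IndelOp | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.proportion <= 1:
            raise ValueError(f"allele {self.label}: proportion outside [0, 1]")
        if self.kind is AlleleKind.INDEL and self.indel_op is None:
            raise ValueError(f"allele {self.label}: INDEL allele needs an indel_op")

    def window(self, spec: AmpliconSpec) -> str:
        if self.window_seq is not None:
            return self.window_seq
        if self.kind is AlleleKind.WT:
            return spec.window_ref
        if self.kind is AlleleKind.HDR:
            return spec.hdr_window
        return self.indel_op.apply(spec.window_ref)


@dataclass(frozen=True)
class PoolSpec:
    """Complete recipe for a simulated read pool.

    Parameters
    ----------
    amplicon : AmpliconSpec
    alleles : alleles with proportions summing to 1
    n_reads : pool size
    error_rate : per-base substitution probability (i.i.d.)
    seed : RNG seed; same spec + seed reproduces the pool byte for byte
    quality : constant Phred score written for every base (default 30)
    indel_error_rate : optional per-read probability of one spurious 1-bp
        sequencing indel at a uniform position — a stress test for
        length-based classification, off by default
    """

    amplicon: AmpliconSpec
    alleles: tuple[AlleleSpec, ...]
    n_reads: int
    error_rate: float = 0.0
    seed: int = 0
    quality: int = 30
    indel_error_rate: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(self.alleles))
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        total = sum(a.proportion for a in self.alleles)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele proportions sum to {total}, expected 1")

    def to_dict(self) -> dict:
        """JSON-serialisable echo of the recipe (for run provenance)."""
        return {
            "amplicon_id": self.amplicon.amplicon_id,
            "alleles": [
                {
                    "label": a.label,
                    "kind": a.kind.value,
                    "proportion": a.proportion,
                    "window_seq": a.window(self.amplicon),
                }
                for a in self.alleles
            ],
            "n_reads": self.n_reads,
            "error_rate": self.error_rate,
            "seed": self.seed,
            "quality": self.quality,
            "indel_error_rate": self.indel_error_rate,
        }


def apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability ``error_rate``.

    A substituted base is drawn uniformly from the three alternatives;
    length is preserved.
    """
    if not 0 <= error_rate <= 1:
        raise ValueError("error_rate must be in [0, 1]")
    if error_rate == 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < error_rate)
    if hit.size:
        # shift by 1..3 within ACGT guarantees a different base
        idx = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(idx + rng.integers(1, 4, hit.size)) % 4]
    return arr.tobytes().decode("ascii")


def _spurious_indel(seq: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(0, len(seq)))
    if rng.random() < 0.5 and len(seq) > 1:
        return seq[:pos] + seq[pos + 1 :]
    base = chr(_BASES[int(rng.integers(0, 4))])
    return seq[:pos] + base + seq[pos:]


def simulate_pool(pool: PoolSpec) -> tuple[list[ReadRecord], list[tuple[str, str]]]:
    """Draw a read pool from a PoolSpec.

    Returns ``(reads, truth)`` where ``truth`` pairs each read id with the
    label of the allele it was drawn from.
    """
    rng = np.random.default_rng(pool.seed)
    amp = pool.amplicon
    lstart = amp.amplicon_seq.index(amp.left_flank)
    wstart = lstart + len(amp.left_flank)
    wend = wstart + len(amp.window_ref)
    prefix = amp.amplicon_seq[:wstart]
    suffix = amp.amplicon_seq[wend:]
    templates = [prefix + a.window(amp) + suffix for a in pool.alleles]
    labels = [a.label for a in pool.alleles]
    probs = np.asarray([a.proportion for a in pool.alleles], dtype=float)
    draws = rng.choice(len(pool.alleles), size=pool.n_reads, p=probs / probs.sum())
    reads: list[ReadRecord] = []
    truth: list[tuple[str, str]] = []
    width = len(str(pool.n_reads))
    for i, a_idx in enumerate(draws):
        seq = apply_errors(templates[a_idx], pool.error_rate, rng)
        if pool.indel_error_rate and rng.random() < pool.indel_error_rate:
            seq = _spurious_indel(seq, rng)
        read_id = f"sim_{i:0{width}d}_{labels[a_idx]}"
        reads.append(
            ReadRecord(read_id, seq, qual=(pool.quality,) * len(seq))
        )
        truth.append((read_id, labels[a_idx]))
    return reads, truth


def enriched_pool_spec(
    amplicon: AmpliconSpec,
    n_reads: int = 20_000,
    hdr: float = 0.985,
    indel: float = 0.010,
    wt: float = 0.005,
    error_rate: float = 0.001,
    seed: int = 1,
    indel_delta: int = -4,
) -> PoolSpec:
    """PoolSpec emulating a selection-enriched knock-in pool.

    Defaults mirror a pool dominated by the precise edit (98.5%) with a
    small indel class (a 4-bp deletion) and residual wild type, read at a
    typical amplicon-seq substitution error rate.
    """
    op = IndelOp(position=len(amplicon.window_ref) // 2, delta=indel_delta,
                 inserted_seq="" if indel_delta < 0 else "A" * indel_delta)
    return PoolSpec(
        amplicon=amplicon,
        alleles=(
            AlleleSpec("HDR", AlleleKind.HDR, hdr),
            AlleleSpec("INDEL", AlleleKind.INDEL, indel, indel_op=op),
            AlleleSpec("WT", AlleleKind.WT, wt),
        ),
        n_reads=n_reads,
        error_rate=error_rate,
        seed=seed,
    )
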