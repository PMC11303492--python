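"""File I/O: FASTQ/FASTA reading and writing, TOML configuration, and
summary serialisation.

FASTQ and FASTA parsing is delegated to Biopython; this module adds gzip
transparency, validation with useful error messages, and the round-trip
contracts the pipeline relies on (a written summary re-reads to identical
counts; a simulated pool re-reads to identical records).
"""

from __future__ import annotations

import gzip
import json
import math
import tomllib
import warnings
from collections.abc import Iterable, Iterator
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .amplicon import BASE_COLUMNS, AmpliconSpec, DonorEdit, EditingSummary, ReadRecord
from .simulate import AlleleKind, AlleleSpec, IndelOp, PoolSpec

__all__ = [
    "ParseError",
    "ConfigError",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "load_amplicon_spec",
    "load_pool_spec",
    "summary_to_dict",
    "write_summary",
    "read_summary",
    "write_truth_table",
]


class ParseError(ValueError):
    """A sequence file could not be parsed."""


class ConfigError(ValueError):
    """A configuration file is missing or inconsistent."""


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream FASTQ records (plain or gzip), preserving order.

    Raises ParseError on malformed records (truncation, length mismatch
    between sequence and quality line).
    """
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                yield ReadRecord(
                    rec.id,
                    str(rec.seq).upper(),
                    tuple(rec.letter_annotations["phred_quality"]),
                )
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    """Write reads as Sanger FASTQ (gzip if the path ends in .gz)."""
    n = 0
    with _open_text(path, "wt") as fh:
        for r in reads:
            rec = SeqRecord(Seq(r.seq), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = list(
                r.qual if r.qual else (30,) * len(r.seq)
            )
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """All FASTA records as (id, uppercased sequence) pairs.

    Duplicate ids raise ParseError; a file with sequence data but no
    header is rejected by the underlying parser.
    """
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise ParseError(f"{path}: not FASTA (first character {first!r})")
        fh.seek(0)
        try:
            for rec in SeqIO.parse(fh, "fasta"):
                if rec.id in seen:
                    raise ParseError(f"{path}: duplicate FASTA id {rec.id!r}")
                seen.add(rec.id)
                out.append((rec.id, str(rec.seq).upper()))
        except ParseError:
            raise
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return out


def _parse_donor_edit(text: str) -> DonorEdit:
    """Parse a ``pos:ref>alt`` donor-edit string (0-based position)."""
    try:
        pos_s, change = text.split(":")
        ref, alt = change.split(">")
        return DonorEdit(int(pos_s), ref.strip().upper(), alt.strip().upper())
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"malformed donor edit {text!r}; expected pos:ref>alt") from exc


def _amplicon_from_mapping(
    cfg: dict, fasta_path: str | Path | None, base_dir: Path
) -> AmpliconSpec:
    for key in ("amplicon_id", "left_flank", "right_flank"):
        if key not in cfg:
            raise ConfigError(f"amplicon config is missing {key!r}")
    if "seq" in cfg:
        seq = cfg["seq"]
    else:
        fasta = fasta_path or cfg.get("fasta")
        if fasta is None:
            raise ConfigError("amplicon config needs 'seq' or a FASTA reference")
        fasta = Path(fasta)
        if not fasta.is_absolute():
            fasta = base_dir / fasta
        records = dict(read_fasta(fasta))
        if cfg["amplicon_id"] in records:
            seq = records[cfg["amplicon_id"]]
        elif len(records) == 1:
            seq = next(iter(records.values()))
        else:
            raise ConfigError(
                f"FASTA {fasta} has no record {cfg['amplicon_id']!r} "
                "and is not single-record"
            )
    try:
        spec = AmpliconSpec(
            amplicon_id=cfg["amplicon_id"],
            amplicon_seq=seq,
            left_flank=cfg["left_flank"],
            right_flank=cfg["right_flank"],
            donor_edits=tuple(_parse_donor_edit(e) for e in cfg.get("donor_edits", ())),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    if "window" in cfg and cfg["window"].upper() != spec.window_ref:
        raise ConfigError(
            f"configured window {cfg['window']!r} does not match the sequence "
            f"between the flanks ({spec.window_ref!r})"
        )
    return spec


def load_amplicon_spec(
    toml_path: str | Path, fasta_path: str | Path | None = None
) -> AmpliconSpec:
    """Load an AmpliconSpec from a TOML config (+ optional FASTA reference).

    The TOML holds ``amplicon_id``, ``left_flank``, ``right_flank``,
    optionally ``window`` (cross-checked), ``donor_edits`` as a list of
    ``"pos:ref>alt"`` strings, and either ``seq`` inline or ``fasta``
    pointing at the reference amplicon.
    """
    toml_path = Path(toml_path)
    with open(toml_path, "rb") as fh:
        cfg = tomllib.load(fh)
    cfg = cfg.get("amplicon", cfg)
    return _amplicon_from_mapping(cfg, fasta_path, toml_path.parent)


def load_pool_spec(
    toml_path: str | Path, seed: int | None = None
) -> PoolSpec:
    """Load a simulation PoolSpec from TOML.

    Layout: an ``[amplicon]`` table (as for :func:`load_amplicon_spec`),
    ``[[alleles]]`` entries (label, kind, proportion; INDEL alleles add
    position/delta/inserted_seq), and a ``[pool]`` table (n_reads,
    error_rate, seed, quality, indel_error_rate). ``seed`` overrides the
    file's seed when given.
    """
    toml_path = Path(toml_path)
    with open(toml_path, "rb") as fh:
        cfg = tomllib.load(fh)
    if "amplicon" not in cfg or "alleles" not in cfg:
        raise ConfigError(f"{toml_path}: pool config needs [amplicon] and [[alleles]]")
    amplicon = _amplicon_from_mapping(cfg["amplicon"], None, toml_path.parent)
    alleles = []
    for a in cfg["alleles"]:
        try:
            kind = AlleleKind(a["kind"])
            op = None
            if kind is AlleleKind.INDEL:
                op = IndelOp(
                    position=a["position"],
                    delta=a["delta"],
                    inserted_seq=a.get("inserted_seq", ""),
                )
            alleles.append(
                AlleleSpec(
                    label=a["label"],
                    kind=kind,
                    proportion=a["proportion"],
                    window_seq=a.get("window_seq"),
                    indel_op=op,
                )
            )
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"{toml_path}: bad allele entry {a!r}: {exc}") from exc
    pool = cfg.get("pool", {})
    try:
        return PoolSpec(
            amplicon=amplicon,
            alleles=tuple(alleles),
            n_reads=pool.get("n_reads", 10_000),
            error_rate=pool.get("error_rate", 0.0),
            seed=seed if seed is not None else pool.get("seed", 0),
            quality=pool.get("quality", 30),
            indel_error_rate=pool.get("indel_error_rate", 0.0),
        )
    except ValueError as exc:
        raise ConfigError(f"{toml_path}: {exc}") from exc


def _nan_to_none(x: float) -> float | None:
    return None if isinstance(x, float) and math.isnan(x) else x


def summary_to_dict(summary: EditingSummary) -> dict:
    """JSON-serialisable dict of an EditingSummary (NaN encoded as null)."""
    has_nan = math.isnan(summary.indel_freq) or math.isnan(
        summary.programmed_edit_freq
    )
    return {
        "n_total": summary.n_total,
        "n_excluded": summary.n_excluded,
        "n_analyzed": summary.n_analyzed,
        "n_indel": summary.n_indel,
        "n_insertion": summary.n_insertion,
        "n_deletion": summary.n_deletion,
        "n_intact": summary.n_intact,
        "indel_freq": _nan_to_none(summary.indel_freq),
        "insertion_freq": _nan_to_none(summary.insertion_freq),
        "deletion_freq": _nan_to_none(summary.deletion_freq),
        "programmed_edit_freq": _nan_to_none(summary.programmed_edit_freq),
        "programmed_edit_freq_intact": _nan_to_none(
            summary.programmed_edit_freq_intact
        ),
        "per_position_edit_freq": {
            str(k): _nan_to_none(v) for k, v in summary.per_position_edit_freq.items()
        },
        "window_ref": summary.window_ref,
        "undefined_frequencies": has_nan,
        "base_freq": [list(map(float, row)) for row in summary.base_freq],
    }


def write_summary(
    summary: EditingSummary,
    outdir: str | Path,
    metadata: dict | None = None,
) -> dict[str, Path]:
    """Write summary.json, base_freq.tsv and run_metadata.json under ``outdir``.

    The TSV has one row per window position with columns (position, A, C,
    G, T, N). Re-reading the JSON reproduces all counts exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    d = summary_to_dict(summary)
    if d["undefined_frequencies"]:
        warnings.warn("summary has undefined frequencies (no analyzed reads)",
                      stacklevel=2)
    json_path = outdir / "summary.json"
    json_path.write_text(json.dumps(d, indent=2) + "\n")
    tsv_path = outdir / "base_freq.tsv"
    with open(tsv_path, "w") as fh:
        fh.write("position\t" + "\t".join(BASE_COLUMNS) + "\n")
        for i, row in enumerate(summary.base_freq):
            fh.write(f"{i}\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
    paths = {"summary": json_path, "base_freq": tsv_path}
    if metadata is not None:
        meta_path = outdir / "run_metadata.json"
        meta_path.write_text(json.dumps(metadata, indent=2, default=str) + "\n")
        paths["metadata"] = meta_path
    return paths


def read_summary(path: str | Path) -> dict:
    """Read back a summary.json (null frequencies restored to NaN)."""
    with open(path) as fh:
        d = json.load(fh)
    for key in (
        "indel_freq",
        "insertion_freq",
        "deletion_freq",
        "programmed_edit_freq",
        "programmed_edit_freq_intact",
    ):
        if d.get(key) is None:
            d[key] = float("nan")
    d["base_freq"] = np.asarray(d["base_freq"], dtype=float)
    return d


def write_truth_table(truth: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write the simulator truth table as TSV (read_id, allele)."""
    with open(path, "w") as fh:
        fh.write("read_id\tallele\n")
        for read_id, label in truth:
            fh.write(f"{read_id}\t{label}\n")
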