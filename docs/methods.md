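# Methods

## Flank-anchored editing-window quantification

### Model

An amplicon-seq run reads out, for one PCR-amplified locus, a pool of
alleles produced by CRISPR editing: the programmed knock-in (HDR), a
spectrum of NHEJ indels, and residual wild type. The classifier reduces
each read to the *editing window* — the amplicon segment between two
fixed 10-bp flank anchors — and calls outcomes from that window alone:

1. **Anchoring.** Both flanks must be located in the read, each within a
   per-flank Hamming-distance tolerance (`max_mismatch`, default 1). All
   placements are scanned (a vectorised sliding-window comparison against
   both the read and its reverse complement); the valid placement with
   the fewest total mismatches wins, ties resolved to the leftmost left
   anchor, then the leftmost right anchor, then to the forward
   orientation. Reads without a valid placement are excluded — they
   contribute to `n_total` but to no frequency denominator.
2. **Indel call by window length.** A window whose length deviates from
   the reference window length is an insertion (longer) or deletion
   (shorter). "Exactly matching the reference" is interpreted as exact
   *length* match, not exact sequence match: substitutions inside the
   window must remain visible as base edits, otherwise every edited read
   would be discarded from the base-frequency tally. This is the one
   deliberate interpretive choice in the classifier and it is load-bearing
   for the knock-in readout.
3. **Base edits.** Per-locus base frequencies over {A, C, G, T, N} are
   computed across intact windows only; rows sum to 1. N (and any
   non-ACGT character) occupies its own column rather than being dropped,
   so the row normalisation is exact.
4. **Programmed-edit (knock-in) frequency.** The fraction of *analyzed*
   reads that are intact and carry the donor base at every programmed
   position. The analyzed-read denominator keeps this commensurable with
   the indel frequency (`indel_freq + n_intact/n_analyzed = 1`); the
   intact-read denominator is also reported
   (`programmed_edit_freq_intact`), as are per-position edit frequencies.

### Assumptions and limitations

- Both flanks must sit on the same read; amplicons longer than the read
  length need externally merged pairs. Unmerged mates are processed
  independently.
- Read-level frequencies proxy allele/cell-level editing rates; no ploidy
  correction or UMI deduplication is attempted.
- A Hamming (substitution-only) flank match: an indel *inside a flank*
  shifts the anchor and usually excludes the read rather than mis-calling
  it. Large deletions that remove a flank likewise exclude the read, so
  indel frequencies are conditional on both anchors surviving.
- Quality scores are parsed and carried but unused by default; an
  optional mean-quality filter (`min_mean_q`) exists and is off by
  default. Filtered reads count as excluded.
- Coordinates are 0-based, intervals half-open; window positions are
  relative to the reference window.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `max_mismatch` | 1 | per-flank Hamming tolerance (mismatches, incl. N) |
| flank length | 10 bp | set by the amplicon spec; anchors must be unique in the reference |
| `try_rc` | on | search the reverse complement of each read (`--no-rc` disables) |
| `min_mean_q` | off | exclude reads below this mean Phred quality |

## Read-pool simulator

The simulator emulates sequencing of a short PCR product from an edited
pool: each read is a full-length amplicon copy whose window is replaced
by a drawn allele's window (multinomial over allele proportions, seeded
`numpy` generator), then perturbed by i.i.d. per-base substitutions at
`error_rate`, each substitution uniform over the three alternative bases.
Qualities are constant Q30. Identical spec + seed reproduce the FASTQ
byte for byte, and a truth table (read id → allele label) accompanies
every pool.

What it deliberately does **not** model: PCR bias and chimeras,
duplicates, platform quality profiles, position-dependent error rates,
and — by default — indel-type sequencing errors, since the classifier
reads any length change as a biological indel. An optional per-read
`indel_error_rate` injects one spurious 1-bp indel to stress-test that
failure mode; it is off by default. Passing parameter-recovery tests on
these pools therefore demonstrates correctness of the classifier's logic
and estimator, not robustness to every artefact of real sequencing runs.

The default "enriched pool" recipe (98.5% HDR, 1.0% indel as a 4-bp
deletion, 0.5% wild type; 20,000 reads; 0.001 substitutions/base)
represents a co-selection-enriched knock-in pool; the true indel spectrum
of such pools is not published, so the single mid-window deletion is an
arbitrary, labelled choice. Validation problem sizes used by the test
suite — 1,000 reads for the brute-force cross-check, 20 replicates of
5,000 reads for parameter recovery, 20,000 reads for the headline pool —
were chosen to give comfortable binomial resolution at each check.

## TIE2 L914F fixture

The packaged fixture frames a 101-bp amplicon with the TIE2 genotyping
primers (F `CAGGGCCACTGATGAGTCGAT`, R `TCGGCAGCGAAGTGAAGGAG`). The donor
edit is the canonical venous-malformation variant c.2740C>T (codon
CTT→TTT, Leu914Phe), a single C>T substitution at window position 9. The
sequence between the primers, including both anchors and the 20-bp
window, is synthetic — chosen to satisfy anchor uniqueness — so the
fixture supports simulation and demonstration, not genotyping of real
TEK amplicons.

## Companion assay metrics

- **%phospho (multiplex)** `= 100·2·P/(P+T)`; the factor 2 reflects that
  the "total" channel of phospho/total electrochemiluminescence kits also
  captures the phosphorylated species, so the range is [0, 200].
- **%phospho (western blot)** `= 100·P/T`.
- **Orientation-in-flow fraction**: cell long axes are undirected, so
  angles are folded modulo 180° into (−90°, 90°] before counting the
  fraction within ±tolerance (default 5°) of the flow axis (0°). Folding
  before thresholding is a documented convention choice; binned folded
  distributions (default 10° bins) are emitted for orientation curves.
- **AUC**: trapezoidal rule over the full time range — the default of
  common curve-analysis software; time must be strictly increasing.
- **Vessel diameters**: per-explant mean and median of traced segment
  diameters (the explant is the unit of analysis when comparing groups)
  plus a pooled fixed-width histogram (default 5 µm bins).

Degenerate inputs signal errors rather than returning silent zeros: zero
phospho denominators, empty angle lists, non-increasing time vectors and
non-positive diameters all raise.

## Numerical and I/O choices

- Frequencies with a zero denominator (no analyzed reads) are NaN, with a
  warning; JSON serialises them as `null` plus an
  `undefined_frequencies` flag.
- Base-frequency rows are exact rational counts divided by `n_intact`;
  the row-sum invariant is enforced to 1e-12 in tests.
- FASTQ/FASTA parsing and writing go through Biopython with gzip
  transparency; malformed records surface as parse errors (CLI exit code
  3), configuration problems as exit code 2.
- All randomness flows from a single integer seed per pool through
  `numpy.random.default_rng`.
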