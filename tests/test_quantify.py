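"""Read classification and pool-level summaries against hand-counted oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampliquant import (
    Category,
    ReadRecord,
    base_frequency_matrix,
    classify_read,
    programmed_edit_frequency,
    quantify_pool,
    revcomp,
)
from ampliquant.amplicon import BASE_COLUMNS
from conftest import random_dna


def _read(spec, window, read_id="r"):
    return ReadRecord(read_id, spec.left_flank + window + spec.right_flank)


class TestClassifyRead:
    def test_deletion_signed_delta(self, toy_spec):
        cls = classify_read(_read(toy_spec, toy_spec.window_ref[:-3]), toy_spec)
        assert cls.category is Category.INDEL
        assert cls.length_delta == -3

    def test_insertion_signed_delta(self, toy_spec):
        w = toy_spec.window_ref[:4] + "AA" + toy_spec.window_ref[4:]
        cls = classify_read(_read(toy_spec, w), toy_spec)
        assert cls.category is Category.INDEL
        assert cls.length_delta == 2

    def test_reference_window_intact(self, toy_spec):
        cls = classify_read(_read(toy_spec, toy_spec.window_ref), toy_spec)
        assert cls.category is Category.INTACT
        assert cls.observed_window == toy_spec.window_ref

    def test_substitution_at_donor_position_is_intact_not_indel(self, toy_spec):
        # length is the indel criterion: a base edit keeps the read intact
        cls = classify_read(_read(toy_spec, toy_spec.hdr_window), toy_spec)
        assert cls.category is Category.INTACT
        assert cls.observed_window == toy_spec.hdr_window

    def test_unmatchable_read_excluded(self, toy_spec):
        cls = classify_read(ReadRecord("r", "A" * 40), toy_spec)
        assert cls.category is Category.EXCLUDED
        assert cls.observed_window is None

    def test_rc_read_recovers_forward_window(self, toy_spec):
        fwd = _read(toy_spec, toy_spec.hdr_window)
        rc = ReadRecord("r", revcomp(fwd.seq))
        assert classify_read(rc, toy_spec).observed_window == toy_spec.hdr_window


class TestQuantifyPoolToy:
    """Hand-counted 10-read pool: 8 edited intact, 1 deletion, 1 unmatchable."""

    @pytest.fixture()
    def summary(self, toy_spec):
        reads = [_read(toy_spec, toy_spec.hdr_window, f"hdr{i}") for i in range(8)]
        reads.append(_read(toy_spec, toy_spec.window_ref[2:], "del2"))
        bad_left = "TTTTTTTTTT"
        reads.append(
            ReadRecord("nomatch", bad_left + toy_spec.window_ref + toy_spec.right_flank[:5] + "T" * 5)
        )
        return quantify_pool(reads, toy_spec, max_mismatch=1)

    def test_counts(self, summary):
        assert (summary.n_total, summary.n_excluded, summary.n_analyzed) == (10, 1, 9)
        assert (summary.n_indel, summary.n_deletion, summary.n_insertion) == (1, 1, 0)
        assert summary.n_intact == 8

    def test_frequencies_hand_counted(self, summary):
        assert summary.indel_freq == pytest.approx(1 / 9)
        assert summary.deletion_freq == pytest.approx(1 / 9)
        assert summary.insertion_freq == 0.0
        assert summary.programmed_edit_freq == pytest.approx(8 / 9)
        assert summary.programmed_edit_freq_intact == 1.0

    def test_base_freq_one_hot_on_edited_base(self, summary, toy_spec):
        # all 8 intact reads carry the donor base at position 2
        row = summary.base_freq[2]
        assert row[BASE_COLUMNS.index("A")] == 1.0
        np.testing.assert_allclose(summary.base_freq.sum(axis=1), 1.0, atol=1e-12)


class TestQuantifyPoolEdges:
    def test_empty_pool_nan_frequencies(self, toy_spec):
        s = quantify_pool([], toy_spec)
        assert s.n_total == 0
        assert math.isnan(s.indel_freq) and math.isnan(s.programmed_edit_freq)

    def test_all_excluded_warns_not_raises(self, toy_spec):
        with pytest.warns(UserWarning, match="no read passed"):
            s = quantify_pool([ReadRecord("r", "A" * 40)], toy_spec)
        assert (s.n_total, s.n_excluded) == (1, 1)
        assert math.isnan(s.indel_freq)

    def test_pure_wildtype_pool(self, toy_spec):
        reads = [_read(toy_spec, toy_spec.window_ref, f"wt{i}") for i in range(5)]
        s = quantify_pool(reads, toy_spec)
        assert s.programmed_edit_freq == 0.0
        assert s.indel_freq == 0.0
        for i, base in enumerate(toy_spec.window_ref):
            assert s.base_freq[i, BASE_COLUMNS.index(base)] == 1.0

    def test_min_mean_q_filter_excludes(self, toy_spec):
        good = ReadRecord("g", _read(toy_spec, toy_spec.window_ref).seq,
                          qual=(30,) * 28)
        bad = ReadRecord("b", _read(toy_spec, toy_spec.window_ref).seq,
                         qual=(10,) * 28)
        s = quantify_pool([good, bad], toy_spec, min_mean_q=20)
        assert (s.n_total, s.n_excluded, s.n_intact) == (2, 1, 1)


class TestBaseFrequencyMatrix:
    def test_reference_only_one_hot(self, toy_spec):
        m = base_frequency_matrix([toy_spec.window_ref], toy_spec.window_ref)
        for i, b in enumerate(toy_spec.window_ref):
            assert m[i, BASE_COLUMNS.index(b)] == 1.0

    def test_hand_counted_mixture(self):
        m = base_frequency_matrix(["ACG", "ACG", "ACT"], "ACG")
        assert m[2, BASE_COLUMNS.index("G")] == pytest.approx(2 / 3)
        assert m[2, BASE_COLUMNS.index("T")] == pytest.approx(1 / 3)

    def test_n_gets_own_column_rows_normalised(self):
        m = base_frequency_matrix(["ANG", "ACG"], "ACG")
        assert m[1, BASE_COLUMNS.index("N")] == 0.5
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            base_frequency_matrix(["ACGT"], "ACG")

    def test_empty_windows_all_zero(self):
        assert not base_frequency_matrix([], "ACG").any()


class TestProgrammedEditFrequency:
    def test_all_intact_edited(self, toy_spec):
        windows = [toy_spec.hdr_window] * 4
        freq, freq_intact, per_pos = programmed_edit_frequency(windows, 5, toy_spec)
        assert freq == pytest.approx(4 / 5)
        assert freq_intact == 1.0
        assert per_pos == {2: pytest.approx(4 / 5)}

    def test_partial_multi_position_edits(self, toy_spec):
        # a second donor edit at window position 5 (G>T in TTGCAGGA)
        from ampliquant import AmpliconSpec, DonorEdit
        spec2 = AmpliconSpec(
            toy_spec.amplicon_id, toy_spec.amplicon_seq,
            toy_spec.left_flank, toy_spec.right_flank,
            donor_edits=(DonorEdit(2, "G", "A"), DonorEdit(5, "G", "T")),
        )
        both = spec2.hdr_window
        only_first = toy_spec.hdr_window  # edit at 2 only
        freq, _, per_pos = programmed_edit_frequency([both, only_first], 2, spec2)
        assert freq == pytest.approx(1 / 2)  # only the double-edited window counts
        assert per_pos[2] == pytest.approx(1.0)
        assert per_pos[5] == pytest.approx(1 / 2)

    def test_no_donor_edits_is_config_error(self, toy_spec):
        from ampliquant import AmpliconSpec
        bare = AmpliconSpec(toy_spec.amplicon_id, toy_spec.amplicon_seq,
                            toy_spec.left_flank, toy_spec.right_flank)
        with pytest.raises(ValueError, match="donor"):
            programmed_edit_frequency([], 0, bare)


def _random_pool(toy_spec, rng, n=30):
    """Reads of mixed provenance: clean, edited, indel, garbage, RC'd."""
    reads = []
    for i in range(n):
        kind = rng.integers(0, 4)
        if kind == 0:
            w = toy_spec.window_ref
        elif kind == 1:
            w = toy_spec.hdr_window
        elif kind == 2:
            cut = int(rng.integers(1, len(toy_spec.window_ref)))
            w = toy_spec.window_ref[cut:]
        else:
            reads.append(ReadRecord(f"g{i}", random_dna(rng, 40)))
            continue
        seq = toy_spec.left_flank + w + toy_spec.right_flank
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append(ReadRecord(f"r{i}", seq))
    return reads


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_partition_and_denominator_invariants(toy_spec, seed):
    """Every read lands in exactly one category; frequencies share one denominator."""
    rng = np.random.default_rng(seed)
    s = quantify_pool(_random_pool(toy_spec, rng), toy_spec)
    assert s.n_total == s.n_excluded + s.n_indel + s.n_intact
    assert s.n_analyzed == s.n_indel + s.n_intact
    if s.n_analyzed:
        assert s.indel_freq + s.n_intact / s.n_analyzed == pytest.approx(1.0)
        assert s.indel_freq == pytest.approx(s.insertion_freq + s.deletion_freq)
    if s.n_intact:
        np.testing.assert_allclose(s.base_freq.sum(axis=1), 1.0, atol=1e-12)


@settings(derandomize=True, max_examples=15, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_reverse_complement_invariance(toy_spec, seed):
    """Reverse-complementing every read leaves the summary unchanged."""
    rng = np.random.default_rng(seed)
    reads = _random_pool(toy_spec, rng)
    rc_reads = [ReadRecord(r.read_id, revcomp(r.seq)) for r in reads]
    a = quantify_pool(reads, toy_spec)
    b = quantify_pool(rc_reads, toy_spec)
    assert (a.n_excluded, a.n_indel, a.n_intact) == (b.n_excluded, b.n_indel, b.n_intact)
    assert a.programmed_edit_freq == b.programmed_edit_freq or (
        math.isnan(a.programmed_edit_freq) and math.isnan(b.programmed_edit_freq)
    )
    np.testing.assert_array_equal(a.base_freq, b.base_freq)


@settings(derandomize=True, max_examples=15, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_n_analyzed_monotone_in_tolerance(toy_spec, seed):
    rng = np.random.default_rng(seed)
    reads = [ReadRecord(f"r{i}", random_dna(rng, 45)) for i in range(20)]
    reads += _random_pool(toy_spec, rng, n=10)
    s0 = quantify_pool(reads, toy_spec, max_mismatch=0)
    s1 = quantify_pool(reads, toy_spec, max_mismatch=1)
    assert s0.n_analyzed <= s1.n_analyzed
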