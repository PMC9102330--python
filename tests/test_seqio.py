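"""FASTA / pattern-TSV round-trips, batch filtering, reverse complement."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nucpatterns as npx
from nucpatterns.seqio import FilterReport

dna = st.text(alphabet="ACGT", min_size=1, max_size=100)


def test_read_fasta_uppercases_and_keeps_order(tmp_path):
    f = tmp_path / "in.fa"
    f.write_text(">a\nacgt\n>b\nGGCC\n")
    batch = npx.read_fasta(f)
    assert batch.records == [("a", "ACGT"), ("b", "GGCC")]
    assert batch.length == 4


def test_read_fasta_record_without_sequence_errors(tmp_path):
    f = tmp_path / "in.fa"
    f.write_text(">a\n")
    with pytest.raises(ValueError, match="a"):
        npx.read_fasta(f)


def test_read_fasta_empty_file_errors(tmp_path):
    f = tmp_path / "in.fa"
    f.write_text("")
    with pytest.raises(ValueError):
        npx.read_fasta(f)


def test_fasta_round_trip_is_byte_stable(tmp_path):
    rng = np.random.default_rng(0)
    batch = npx.SequenceBatch(
        [(f"s{i}", "".join(rng.choice(list("ACGT"), size=150))) for i in range(5)]
    )
    p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
    npx.write_fasta(batch, p1)
    npx.write_fasta(npx.read_fasta(p1), p2)
    assert p1.read_bytes() == p2.read_bytes()


class TestFilterBatch:
    def test_drop_counts_and_removes_n_records(self):
        records = [("a", "ACGT"), ("b", "ACNT"), ("c", "GGGG")]
        out, rep = npx.filter_batch(npx.SequenceBatch(records), n_policy="drop")
        assert out.ids == ["a", "c"]
        assert rep == FilterReport(kept=2, dropped=1, dropped_ids=["b"])

    def test_clean_batch_untouched(self):
        batch = npx.SequenceBatch([("a", "ACGT"), ("b", "TTTT"), ("c", "GATC")])
        out, rep = npx.filter_batch(batch)
        assert (rep.kept, rep.dropped) == (3, 0)
        assert out.records == batch.records

    def test_error_policy_names_record(self):
        batch = npx.SequenceBatch([("ok", "ACGT"), ("badrec", "ANGT")])
        with pytest.raises(ValueError, match="badrec"):
            npx.filter_batch(batch, n_policy="error")

    def test_all_dropped_is_error(self):
        with pytest.raises(ValueError):
            npx.filter_batch(npx.SequenceBatch([("a", "NNNN")]))

    def test_require_equal_length(self):
        batch = npx.SequenceBatch([("a", "A" * 100), ("b", "C" * 101)])
        with pytest.raises(ValueError):
            npx.filter_batch(batch, require_equal_length=True)

    def test_kept_plus_dropped_is_total_and_idempotent(self):
        rng = np.random.default_rng(3)
        records = [
            (f"s{i}", "".join(rng.choice(list("ACGTN"), size=40, p=[0.23] * 4 + [0.08])))
            for i in range(50)
        ]
        batch = npx.SequenceBatch(records)
        out, rep = npx.filter_batch(batch)
        assert rep.kept + rep.dropped == len(batch)
        again, rep2 = npx.filter_batch(out)
        assert again.records == out.records and rep2.dropped == 0


@pytest.mark.parametrize("seq,expected", [("ACGT", "ACGT"), ("AAC", "GTT"), ("AATT", "AATT")])
def test_reverse_complement_examples(seq, expected):
    assert npx.reverse_complement(seq) == expected


def test_reverse_complement_rejects_non_acgt():
    with pytest.raises(ValueError):
        npx.reverse_complement("ACNT")


@given(dna)
def test_reverse_complement_is_involution(seq):
    assert npx.reverse_complement(npx.reverse_complement(seq)) == seq


class TestPatternTable:
    def test_round_trip_lossless(self, tmp_path):
        rng = np.random.default_rng(1)
        table = npx.PatternTable(
            np.arange(1, 140), rng.normal(size=139), {"class_code": "WW", "window": "146"}
        )
        path = tmp_path / "p.tsv"
        npx.write_pattern(table, path)
        back = npx.read_pattern(path)
        assert np.array_equal(back.positions, table.positions)
        assert np.array_equal(back.values, table.values)  # repr round-trip is exact
        assert back.metadata == table.metadata

    def test_round_trip_byte_stable(self, tmp_path):
        table = npx.PatternTable(np.arange(1, 10), np.linspace(0, 1, 9), {"k": "v"})
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        npx.write_pattern(table, p1)
        npx.write_pattern(npx.read_pattern(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_gap_in_positions_errors(self):
        with pytest.raises(ValueError):
            npx.PatternTable(np.array([1, 2, 4]), np.zeros(3))

    def test_non_finite_values_error(self):
        with pytest.raises(ValueError):
            npx.PatternTable(np.array([1, 2]), np.array([0.0, np.nan]))
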