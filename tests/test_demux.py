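"""Barcode matching, junction calling, demux round trips and filters."""

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bpmpra import (
    FilterConfig,
    SpliceModelParams,
    apply_filters,
    build_transcript_table,
    call_junction,
    generate_library,
    match_barcode,
    simulate_transcripts,
    truth_to_table,
)
from bpmpra.demux import build_barcode_index, isoform_references
from bpmpra.simulate import emit_reads, make_minigene, DEFAULT_SCAFFOLD


def _mutate_at(seq, i, to):
    assert seq[i] != to
    return seq[:i] + to + seq[i + 1 :]


@pytest.fixture(scope="module")
def index(small_library):
    return build_barcode_index(small_library)


class TestMatchBarcode:
    def test_exact_match(self, small_library, index):
        mg = small_library[3]
        assert match_barcode(mg.barcode + "ACGTACGTAC", index, 0) == mg.id

    def test_one_substitution_unique_neighbor(self, small_library, index):
        mg = small_library[5]
        r2 = _mutate_at(mg.barcode, 4, "A" if mg.barcode[4] != "A" else "C")
        assert match_barcode(r2, index, max_mismatch=1) == mg.id
        assert match_barcode(r2, index, max_mismatch=0) is None

    def test_equidistant_tie_unassigned(self):
        lib = generate_library(2, seed=61)
        bcs = ["A" * 20, "C" + "A" * 19]
        lib2 = [make_minigene(f"M{i}", bc, m.n25a, m.n25b, DEFAULT_SCAFFOLD)
                for i, (bc, m) in enumerate(zip(bcs, lib))]
        index = build_barcode_index(lib2)
        r2 = "G" + "A" * 19  # Hamming distance 1 from both barcodes
        assert all(sum(x != y for x, y in zip(r2, bc)) == 1 for bc in bcs)
        assert match_barcode(r2, index, max_mismatch=1) is None

    def test_short_read_unassigned(self, index):
        assert match_barcode("ACGT", index, 1) is None

    def test_duplicate_barcodes_fail_loudly(self, small_library):
        with pytest.raises(ValueError, match="duplicate"):
            build_barcode_index(list(small_library) + [small_library[0]])


@pytest.fixture(scope="module")
def minigene(small_library):
    return small_library[0]


class TestCallJunction:
    def _read(self, mg, acceptor_pos, read_len=50):
        iso = mg.full_seq[: mg.donor_pos] + mg.full_seq[acceptor_pos:]
        start = mg.donor_pos - read_len // 2
        return iso[start : start + read_len]

    def test_error_free_sa2_read(self, minigene):
        call = call_junction(self._read(minigene, minigene.sa2_pos), minigene)
        assert call == ("SA2", minigene.sa2_pos)

    def test_error_free_sa1_read(self, minigene):
        call = call_junction(self._read(minigene, minigene.sa1_pos), minigene)
        assert call == ("SA1", minigene.sa1_pos)

    def test_exon2_only_read_uncalled(self, minigene):
        r1 = minigene.full_seq[minigene.sa2_pos : minigene.sa2_pos + 40]
        assert call_junction(r1, minigene) is None

    def test_one_substitution_tolerated(self, minigene):
        r1 = self._read(minigene, minigene.sa1_pos)
        r1 = _mutate_at(r1, 10, "A" if r1[10] != "A" else "C")
        assert call_junction(r1, minigene) == ("SA1", minigene.sa1_pos)

    def test_insufficient_flank_uncalled(self, minigene):
        iso = minigene.full_seq[: minigene.donor_pos] + \
            minigene.full_seq[minigene.sa2_pos :]
        r1 = iso[minigene.donor_pos - 5 : minigene.donor_pos + 45]  # 5 nt flank
        assert call_junction(r1, minigene, min_flank=15) is None

    def test_references_cover_all_candidates(self, minigene):
        refs = isoform_references(minigene)
        labels = [r[0] for r in refs]
        assert labels.count("SA1") == 1 and labels.count("SA2") == 1


class TestRoundTrip:
    def test_zero_noise_recovers_truth(self, tmp_path):
        library = generate_library(100, seed=71)
        params = SpliceModelParams(lambda_minus1=0.4)
        truth = simulate_transcripts(library, "WT", params, 10, seed=72)
        emit_reads(truth, library, tmp_path / "r1.fq", tmp_path / "r2.fq",
                   tmp_path / "side.tsv", read_len=50, error_rate=0.0, seed=73)
        table, report = build_transcript_table(
            tmp_path / "r1.fq", tmp_path / "r2.fq", library, "WT")
        assert report["unassigned"] == report["uncalled"] == 0
        assert report["assigned"] == truth["count"].sum()
        want = truth_to_table(truth).sort_values(
            ["minigene_id", "acceptor_class", "acceptor_pos"]).reset_index(drop=True)
        got = table.sort_values(
            ["minigene_id", "acceptor_class", "acceptor_pos"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(got, want)

    def test_tally_conservation_with_errors(self, tmp_path):
        library = generate_library(80, seed=74)
        params = SpliceModelParams(lambda_minus1=0.4)
        truth = simulate_transcripts(library, "K700E", params, 10, seed=75)
        emit_reads(truth, library, tmp_path / "r1.fq", tmp_path / "r2.fq",
                   tmp_path / "side.tsv", read_len=50, error_rate=0.02, seed=76)
        table, report = build_transcript_table(
            tmp_path / "r1.fq", tmp_path / "r2.fq", library, "K700E")
        assert (report["assigned"] + report["unassigned"] + report["uncalled"]
                == report["n_pairs"] == truth["count"].sum())
        assert table["n_reads"].sum() == report["assigned"]


class TestApplyFilters:
    def _tables(self, counts):
        """counts: {cond: {mg: n_reads}} -> transcript tables."""
        return {
            cond: pd.DataFrame(
                [(mg, cond, "SA2", 291, n) for mg, n in per.items()],
                columns=["minigene_id", "condition", "acceptor_class",
                         "acceptor_pos", "n_reads"])
            for cond, per in counts.items()
        }

    def test_boundary_five_reads_kept(self):
        tables = self._tables({"WT": {"m1": 5}, "K700E": {"m1": 5}})
        out = apply_filters(tables, FilterConfig(min_reads=5))
        assert set(out["WT"]["minigene_id"]) == {"m1"}

    def test_absent_in_one_condition_dropped(self):
        tables = self._tables({"WT": {"m1": 12, "m2": 9}, "K700E": {"m2": 9}})
        out = apply_filters(tables, FilterConfig(min_reads=5))
        assert set(out["WT"]["minigene_id"]) == {"m2"}

    def test_idempotent(self):
        tables = self._tables({"WT": {"m1": 5, "m2": 3, "m3": 20},
                               "K700E": {"m1": 7, "m3": 2}})
        once = apply_filters(tables, FilterConfig())
        twice = apply_filters(once, FilterConfig())
        for cond in tables:
            pd.testing.assert_frame_equal(once[cond], twice[cond])

    @given(st.integers(1, 30))
    def test_monotone_in_min_reads(self, min_reads):
        tables = self._tables({
            "WT": {f"m{i}": i for i in range(1, 31)},
            "K700E": {f"m{i}": 31 - i for i in range(1, 31)},
        })
        lo = apply_filters(tables, FilterConfig(min_reads=min_reads))
        hi = apply_filters(tables, FilterConfig(min_reads=min_reads + 1))
        assert set(hi["WT"]["minigene_id"]) <= set(lo["WT"]["minigene_id"])

    def test_requires_two_tables(self):
        tables = self._tables({"WT": {"m1": 9}})
        with pytest.raises(ValueError):
            apply_filters(tables, FilterConfig())
        out = apply_filters(tables, FilterConfig(require_both_conditions=False))
        assert set(out["WT"]["minigene_id"]) == {"m1"}
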