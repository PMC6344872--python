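"""6-mer odds-ratio statistics, motif classification and enhancer ranking."""

import itertools
import re
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bpmpra import (
    ALL_6MERS,
    MotifClass,
    classification_census,
    classify_kmer,
    compute_all,
    delta_log2,
    generate_library,
    kmer_presence,
    odds_ratio,
    top_enhancers,
)

DNA6 = st.text(alphabet="ACGT", min_size=6, max_size=6)


def make_tables(library, sa1_ids, condition="WT"):
    """Transcript table where minigenes in ``sa1_ids`` carry one SA1 read."""
    rows = []
    for mg in library:
        rows.append((mg.id, condition, "SA2", mg.sa2_pos, 10))
        if mg.id in sa1_ids:
            rows.append((mg.id, condition, "SA1", mg.sa1_pos, 3))
    return pd.DataFrame(
        rows,
        columns=["minigene_id", "condition", "acceptor_class", "acceptor_pos",
                 "n_reads"])


class TestKmerPresence:
    def test_examples(self):
        assert kmer_presence("CTAACG", 6) == {"CTAACG"}
        assert kmer_presence("AAAAAAA", 6) == {"AAAAAA"}

    @given(st.text(alphabet="ACGT", min_size=25, max_size=25))
    def test_25mer_has_at_most_20_kmers(self, seq):
        assert len(kmer_presence(seq, 6)) <= 20

    def test_short_sequence_flagged_empty(self):
        with pytest.warns(UserWarning):
            assert kmer_presence("ACGT", 6) == set()


class TestOddsRatio:
    def test_plain_value(self):
        assert odds_ratio(3, 1, 2, 4, pseudocount=0) == pytest.approx(6.0)

    @pytest.mark.parametrize("p", [0, 0.5, 1.0])
    def test_balanced_identity(self, p):
        assert odds_ratio(5, 5, 5, 5, pseudocount=p) == pytest.approx(1.0)

    def test_haldane_anscombe_zero_cell(self):
        # (0 + .5)(5 + .5) / ((10 + .5)(5 + .5)) = 0.5 / 10.5
        assert odds_ratio(0, 10, 5, 5, pseudocount=0.5) == pytest.approx(
            (0.5 * 5.5) / (10.5 * 5.5))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            odds_ratio(0, 0, 5, 5)
        with pytest.raises(ValueError):
            odds_ratio(-1, 2, 3, 4)

    @given(st.tuples(*[st.integers(0, 200)] * 4))
    def test_label_inversion_reciprocal(self, cells):
        """Swapping SA1/non-SA1 labels maps OR to its reciprocal."""
        a, b, c, d = cells
        if a + b == 0 or c + d == 0:
            return
        assert odds_ratio(c, d, a, b) == pytest.approx(1.0 / odds_ratio(a, b, c, d))


@pytest.fixture(scope="module")
def fixture():
    library = generate_library(120, seed=31)
    rng = np.random.default_rng(32)
    sa1 = {mg.id for mg in library if rng.random() < 0.4}
    return library, make_tables(library, sa1), sa1


class TestComputeAll:
    def test_4096_rows(self, fixture):
        library, table, _ = fixture
        stats = compute_all(library, table, "25A")
        assert len(stats) == 4096
        assert list(stats["kmer"]) == ALL_6MERS

    def test_margins_constant(self, fixture):
        library, table, sa1 = fixture
        stats = compute_all(library, table, "25A")
        assert (stats["a"] + stats["b"] == len(sa1)).all()
        assert (stats["c"] + stats["d"] == len(library) - len(sa1)).all()

    def test_brute_force_recount(self, fixture):
        """Every 2x2 cell and OR matches an independent substring recount."""
        library, table, sa1 = fixture
        stats = compute_all(library, table, "25B").set_index("kmer")
        rng = np.random.default_rng(33)
        for kmer in rng.choice(ALL_6MERS, size=300, replace=False):
            a = sum(1 for m in library if m.id in sa1 and kmer in m.n25b)
            c = sum(1 for m in library if m.id not in sa1 and kmer in m.n25b)
            row = stats.loc[kmer]
            assert (row["a"], row["c"]) == (a, c)
            assert row["odds_ratio"] == pytest.approx(
                odds_ratio(a, len(sa1) - a, c, len(library) - len(sa1) - c))

    def test_universal_kmer_is_nondiscriminative(self):
        """A 6-mer carried by every minigene gives OR 1 on balanced groups."""
        from bpmpra import DEFAULT_SCAFFOLD
        from bpmpra.simulate import make_minigene

        library = [
            make_minigene(mg.id, mg.barcode, "CTAACG" + mg.n25a[6:], mg.n25b,
                          DEFAULT_SCAFFOLD)
            for mg in generate_library(40, seed=34)
        ]
        sa1 = {mg.id for mg in library[:20]}
        stats = compute_all(library, make_tables(library, sa1), "25A")
        row = stats.set_index("kmer").loc["CTAACG"]
        assert row["b"] == row["d"] == 0
        assert row["odds_ratio"] == pytest.approx(1.0)

    def test_empty_sa1_set_is_an_error(self):
        library = generate_library(10, seed=35)
        with pytest.raises(ValueError, match="WT"):
            compute_all(library, make_tables(library, set()), "25A")


@pytest.fixture(scope="module")
def stats_pair():
    library = generate_library(80, seed=41)
    rng = np.random.default_rng(42)
    s1 = compute_all(library, make_tables(
        library, {m.id for m in library if rng.random() < 0.3}), "25A")
    s2 = compute_all(library, make_tables(
        library, {m.id for m in library if rng.random() < 0.5}), "25A")
    return s1, s2


class TestDeltaLog2:
    def test_identical_inputs_zero(self, stats_pair):
        s1, _ = stats_pair
        assert (delta_log2(s1, s1)["delta_log2"] == 0).all()

    def test_antisymmetry(self, stats_pair):
        s1, s2 = stats_pair
        d12 = delta_log2(s1, s2)["delta_log2"].to_numpy()
        d21 = delta_log2(s2, s1)["delta_log2"].to_numpy()
        assert np.allclose(d12, -d21)

    def test_mismatched_universe_rejected(self, stats_pair):
        s1, s2 = stats_pair
        with pytest.raises(ValueError):
            delta_log2(s1, s2.iloc[::-1].reset_index(drop=True))


class TestClassifyKmer:
    @pytest.mark.parametrize("kmer,expected", [
        ("CTAAGT", MotifClass.CANONICAL_TAA),
        ("GTGACC", MotifClass.MINUS1_VARIANT),
        ("CCAAGG", MotifClass.MINUS2_VARIANT),
        ("GGGGGG", MotifClass.NONE),
        ("GCGACC", MotifClass.BOTH_VARIANT),
    ])
    def test_examples(self, kmer, expected):
        assert classify_kmer(kmer) is expected

    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError):
            classify_kmer("CTAANN")

    @given(DNA6)
    def test_total_and_hierarchical(self, kmer):
        cls = classify_kmer(kmer)
        assert isinstance(cls, MotifClass)
        if "TAA" in kmer:
            assert cls is MotifClass.CANONICAL_TAA

    def test_census_matches_independent_regex_scan(self):
        """Dual-implementation oracle: regex-based scanning enumeration."""
        pats = {
            MotifClass.CANONICAL_TAA: re.compile("TAA"),
            MotifClass.MINUS1_VARIANT: re.compile("T[CGT]A"),
            MotifClass.MINUS2_VARIANT: re.compile("[ACG]AA"),
            MotifClass.BOTH_VARIANT: re.compile("[ACG][CGT]A"),
        }
        expected = {cls: 0 for cls in MotifClass}
        for kmer in map("".join, itertools.product("ACGT", repeat=6)):
            for cls in (MotifClass.CANONICAL_TAA, MotifClass.MINUS1_VARIANT,
                        MotifClass.MINUS2_VARIANT, MotifClass.BOTH_VARIANT):
                if pats[cls].search(kmer):
                    expected[cls] += 1
                    break
            else:
                expected[MotifClass.NONE] += 1
        census = classification_census().set_index("motif_class")
        for cls in MotifClass:
            assert census.loc[cls.value, "count"] == expected[cls]
        assert census["count"].sum() == 4096


class TestTopEnhancers:
    @pytest.fixture()
    def delta_table(self):
        rng = np.random.default_rng(51)
        or_wt = rng.lognormal(0, 0.4, 4096)
        or_k = rng.lognormal(0, 0.4, 4096)
        return pd.DataFrame({
            "kmer": ALL_6MERS, "region": "25A",
            "or_wt": or_wt, "or_k700e": or_k,
            "log2_or_wt": np.log2(or_wt), "log2_or_k700e": np.log2(or_k),
            "delta_log2": np.log2(or_k) - np.log2(or_wt),
        })

    def test_threshold_filters_all(self, delta_table):
        delta_table["or_k700e"] = 0.5
        with pytest.warns(UserWarning):
            ranked, shares = top_enhancers(delta_table, or_threshold=1.5)
        assert len(ranked) == 0
        assert all(v == 0 for v in shares.values())

    def test_threshold_zero_by_or_full_ranking(self, delta_table):
        ranked, _ = top_enhancers(delta_table, or_threshold=0, by="OR")
        assert len(ranked) == 4096
        assert ranked["or_k700e"].iloc[0] == delta_table["or_k700e"].max()

    def test_delta_ranking_sorted_and_positive(self, delta_table):
        ranked, shares = top_enhancers(delta_table, or_threshold=1.5, by="delta")
        assert (ranked["or_k700e"] > 1.5).all()
        assert (ranked["delta_log2"] > 0).all()
        assert (ranked["delta_log2"].diff().dropna() <= 0).all()
        assert sum(shares.values()) == pytest.approx(100.0)
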