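import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import gammaln

from hiberseq import seqfeatures as sf
from hiberseq.config import AREConfig


def _revcomp(seq):
    return seq[::-1].translate(str.maketrans("ACGTN", "TGCAN"))


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GGCC", 1.0), ("ATGC", 0.5), ("ANT", 0.0), ("aTgC", 0.5)],
    )
    def test_examples(self, seq, expected):
        assert sf.gc_content(seq) == pytest.approx(expected)

    def test_all_n_is_nan(self):
        assert math.isnan(sf.gc_content("NNNN"))

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_case_and_revcomp_invariance(self, seq):
        a = sf.gc_content(seq)
        if math.isnan(a):
            return
        assert sf.gc_content(seq.lower()) == pytest.approx(a)
        assert sf.gc_content(_revcomp(seq)) == pytest.approx(a)


class TestAreScore:
    def test_no_pentamer_scores_zero(self):
        seq = "G" * 300
        assert sf.are_score(seq) == 0.0
        assert sf.are_class(0.0) == "no_ARE"

    def test_overlapping_pair_hand_enumeration(self):
        # ATTTATTTA: occurrences at 0 and 4 -> P=2, one adjacent pair -> C=1
        seq = "ATTTATTTA" + "G" * 291
        assert sf.are_score(seq) == pytest.approx(2 + 1.5 * 1)

    def test_short_utr_excluded(self):
        assert sf.are_score("ATTTA" * 30) is None  # 150 nt < 200
        assert sf.are_class(None) is None

    def test_isolated_pentamer_adds_exactly_one(self):
        base = "G" * 300
        one = "G" * 100 + "ATTTA" + "G" * 195
        two = "G" * 100 + "ATTTA" + "G" * 95 + "ATTTA" + "G" * 95
        assert sf.are_score(one) == sf.are_score(base) + 1
        assert sf.are_score(two) == sf.are_score(one) + 1

    def test_adjacency_adds_cluster_bonus(self):
        gap_wide = "G" * 100 + "ATTTA" + "G" * 50 + "ATTTA" + "G" * 140
        # start-to-start distance 10 <= 5 + 9 -> clustered
        gap_tight = "G" * 100 + "ATTTA" + "G" * 5 + "ATTTA" + "G" * 185
        assert sf.are_score(gap_tight) == sf.are_score(gap_wide) + 1.5

    def test_high_class_threshold(self):
        cfg = AREConfig()
        seq = ("ATTTA" + "G" * 50) * 8 + "G" * 100  # 8 isolated pentamers
        score = sf.are_score(seq, cfg)
        assert score == 8.0
        assert sf.are_class(score, cfg) == "high_ARE"

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            sf.are_score("ATTTAX" + "G" * 300)


class TestMotifScan:
    def test_overlap_counting(self):
        out = sf.motif_scan({"s": "ATGATG"}, "ATG")
        assert out.loc["s", "count"] == 2

    def test_iupac_expansion(self):
        out = sf.motif_scan({"s": "ACAT"}, "AY")
        assert out.loc["s", "count"] == 2

    def test_density_per_kb(self):
        out = sf.motif_scan({"s": "ATG" + "C" * 997}, "ATG")
        assert out.loc["s", "per_kb"] == pytest.approx(1.0)

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            sf.motif_scan({"s": "ACGT"}, "AXG")

    def test_overlapping_ambiguous(self):
        # AAAA with motif AA -> 3 overlapping matches
        out = sf.motif_scan({"s": "AAAA"}, "AA")
        assert out.loc["s", "count"] == 3


def _fisher_two_sided_oracle(a, b, c, d):
    """Brute-force two-sided Fisher p: sum of hypergeometric probabilities
    <= that of the observed table, over all tables with the same margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def logp(x):
        return (
            gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
            + gammaln(r2 + 1) - gammaln(c1 - x + 1) - gammaln(r2 - c1 + x + 1)
            - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = logp(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = logp(x)
        if lp <= obs + 1e-9:
            total += math.exp(lp)
    return min(total, 1.0)


class TestFisherOracle:
    @given(
        st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15)
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_enumeration(self, a, b, c, d):
        _, p = stats.fisher_exact([[a, b], [c, d]])
        assert p == pytest.approx(_fisher_two_sided_oracle(a, b, c, d), abs=1e-9)


class TestKmerEnrichment:
    def _seqs(self, rng, n, with_kmer_frac, kmer="ACGTAC", length=60):
        out = {}
        for i in range(n):
            s = "".join(rng.choice(list("ACGT"), size=length))
            s = s.replace(kmer, "ACCCCC")  # avoid accidental presence
            if i < with_kmer_frac * n:
                pos = int(rng.integers(0, length - len(kmer)))
                s = s[:pos] + kmer + s[pos + len(kmer):]
            out[f"s{i}"] = s
        return out

    def test_identical_sets_no_signal(self):
        rng = np.random.default_rng(1)
        seqs = self._seqs(rng, 30, 0.5)
        out = sf.kmer_enrichment(seqs, seqs, 6)
        assert (out["qvalue"] > 0.9).all()
        assert np.allclose(out["odds_ratio"].replace([np.inf], 1).fillna(1), 1.0)

    def test_planted_kmer_has_smallest_p(self):
        rng = np.random.default_rng(2)
        fg = self._seqs(rng, 100, 0.9)
        bg = self._seqs(rng, 100, 0.1)
        out = sf.kmer_enrichment(fg, bg, 6)
        assert out["pvalue"].idxmin() == "ACGTAC"

    def test_swap_inverts_odds(self):
        rng = np.random.default_rng(3)
        fg = self._seqs(rng, 40, 0.8)
        bg = self._seqs(rng, 40, 0.2)
        fwd = sf.kmer_enrichment(fg, bg, 6)
        rev = sf.kmer_enrichment(bg, fg, 6)
        k = "ACGTAC"
        assert fwd.loc[k, "odds_ratio"] == pytest.approx(1.0 / rev.loc[k, "odds_ratio"])

    def test_k_bounds(self):
        with pytest.raises(ValueError, match="k must be"):
            sf.kmer_enrichment({"a": "ACGT"}, {"b": "ACGT"}, 0)


class TestClusterFeatureFisher:
    def test_uniform_class_no_signal(self):
        genes = [f"g{i}" for i in range(200)]
        assignments = pd.Series(["c1"] * 100 + ["c2"] * 100, index=genes)
        classes = pd.Series((["x", "y"] * 100)[:200], index=genes)
        out = sf.cluster_feature_fisher(assignments, classes, genes)
        assert (out["pvalue"] > 0.5).all()

    def test_enrichment_detected(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(400)]
        assignments = pd.Series("other", index=genes)
        assignments.iloc[:100] = "seeded"
        labels = ["no_ARE" if rng.random() < 0.5 else "high_ARE" for _ in genes]
        labels[:100] = ["no_ARE" if rng.random() < 0.8 else "high_ARE" for _ in range(100)]
        classes = pd.Series(labels, index=genes)
        out = sf.cluster_feature_fisher(assignments, classes, genes)
        row = out[(out.cluster == "seeded") & (out.feature_class == "no_ARE")].iloc[0]
        assert row["pvalue"] < 0.01

    def test_margins_bookkeeping(self):
        genes = [f"g{i}" for i in range(50)]
        assignments = pd.Series(["c"] * 20 + [None] * 30, index=genes)
        classes = pd.Series(["x"] * 25 + ["y"] * 25, index=genes)
        out = sf.cluster_feature_fisher(assignments, classes, genes)
        row = out.iloc[0]
        assert row["in_cluster_class"] + row["in_cluster_other"] == 20
        total = (
            row["in_cluster_class"] + row["in_cluster_other"]
            + row["background_class"] + row["background_other"]
        )
        assert total == 50


class TestWilcoxon:
    def test_exact_enumeration_value(self):
        assert sf.wilcoxon_compare([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_equal_singletons(self):
        assert sf.wilcoxon_compare([1.0], [1.0]) == pytest.approx(1.0)

    def test_null_p_uniformish(self):
        rng = np.random.default_rng(5)
        ps = [
            sf.wilcoxon_compare(rng.normal(size=20), rng.normal(size=20))
            for _ in range(300)
        ]
        assert 0.01 <= np.mean(np.asarray(ps) < 0.05) <= 0.12

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            sf.wilcoxon_compare([], [1.0])


class TestGoEnrichment:
    def _collections(self):
        return {
            "TERM_A": {f"g{i}" for i in range(10)},
            "TERM_B": {f"g{i}" for i in range(40, 60)},
        }

    def test_whole_term_minimal_p(self):
        background = {f"g{i}" for i in range(100)}
        out = sf.go_enrichment({f"g{i}" for i in range(10)}, self._collections(), background)
        assert out["pvalue"].idxmin() == "TERM_A"

    def test_random_sets_uniform(self):
        rng = np.random.default_rng(6)
        background = [f"g{i}" for i in range(200)]
        collections = {
            f"T{j}": set(rng.choice(background, size=30, replace=False)) for j in range(40)
        }
        ps = []
        for _ in range(10):
            genes = set(rng.choice(background, size=25, replace=False))
            ps.extend(sf.go_enrichment(genes, collections, background)["pvalue"])
        assert np.mean(np.asarray(ps) < 0.05) < 0.12

    def test_background_changes_margins(self):
        genes = {f"g{i}" for i in range(5)}
        full = {f"g{i}" for i in range(100)}
        small = {f"g{i}" for i in range(50)}
        a = sf.go_enrichment(genes, self._collections(), full)
        b = sf.go_enrichment(genes, self._collections(), small)
        assert a.loc["TERM_A", "not_set_not_term"] != b.loc["TERM_A", "not_set_not_term"]

    def test_disjoint_background_errors(self):
        with pytest.raises(ValueError, match="disjoint"):
            sf.go_enrichment({"x"}, self._collections(), {"g1", "g2"})


class TestGmt:
    def test_parse(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("SET1\tdesc\tg1\tg2\tg3\nSET2\tdesc\tg9\n")
        sets = sf.read_gmt(path)
        assert sets == {"SET1": {"g1", "g2", "g3"}, "SET2": {"g9"}}

    def test_bad_row_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("ONLY_NAME\n")
        with pytest.raises(ValueError, match="3 columns"):
            sf.read_gmt(path)
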