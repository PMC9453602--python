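"""Nearest-centroid triad classification and summary tables."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from polym6a import triad_bias as tb


def _oracle_classify(v):
    """Independent oracle: exhaustive distance computation over 7 centroids."""
    v = np.asarray(v, float)
    r = v / v.sum()
    best, bd = None, np.inf
    for c in tb.CATEGORIES:
        d = float(np.sqrt(((r - tb.CENTROIDS[c]) ** 2).sum()))
        if d < bd - 1e-15:
            best, bd = c, d
    return best, bd


class TestClassifyTriad:
    @pytest.mark.parametrize("v,expected,dist", [
        ((1, 0, 0), "A-dominant", 0.0),
        ((1, 1, 1), "Balanced", 0.0),
        ((0, 1, 1), "A-suppressed", 0.0),
    ])
    def test_centroid_values(self, v, expected, dist):
        c = tb.classify_triad(v)
        assert c.category == expected
        assert c.distance == pytest.approx(dist, abs=1e-12)

    def test_mild_dominance_stays_balanced(self):
        c = tb.classify_triad((2, 1, 1))
        oc, od = _oracle_classify((2, 1, 1))
        assert c.category == oc == "Balanced"
        assert c.distance == pytest.approx(od, abs=1e-12)
        assert c.distance == pytest.approx(0.2041, abs=1e-4)

    def test_strong_dominance(self):
        c = tb.classify_triad((8, 1, 1))
        oc, _ = _oracle_classify((8, 1, 1))
        assert c.category == oc == "A-dominant"
        assert c.distance == pytest.approx(0.2455, abs=1e-3)

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(trial)
        v = rng.gamma(1.0, 2.0, size=3) + 1e-6
        c = tb.classify_triad(v)
        oc, od = _oracle_classify(v)
        if not c.tie:
            assert c.category == oc
        assert c.distance == pytest.approx(od, abs=1e-12)

    def test_zero_sum_unclassifiable(self):
        with pytest.raises(ValueError):
            tb.classify_triad((0, 0, 0))


@settings(deadline=None, derandomize=True, max_examples=100)
@given(v=hst.tuples(*[hst.floats(0.01, 100)] * 3), k=hst.floats(0.01, 50))
def test_scale_invariance(v, k):
    a, b = tb.classify_triad(v), tb.classify_triad(tuple(k * x for x in v))
    assert a.category == b.category
    assert a.distance == pytest.approx(b.distance, abs=1e-9)


@settings(deadline=None, derandomize=True, max_examples=100)
@given(v=hst.tuples(*[hst.floats(0.01, 100)] * 3))
def test_label_permutation_consistency(v):
    """Swapping A and B swaps A-/B- categories and fixes Balanced."""
    swap = {"A-dominant": "B-dominant", "B-dominant": "A-dominant",
            "A-suppressed": "B-suppressed", "B-suppressed": "A-suppressed"}
    a = tb.classify_triad(v)
    b = tb.classify_triad((v[1], v[0], v[2]))
    if not (a.tie or b.tie):
        assert b.category == swap.get(a.category, a.category)


class TestNoiseRecovery:
    def test_exact_at_centroids(self):
        rng = np.random.default_rng(0)
        cats = rng.choice(tb.CATEGORIES, size=200)
        assert all(tb.classify_triad(tb.CENTROIDS[c] + 0).category == c
                   for c in cats)

    def test_small_noise_high_accuracy(self):
        rng = np.random.default_rng(1)
        hits = total = 0
        for _ in range(500):
            c = str(rng.choice(tb.CATEGORIES))
            v = np.clip(tb.CENTROIDS[c] + rng.normal(0, 0.05, 3), 0, None)
            if v.sum() == 0:
                continue
            total += 1
            hits += tb.classify_triad(v).category == c
        assert hits / total >= 0.9


class TestInclusionAndSummary:
    @pytest.fixture
    def triads(self):
        return pd.DataFrame([
            dict(triad_id="tr1", gene_A="a1", gene_B="b1", gene_D="d1", syntenic=True),
            dict(triad_id="tr2", gene_A="a2", gene_B="b2", gene_D="d2", syntenic=False),
            dict(triad_id="tr3", gene_A="a3", gene_B="b3", gene_D="d3", syntenic=True),
        ])

    def test_one_methylated_gene_includes_triad(self, triads):
        kept = tb.triad_inclusion(triads, {"a1"})
        assert list(kept["triad_id"]) == ["tr1"]

    def test_no_peaks_excludes(self, triads):
        assert len(tb.triad_inclusion(triads, set())) == 0

    def test_unknown_gene_drops_triad(self, triads):
        known = {"a1", "b1", "d1", "a2", "b2", "d2"}  # tr3 genes unknown
        kept = tb.triad_inclusion(triads, {"a1", "a3"}, known_genes=known)
        assert list(kept["triad_id"]) == ["tr1"]

    def test_summary_totals_and_percentages(self):
        classified = pd.DataFrame(
            [dict(triad_id=f"t{i}", syntenic=i % 4 != 0, signal="m6A",
                  category="A-dominant" if i < 6 else "Balanced")
             for i in range(10)])
        s = tb.summarize_categories(classified).set_index("category")
        assert s.loc["Total", "total"] == 10
        assert (s.loc["Total", "syntenic"] + s.loc["Total", "non_syntenic"]) == 10
        assert s.loc["Total", "syntenic_pct"] == pytest.approx(
            100 * s.loc["Total", "syntenic"] / 10)
        # category rows sum to the totals row
        cats = s.drop("Total")
        assert cats["total"].sum() == 10


class TestCrossTabulate:
    def _cats(self, mapping, signal):
        return pd.DataFrame([dict(triad_id=k, category=v, signal=signal)
                             for k, v in mapping.items()])

    def test_all_balanced_single_cell(self):
        a = self._cats({f"t{i}": "Balanced" for i in range(5)}, "m6A")
        b = self._cats({f"t{i}": "Balanced" for i in range(5)}, "RNA")
        m = tb.cross_tabulate(a, b)
        assert m.loc["Balanced", "Balanced"] == 100.0
        assert m.to_numpy().sum() == 100.0

    def test_row_split_percentages(self):
        a = self._cats({f"t{i}": "A-dominant" for i in range(4)}, "m6A")
        b = self._cats({"t0": "Balanced", "t1": "Balanced", "t2": "Balanced",
                        "t3": "B-dominant"}, "RNA")
        m = tb.cross_tabulate(a, b)
        assert m.loc["A-dominant", "Balanced"] == 75.0
        assert m.loc["A-dominant", "B-dominant"] == 25.0

    def test_planted_pairs_are_matrix_mode(self, small_dataset, called_peaks):
        """Cross-tab of m6A vs RNA categories peaks at the planted pairs."""
        ds = small_dataset
        cons, _ = called_peaks
        from polym6a import quantify as qt
        meth = {p.transcript_id for p in cons}
        lengths = {t: m.length for t, m in ds.genome.models.items()}
        prof = qt.profile_transcripts(ds.window_counts, ds.transcript_counts,
                                      lengths, methylated_ids=meth)
        extent = dict(zip(prof.transcript_id, prof.extent.fillna(0.0)))
        rna = dict(zip(prof.transcript_id, prof.fpkm_input))
        g = lambda d: {t.rsplit(".", 1)[0]: v for t, v in d.items()}
        meth_genes = {t.rsplit(".", 1)[0] for t in meth}
        inc = tb.triad_inclusion(ds.genome.triads, meth_genes)
        cats_m = tb.classify_triads(inc, g(extent), "m6A")
        cats_r = tb.classify_triads(inc, g(rna), "RNA")
        m = tb.cross_tabulate(cats_m, cats_r)
        # the planted (m6A, RNA) category pair of each classified triad
        merged = cats_m.merge(cats_r, on="triad_id", suffixes=("_a", "_b"))
        planted_pairs = [(ds.truth.m6a_category.get(t), ds.truth.rna_category.get(t))
                         for t in merged["triad_id"]]
        planted_pairs = [p for p in planted_pairs if None not in p]
        from collections import Counter
        (top_pair, _), = Counter(planted_pairs).most_common(1)
        row = m.loc[top_pair[0]]
        assert row.idxmax() == top_pair[1]
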