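"""Ka/Ks (NG86), pi, Tajima's D, Weir-Cockerham Fst against independent oracles."""

import itertools
import math

import numpy as np
import pytest

from polym6a import evolution as ev
from polym6a.interface_io import HaplotypeMatrix

from oracles import (mutate_cds as _mutate, oracle_kaks as _oracle_kaks,
                     oracle_pi as _oracle_pi, oracle_tajima as _oracle_tajima,
                     random_cds as _random_cds)


class TestKaKs:
    def test_identical_sequences_zero(self):
        s = _random_cds(np.random.default_rng(0), 100)
        r = ev.kaks_ng86(s, s)
        assert r.ka == 0.0 and r.ks == 0.0

    def test_single_nonsynonymous_change(self):
        a = "ATG" + "AAA" * 20
        b = "ATG" + "ACA" + "AAA" * 19      # K -> T, nonsynonymous
        r = ev.kaks_ng86(a, b)
        assert r.ks == 0.0
        assert r.ka > 0.0

    def test_single_synonymous_change(self):
        a = "ATG" + "AAA" * 20
        b = "ATG" + "AAG" + "AAA" * 19      # K -> K, synonymous third position
        r = ev.kaks_ng86(a, b)
        assert r.ka == 0.0
        assert r.ks > 0.0

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_pathway_enumeration_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        a = _mutate(rng, _random_cds(rng, 300), 10)  # avoid shared ancestry bias
        b = _mutate(rng, a, 25)
        r = ev.kaks_ng86(a, b)
        ka_o, ks_o = _oracle_kaks(a, b)
        assert r.ka == pytest.approx(ka_o, abs=1e-12)
        assert r.ks == pytest.approx(ks_o, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        a = _random_cds(rng, 200)
        b = _mutate(rng, a, 15)
        r1, r2 = ev.kaks_ng86(a, b), ev.kaks_ng86(b, a)
        assert r1.ka == pytest.approx(r2.ka, abs=1e-12)
        assert r1.ks == pytest.approx(r2.ks, abs=1e-12)

    def test_internal_stop_errors(self):
        with pytest.raises(ValueError, match="stop"):
            ev.kaks_ng86("ATGTAAAAA", "ATGAAAAAA")

    def test_align_codons_strips_gap_columns(self):
        a = "ATGAAACCCGGG"
        b = "ATGCCCGGG"      # AAA codon deleted
        aa, bb = ev.align_codons(a, b)
        assert len(aa) == len(bb) == 9
        assert ev.kaks_ng86(aa, bb).ka == 0.0


# ---------------------------------------------------------------------------
# population statistics
# ---------------------------------------------------------------------------

def _haps(geno, pops=None, span=100):
    geno = np.asarray(geno, dtype=np.int8)
    n = geno.shape[1]
    return HaplotypeMatrix(
        genotypes=geno, positions=np.arange(1, geno.shape[0] + 1),
        samples=[], populations=pops or ["p1"] * n, span=span)




class TestPi:
    def test_two_haplotypes_one_difference(self):
        geno = np.zeros((1, 2), dtype=np.int8)
        geno[0, 1] = 1
        assert ev.pi(_haps(geno, span=100)) == pytest.approx(0.01)

    def test_identical_haplotypes_zero(self):
        assert ev.pi(_haps(np.zeros((5, 4)), span=100)) == 0.0

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_pairwise_oracle(self, trial):
        rng = np.random.default_rng(trial)
        geno = (rng.random((10, 4)) < 0.4).astype(np.int8)
        h = _haps(geno, span=10)
        assert ev.pi(h) == pytest.approx(_oracle_pi(geno, 10), abs=1e-12)

    def test_single_haplotype_errors(self):
        with pytest.raises(ValueError):
            ev.pi(_haps(np.zeros((3, 1))))


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        assert ev.tajimas_d(_haps(np.zeros((4, 6)))) is None

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_formula_oracle(self, trial):
        rng = np.random.default_rng(50 + trial)
        geno = (rng.random((10, 4)) < 0.4).astype(np.int8)
        h = _haps(geno, span=10)
        oracle = _oracle_tajima(geno, 10)
        got = ev.tajimas_d(h)
        if oracle is None:
            assert got is None
        else:
            assert got == pytest.approx(oracle, abs=1e-9)

    def test_two_haplotypes_flagged_undefined(self):
        """n=2 degenerates (c1 = c2 = 0): flagged as undefined, not 0."""
        geno = np.array([[0, 1], [0, 1]], dtype=np.int8)
        assert ev.tajimas_d(_haps(geno, span=10)) is None

    def test_neutral_simulation_centred_near_zero(self, small_dataset):
        vals = [ev.tajimas_d(m) for m in small_dataset.population.values()]
        vals = [v for v in vals if v is not None]
        assert len(vals) >= 30
        assert abs(np.mean(vals)) < 0.3


class TestFst:
    def test_fixed_difference_is_one(self):
        geno = np.array([[1, 1, 1, 0, 0, 0]], dtype=np.int8)
        pops = ["p1"] * 3 + ["p2"] * 3
        raw, clamped = ev.fst_wc(_haps(geno, pops=pops))
        assert clamped == pytest.approx(1.0)

    def test_identical_frequencies_clamped_to_zero(self):
        geno = np.array([[1, 0, 1, 0, 1, 0, 1, 0]], dtype=np.int8)
        pops = ["p1"] * 4 + ["p2"] * 4
        raw, clamped = ev.fst_wc(_haps(geno, pops=pops))
        assert raw <= 0.0
        assert clamped == 0.0

    def test_monomorphic_undefined(self):
        geno = np.ones((3, 6), dtype=np.int8)
        pops = ["p1"] * 3 + ["p2"] * 3
        assert ev.fst_wc(_haps(geno, pops=pops)) == (None, None)

    def test_matches_hand_computed_variance_components(self):
        # one site, p1: 3/4 alt, p2: 1/4 alt; n1 = n2 = 4 haplotypes
        geno = np.array([[1, 1, 1, 0, 1, 0, 0, 0]], dtype=np.int8)
        pops = ["p1"] * 4 + ["p2"] * 4
        r, nbar, pbar = 2, 4.0, 0.5
        nc = (8 - (16 + 16) / 8) / (r - 1)
        s2 = (4 * (0.75 - 0.5) ** 2 + 4 * (0.25 - 0.5) ** 2) / ((r - 1) * nbar)
        pq = pbar * (1 - pbar)
        b = (nbar / (nbar - 1)) * (pq - s2 * (r - 1) / r)
        a = (nbar / nc) * (s2 - b / nbar)
        raw, _ = ev.fst_wc(_haps(geno, pops=pops))
        assert raw == pytest.approx(a / (a + b), abs=1e-12)

    def test_clamping_never_negative(self, small_dataset):
        for m in small_dataset.population.values():
            res = ev.fst_wc(m)
            if res[1] is not None:
                assert res[1] >= 0.0


class TestClassCompare:
    def test_planted_diversity_difference(self, small_dataset):
        ds = small_dataset
        mats = ds.population
        pi_by_class = {"methylated": [], "non-methylated": []}
        for gid, cls in ds.truth.pop_class.items():
            pi_by_class[cls].append(ev.pi(mats[gid]))
        res = ev.class_compare(pi_by_class["methylated"],
                               pi_by_class["non-methylated"])
        assert res["methylated"]["mean"] < res["non-methylated"]["mean"]

    def test_single_shared_value_p_one(self):
        res = ev.class_compare([1.0], [1.0])
        assert res["p"] == 1.0

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            ev.class_compare([], [1.0])
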