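"""Small-RNA length profile, phasing score, target scoring, synergy groups."""

import math

import numpy as np
import pandas as pd
import pytest

from polym6a import smallrna as sr


def _reads(rows):
    return pd.DataFrame(rows, columns=["sequence", "length", "chrom",
                                       "position", "strand", "count"])


class TestLengthProfile:
    def test_empty_input_all_zero(self):
        lp = sr.length_profile(_reads([]))
        assert (lp == 0).all()

    def test_single_read_bin(self):
        lp = sr.length_profile(_reads([("A" * 21, 21, "c", 0, "+", 5)]))
        assert lp.loc[21] == 5

    def test_planted_24nt_mode(self, small_dataset):
        lp = sr.length_profile(small_dataset.smallrna)
        assert lp.idxmax() == 24


class TestPhaseScore:
    def test_formula_value(self):
        # 5 occupied cycles, 10 phased, 0 unphased: P = 3 ln(101)
        pos = np.array([k * 21 for k in range(5)])
        cnt = np.array([2, 2, 2, 2, 2])
        p, k, n_p, n_u = sr.phase_score(pos, cnt, 0, 21)
        assert k == 5 and n_p == 10 and n_u == 0
        assert p == pytest.approx(3 * math.log(101), abs=1e-9)
        assert p == pytest.approx(13.85, abs=0.01)

    def test_two_cycles_zero(self):
        pos = np.array([0, 21])
        p, k, *_ = sr.phase_score(pos, np.array([5, 5]), 0, 21)
        assert k == 2 and p == 0.0

    def test_bad_register_errors(self):
        with pytest.raises(ValueError):
            sr.phase_score(np.array([0]), np.array([1]), 0, 22)

    def test_register_translation_invariance(self):
        rng = np.random.default_rng(4)
        pos = rng.integers(0, 9 * 21, 40)
        cnt = rng.integers(1, 5, 40)
        a = sr.phase_score(pos, cnt, 0, 21)
        b = sr.phase_score(pos + 21, cnt, 21, 21)
        assert a == b

    def test_null_calibration(self):
        """Uniform random starts rarely reach the locus threshold."""
        rng = np.random.default_rng(9)
        exceed = 0
        n_trials = 1000
        for _ in range(n_trials):
            pos = rng.integers(0, 9 * 21, 50)
            cnt = rng.integers(1, 4, 50)
            p, k, *_ = sr.phase_score(pos, cnt, 0, 21)
            exceed += (p >= 10.0 and k >= 4)
        assert exceed / n_trials <= 0.05


class TestCallPhasedLoci:
    def test_planted_loci_detected_at_own_register_only(self, small_dataset):
        reads = small_dataset.smallrna
        truth = small_dataset.truth.phased_loci
        for register, thr in ((21, 10.0), (24, 15.0)):
            loci = sr.call_phased_loci(reads, register, thr)
            planted = [t for t in truth if t["register"] == register]
            assert planted
            for t in planted:
                assert any(l.interval[0] < t["end"] and l.interval[1] > t["start"]
                           for l in loci), f"missed {t}"

    def test_cross_register_specificity(self, small_dataset):
        truth21 = [t for t in small_dataset.truth.phased_loci
                   if t["register"] == 21][0]
        reads = small_dataset.smallrna
        window = reads[(reads.position >= truth21["start"] - 50)
                       & (reads.position <= truth21["end"] + 50)]
        assert sr.call_phased_loci(window, 24, 15.0) == []

    def test_no_reads_empty(self):
        assert sr.call_phased_loci(_reads([]), 21, 10.0) == []


REVC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(s):
    return "".join(REVC[b] for b in reversed(s))


class TestTargetScore:
    SRNA = "TGGAGCTCCCTTCATTCCAAT"  # 21 nt

    def test_perfect_complement_zero(self):
        assert sr.target_score(self.SRNA, _revcomp(self.SRNA)) == 0.0

    def test_mismatch_outside_seed(self):
        srna = "TTTTTTTTTTTTTTTTTTTTT"
        w = list(_revcomp(srna))      # all A
        # sRNA position 15 (1-based, outside the 2-13 seed) pairs window index 6
        w[21 - 15] = "C"              # T:C mismatch
        assert sr.target_score(srna, "".join(w)) == 1.0

    def test_seed_mismatch_doubled(self):
        srna = "TTTTTTTTTTTTTTTTTTTTT"
        w = list(_revcomp(srna))      # all A
        w[21 - 3] = "C"               # sRNA position 3 (seed): T:C mismatch
        assert sr.target_score(srna, "".join(w)) == 2.0

    def test_seed_wobble_half_then_doubled(self):
        srna = "TTTTTTTTTTTTTTTTTTTTT"
        w = list(_revcomp(srna))
        w[21 - 3] = "G"               # T:G wobble at seed position 3
        assert sr.target_score(srna, "".join(w)) == 1.0

    def test_ambiguous_base_errors(self):
        with pytest.raises(ValueError):
            sr.target_score("TGGAGCTCCCTTCATTCCANT", "A" * 21)

    def test_scan_finds_planted_site(self, small_dataset):
        ds = small_dataset
        mi = ds.mirnas.iloc[0]
        t = [x for x in ds.truth.mirna_targets if x["srna_id"] == mi.srna_id][0]
        model = ds.genome.models[t["mrna_id"]]
        sites = sr.scan_targets(mi.srna_id, mi.sequence,
                                model.transcript_id, model.sequence)
        assert any(s.interval == (t["start"], t["end"]) and s.score == 0.0
                   for s in sites)

    def test_scrambled_srna_no_sites(self):
        rng = np.random.default_rng(2)
        misses = 0
        trials = 50
        for _ in range(trials):
            srna = "".join("ACGT"[i] for i in rng.integers(0, 4, 21))
            mrna = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
            if not sr.scan_targets("x", srna, "m", mrna, cutoff=5.0):
                misses += 1
        assert misses / trials >= 0.99 or misses == trials


class TestTopAbundantAndSynergy:
    def test_top_abundant_ranks_sequences(self):
        reads = _reads([("AAA", 3, "c", 0, "+", 5), ("AAA", 3, "c", 9, "+", 7),
                        ("CCC", 3, "c", 1, "+", 4)])
        top = sr.top_abundant(reads, n=1)
        assert top.iloc[0]["sequence"] == "AAA"
        assert top.iloc[0]["count"] == 12

    def test_identical_te_lists_p_one(self):
        te = {f"t{i}": 2.0 for i in range(10)}
        m6a = {f"t{i}" for i in range(5)}
        tgt = {f"t{i}" for i in range(5, 10)}
        df = sr.synergy_compare(te, m6a, tgt, set())
        row = df[(df.group_a == "m6A_only") & (df.group_b == "target_only")].iloc[0]
        assert row["p"] == 1.0

    def test_stronger_srna_repression_orders_medians(self):
        rng = np.random.default_rng(1)
        te, m6a, tgt = {}, set(), set()
        for i in range(60):
            tid = f"t{i}"
            if i < 20:
                te[tid] = float(np.exp(rng.normal(np.log(9) - 0.2, 0.1)))
                m6a.add(tid)
            elif i < 40:
                te[tid] = float(np.exp(rng.normal(np.log(9) - 1.0, 0.1)))
                tgt.add(tid)
            else:
                te[tid] = float(np.exp(rng.normal(np.log(9), 0.1)))
        df = sr.synergy_compare(te, m6a, tgt, set())
        row = df[(df.group_a == "m6A_only") & (df.group_b == "target_only")].iloc[0]
        assert row["median_b"] < row["median_a"]

    def test_empty_group_skipped_with_note(self):
        te = {"t1": 1.0, "t2": 2.0}
        df = sr.synergy_compare(te, {"t1"}, set(), set())
        row = df[(df.group_a == "m6A_only") & (df.group_b == "target_only")].iloc[0]
        assert row["note"] == "empty group"
        assert np.isnan(row["p"])
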