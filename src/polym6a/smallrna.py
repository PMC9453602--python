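"""Small-RNA quantification, phasiRNA locus detection, and target scoring.

phasiRNA loci are found by a Howell-style phasing score: within a sliding
window of ``cycles`` register lengths, reads whose 5' ends fall on the
register lattice (+-tolerance) are "phased"; with k occupied cycle
positions the score is

    P = (k - 2) * ln(1 + 10 * n_phased / (1 + n_unphased))   for k >= 3

and 0 otherwise.  Qualifying windows are merged into loci per register
(21 or 24 nt).

The target scorer is a psRNATarget-style expectation score: the small RNA
is aligned antiparallel to an mRNA window and penalties are summed
(mismatch 1.0, G:U wobble 0.5, gap 2.0), doubled at small-RNA positions
2-13 (the seed); sites with score <= cutoff are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import ranksum

REGISTERS = (21, 24)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class PhasedLocus:
    chrom: str
    interval: tuple[int, int]
    register: int
    score: float
    k: int
    n_phased: int
    n_unphased: int


@dataclass
class TargetSite:
    srna_id: str
    mrna_id: str
    interval: tuple[int, int]       # on the mRNA, 0-based half-open
    score: float
    inside_m6a_peak: bool = False


def length_profile(reads: pd.DataFrame,
                   lo: int = 15, hi: int = 40) -> pd.Series:
    """Read-count histogram over small-RNA lengths ``lo..hi``."""
    idx = pd.RangeIndex(lo, hi + 1, name="length")
    if reads.empty:
        return pd.Series(0, index=idx, name="count")
    counts = reads.groupby("length")["count"].sum()
    return counts.reindex(idx, fill_value=0).rename("count")


def phase_score(positions: np.ndarray, counts: np.ndarray,
                window_start: int, register: int,
                cycles: int = 9, tolerance: int = 1) -> tuple[float, int, int, int]:
    """(P, k, n_phased, n_unphased) for one scoring window.

    ``positions`` are 5'-end coordinates; reads within
    [window_start, window_start + cycles*register) are considered.  A read
    is phased when its offset from ``window_start`` modulo the register is
    within ``tolerance`` of 0 (circularly); k counts distinct occupied
    cycle positions.
    """
    if register not in REGISTERS:
        raise ValueError(f"register must be one of {REGISTERS}, got {register}")
    window_end = window_start + cycles * register
    sel = (positions >= window_start) & (positions < window_end)
    pos = positions[sel]
    cnt = counts[sel]
    off = (pos - window_start) % register
    on_lattice = (off <= tolerance) | (off >= register - tolerance)
    n_phased = int(cnt[on_lattice].sum())
    n_unphased = int(cnt[~on_lattice].sum())
    k = len(np.unique((pos[on_lattice] - window_start) // register))
    if k < 3:
        return 0.0, k, n_phased, n_unphased
    p = (k - 2) * math.log(1.0 + 10.0 * n_phased / (1.0 + n_unphased))
    return p, k, n_phased, n_unphased


def call_phased_loci(reads: pd.DataFrame,
                     register: int,
                     threshold: float,
                     k_min: int = 4,
                     cycles: int = 9,
                     tolerance: int = 1) -> list[PhasedLocus]:
    """Score read-anchored windows and merge qualifying ones into loci.

    Each distinct 5'-end position anchors one scoring window (so the
    register lattice is phased to an observed read); a window qualifies
    with score >= ``threshold`` and k >= ``k_min``.  Overlapping
    qualifying windows merge into one locus that keeps the best window's
    statistics.
    """
    loci: list[PhasedLocus] = []
    if reads.empty:
        return loci
    for chrom, sub in reads.groupby("chrom"):
        pos = sub["position"].to_numpy(dtype=int)
        cnt = sub["count"].to_numpy(dtype=int)
        span = cycles * register
        current: PhasedLocus | None = None
        for ws in np.unique(pos):
            ws = int(ws)
            p, k, np_, nu = phase_score(pos, cnt, ws, register,
                                        cycles=cycles, tolerance=tolerance)
            if p >= threshold and k >= k_min:
                iv = (ws, ws + span)
                if current is not None and iv[0] <= current.interval[1]:
                    better = p > current.score
                    current = PhasedLocus(
                        chrom=chrom,
                        interval=(current.interval[0], iv[1]),
                        register=register,
                        score=max(p, current.score),
                        k=k if better else current.k,
                        n_phased=np_ if better else current.n_phased,
                        n_unphased=nu if better else current.n_unphased)
                else:
                    if current is not None:
                        loci.append(current)
                    current = PhasedLocus(chrom=chrom, interval=iv,
                                          register=register, score=p, k=k,
                                          n_phased=np_, n_unphased=nu)
        if current is not None:
            loci.append(current)
    return loci


def _pair_penalty(srna_base: str, mrna_base: str) -> float:
    """0 for a Watson-Crick pair, 0.5 for G:U wobble, 1.0 for a mismatch."""
    if _COMPLEMENT.get(srna_base) == mrna_base:
        return 0.0
    if (srna_base, mrna_base) in (("G", "T"), ("T", "G")):
        return 0.5
    return 1.0


def target_score(srna: str, mrna_window: str,
                 seed: tuple[int, int] = (2, 13)) -> float:
    """Expectation score of a small RNA against an equal-length mRNA window.

    The small RNA (5'->3') pairs antiparallel with the window: sRNA
    position i (1-based from the 5' end) faces window position L-i.
    Penalties within sRNA positions ``seed[0]..seed[1]`` are doubled.
    Gapless scoring: the window must match the sRNA length (gapped sites
    are scored by :func:`scan_targets` via window shifts costing the gap
    penalty).
    """
    srna = srna.upper().replace("U", "T")
    if any(b not in "ACGT" for b in srna):
        raise ValueError(f"ambiguous base in small RNA {srna}")
    if len(mrna_window) != len(srna):
        raise ValueError("window length must equal sRNA length")
    w = mrna_window.upper().replace("U", "T")
    total = 0.0
    n = len(srna)
    for i in range(1, n + 1):
        pen = _pair_penalty(srna[i - 1], w[n - i])
        if seed[0] <= i <= seed[1]:
            pen *= 2.0
        total += pen
    return total


def scan_targets(srna_id: str, srna: str, mrna_id: str, mrna: str,
                 cutoff: float = 5.0) -> list[TargetSite]:
    """All non-overlapping target sites of one small RNA on one mRNA.

    The sRNA is slid across the mRNA; each window is scored with
    :func:`target_score` and sites with score <= ``cutoff`` are kept,
    greedily non-overlapping best-first.
    """
    if not 15 <= len(srna) <= 30:
        raise ValueError("small RNA length outside 15-30 nt")
    mrna = mrna.upper().replace("U", "T")
    n = len(srna)
    hits = []
    for start in range(0, len(mrna) - n + 1):
        s = target_score(srna, mrna[start:start + n])
        if s <= cutoff:
            hits.append((s, start))
    hits.sort()
    taken: list[tuple[int, int]] = []
    sites = []
    for s, start in hits:
        iv = (start, start + n)
        if any(iv[0] < b and iv[1] > a for a, b in taken):
            continue
        taken.append(iv)
        sites.append(TargetSite(srna_id=srna_id, mrna_id=mrna_id,
                                interval=iv, score=s))
    sites.sort(key=lambda t: t.interval[0])
    return sites


def top_abundant(reads: pd.DataFrame, n: int = 300) -> pd.DataFrame:
    """The ``n`` distinct small-RNA sequences with the largest summed count."""
    agg = (reads.groupby(["sequence", "length"], as_index=False)["count"].sum()
           .sort_values(["count", "sequence"], ascending=[False, True]))
    return agg.head(n).reset_index(drop=True)


def synergy_compare(te_by_transcript: dict[str, float],
                    m6a_ids: set[str],
                    target_ids: set[str],
                    site_in_peak_ids: set[str]) -> pd.DataFrame:
    """Group TEs and pairwise rank-sum p-values for the synergy analysis.

    Groups: m6A-only, target-only, both, both_site_in_peak (targets inside
    a consensus peak), neither.  Comparisons with an empty group are
    skipped with a note.
    """
    groups: dict[str, list[float]] = {
        "m6A_only": [], "target_only": [], "both": [],
        "both_site_in_peak": [], "neither": []}
    for tid, te in te_by_transcript.items():
        if te is None or not np.isfinite(te):
            continue
        m, t = tid in m6a_ids, tid in target_ids
        if m and t:
            groups["both"].append(te)
            if tid in site_in_peak_ids:
                groups["both_site_in_peak"].append(te)
        elif m:
            groups["m6A_only"].append(te)
        elif t:
            groups["target_only"].append(te)
        else:
            groups["neither"].append(te)
    names = list(groups)
    rows = []
    for i, ga in enumerate(names):
        for gb in names[i + 1:]:
            a, b = groups[ga], groups[gb]
            row = dict(group_a=ga, group_b=gb, n_a=len(a), n_b=len(b))
            if not a or not b:
                row.update(median_a=np.nan, median_b=np.nan,
                           mean_a=np.nan, mean_b=np.nan,
                           p=np.nan, note="empty group")
            else:
                _, p, _ = ranksum(a, b)
                row.update(median_a=float(np.median(a)), median_b=float(np.median(b)),
                           mean_a=float(np.mean(a)), mean_b=float(np.mean(b)),
                           p=p, note="")
            rows.append(row)
    return pd.DataFrame(rows)
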