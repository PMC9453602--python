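"""m6A peak calling from IP vs input window counts.

Per replicate, each fixed-width transcript window is tested for IP
enrichment against a Poisson null whose mean is the (library-size scaled,
floored) input count — the ChIP-seq-style local-lambda test — followed by
Benjamini-Hochberg correction over all windows of the replicate.
Significant windows are merged into peaks, and peaks present in at least
``consensus_min`` replicates (any >=1 nt overlap) form the replicate
consensus used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class WindowTest:
    """One IP-vs-input window test."""

    transcript_id: str
    window: tuple[int, int]
    ip_count: int
    input_count: int
    lam: float
    p: float
    q: float = 1.0


@dataclass
class PeakCall:
    """A (per-replicate or consensus) m6A peak in transcript coordinates."""

    transcript_id: str
    interval: tuple[int, int]
    summit: int
    q_min: float
    supporting_replicates: frozenset = field(default_factory=frozenset)
    region_label: str | None = None

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


def test_windows(windows: pd.DataFrame,
                 ip_library_size: int | None = None,
                 input_library_size: int | None = None,
                 lambda_floor: float = 0.25) -> list[WindowTest]:
    """Poisson upper-tail test of IP enrichment for each window.

    ``windows`` needs columns transcript_id, start, end, ip_count,
    input_count.  The null mean is
    ``lambda = input_count * ip_library_size / input_library_size``,
    floored at ``lambda_floor``; p = P(Poisson(lambda) >= ip_count).
    Library sizes default to the column sums.  q is BH-adjusted over all
    windows passed in (one replicate's worth).
    """
    ip = windows["ip_count"].to_numpy(dtype=float)
    inp = windows["input_count"].to_numpy(dtype=float)
    if ip_library_size is None:
        ip_library_size = int(ip.sum())
    if input_library_size is None:
        input_library_size = int(inp.sum())
    if ip_library_size <= 0:
        raise ValueError("IP library size is zero")
    if input_library_size <= 0:
        raise ValueError("input library size is zero")

    lam = np.maximum(inp * (ip_library_size / input_library_size), lambda_floor)
    # P(X >= k) = sf(k - 1)
    p = sps.poisson.sf(ip - 1, lam)
    p = np.clip(p, 0.0, 1.0)
    q = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])

    out = []
    for i, row in enumerate(windows.itertuples(index=False)):
        out.append(WindowTest(
            transcript_id=row.transcript_id,
            window=(int(row.start), int(row.end)),
            ip_count=int(row.ip_count), input_count=int(row.input_count),
            lam=float(lam[i]), p=float(p[i]), q=float(q[i])))
    return out


def merge_windows(tests: list[WindowTest],
                  q_threshold: float = 0.05,
                  max_gap: int = 50,
                  min_len: int = 100) -> list[PeakCall]:
    """Merge significant windows of one replicate into peaks.

    Maximal runs of windows with ``q < q_threshold`` whose inter-window gap
    is <= ``max_gap`` nt form one peak, trimmed to the covered extent; runs
    shorter than ``min_len`` are dropped.  The summit is the midpoint of
    the run's best (lowest-q, ties by higher IP count) window.
    """
    sig = [t for t in tests if t.q < q_threshold]
    sig.sort(key=lambda t: (t.transcript_id, t.window[0]))
    peaks: list[PeakCall] = []
    run: list[WindowTest] = []

    def flush(run: list[WindowTest]) -> None:
        if not run:
            return
        start = min(t.window[0] for t in run)
        end = max(t.window[1] for t in run)
        if end - start < min_len:
            return
        best = min(run, key=lambda t: (t.q, -t.ip_count))
        peaks.append(PeakCall(
            transcript_id=run[0].transcript_id,
            interval=(start, end),
            summit=(best.window[0] + best.window[1]) // 2,
            q_min=min(t.q for t in run)))

    for t in sig:
        if run and (t.transcript_id != run[-1].transcript_id
                    or t.window[0] - run[-1].window[1] > max_gap):
            flush(run)
            run = []
        run.append(t)
    flush(run)
    return peaks


def consensus(replicate_peaks: list[list[PeakCall]],
              min_support: int = 2) -> list[PeakCall]:
    """Replicate-consensus peaks.

    Peaks from all replicates are clustered per transcript by transitive
    >=1-nt overlap; clusters supported by >= ``min_support`` distinct
    replicates are kept, with the consensus interval the union (envelope)
    of the supporting intervals and ``q_min`` the best q across them.
    """
    if min_support > len(replicate_peaks):
        raise ValueError(
            f"min_support={min_support} exceeds {len(replicate_peaks)} replicates")

    tagged: list[tuple[int, PeakCall]] = []
    for rep, plist in enumerate(replicate_peaks):
        tagged.extend((rep, p) for p in plist)
    tagged.sort(key=lambda rp: (rp[1].transcript_id, rp[1].interval[0]))

    out: list[PeakCall] = []
    cluster: list[tuple[int, PeakCall]] = []

    def flush(cluster: list[tuple[int, PeakCall]]) -> None:
        reps = frozenset(r for r, _ in cluster)
        if len(reps) < min_support:
            return
        start = min(p.interval[0] for _, p in cluster)
        end = max(p.interval[1] for _, p in cluster)
        best = min((p for _, p in cluster), key=lambda p: p.q_min)
        out.append(PeakCall(
            transcript_id=cluster[0][1].transcript_id,
            interval=(start, end), summit=best.summit, q_min=best.q_min,
            supporting_replicates=reps))

    cluster_end = -1
    for rep, p in tagged:
        if cluster and (p.transcript_id != cluster[0][1].transcript_id
                        or p.interval[0] >= cluster_end):
            flush(cluster)
            cluster = []
            cluster_end = -1
        cluster.append((rep, p))
        cluster_end = max(cluster_end, p.interval[1])
    flush(cluster)
    out.sort(key=lambda p: (p.transcript_id, p.interval[0]))
    return out


def call_peaks(window_counts: pd.DataFrame,
               q_threshold: float = 0.05,
               max_gap: int = 50,
               min_len: int = 100,
               lambda_floor: float = 0.25,
               consensus_min: int = 2) -> tuple[list[PeakCall], list[list[PeakCall]]]:
    """Full per-replicate + consensus peak calling from a window count table.

    ``window_counts`` is long-format with columns transcript_id, start,
    end, replicate, library (IP/input), count.  Returns (consensus peaks,
    per-replicate peak lists).
    """
    wide = window_counts.pivot_table(
        index=["transcript_id", "start", "end", "replicate"],
        columns="library", values="count", fill_value=0).reset_index()
    for col in ("IP", "input"):
        if col not in wide.columns:
            raise ValueError(f"window count table lacks {col} library")
    wide = wide.rename(columns={"IP": "ip_count", "input": "input_count"})

    per_rep: list[list[PeakCall]] = []
    for rep in sorted(wide["replicate"].unique()):
        sub = wide[wide["replicate"] == rep]
        tests = test_windows(sub, lambda_floor=lambda_floor)
        per_rep.append(merge_windows(tests, q_threshold=q_threshold,
                                     max_gap=max_gap, min_len=min_len))
    cons = consensus(per_rep, min_support=consensus_min)
    return cons, per_rep
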