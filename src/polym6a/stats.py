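"""Shared statistical kernels and the comparison-report assembler.

Hypergeometric term enrichment with Benjamini-Hochberg FDR, two-sided
rank-sum tests (exact enumeration for small tie-free samples, normal
approximation with tie correction otherwise), Pearson/Spearman
correlation, and the per-region report table comparing methylated and
non-methylated transcripts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

REPORT_REGIONS = ("5'UTR", "start_codon", "CDS", "stop_codon", "3'UTR", "All")


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    universe: int
    term_size: int
    selection: int
    overlap: int
    p: float
    q: float = 1.0


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(selection: set[str],
                     annotation: pd.DataFrame,
                     universe: set[str],
                     namespace_col: str | None = None) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of each term in the selection.

    p = P(X >= k) with X ~ Hypergeom(N=len(universe), K=term size,
    n=len(selection)); BH correction is applied across the tested terms,
    within each namespace separately when ``namespace_col`` is given.
    Terms with no gene in the universe are skipped.
    """
    outside = selection - universe
    if outside:
        raise ValueError(f"selection genes outside universe: {sorted(outside)[:5]}")
    ann = annotation[annotation["gene_id"].isin(universe)]
    results: list[EnrichmentResult] = []
    big_n, n = len(universe), len(selection)
    for (term_id, term_name), genes in ann.groupby(["term_id", "term_name"])["gene_id"]:
        gset = set(genes)
        big_k = len(gset)
        if big_k == 0:
            continue
        k = len(gset & selection)
        # P(X >= k) = sf(k - 1)
        p = float(sps.hypergeom.sf(k - 1, big_n, big_k, n))
        results.append(EnrichmentResult(
            term_id=term_id, term_name=term_name, universe=big_n,
            term_size=big_k, selection=n, overlap=k, p=min(1.0, max(p, 0.0))))
    if namespace_col and namespace_col in annotation.columns:
        ns_of = annotation.drop_duplicates("term_id").set_index("term_id")[namespace_col]
        for ns in ns_of.unique():
            idx = [i for i, r in enumerate(results) if ns_of.get(r.term_id) == ns]
            q = bh_adjust([results[i].p for i in idx])
            for i, qi in zip(idx, q):
                results[i].q = float(qi)
    else:
        q = bh_adjust([r.p for r in results])
        for r, qi in zip(results, q):
            r.q = float(qi)
    results.sort(key=lambda r: (r.q, r.p, r.term_id))
    return results


def ranksum(x, y) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when n_x + n_y <= 20 and there are no ties; normal
    approximation with tie correction otherwise.  Returns (U statistic,
    two-sided p, method used).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2.0), 1.0, "degenerate"
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) + len(y) <= 20 and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "exact"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue), "normal"


def correlate(x, y, method: str = "spearman") -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p.

    Pairs with an undefined member are dropped (count logged); raises on
    zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("correlate: dropped %d incomplete pairs", dropped)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def build_report(profiles: pd.DataFrame,
                 region_of: dict[str, str],
                 min_group: int = 3) -> pd.DataFrame:
    """Per-region comparison of methylated vs non-methylated transcripts.

    For each region group (and "All" = any methylated transcript):
    rank-sum p of input abundance and of TE against the non-methylated
    set, plus Spearman correlations (R, p) of methylation extent against
    abundance and against TE within the group.  Groups below ``min_group``
    quantifiable members yield NA cells.
    """
    q = profiles[profiles["quantifiable"]]
    non = q[~q["is_methylated"]]
    rows = []
    for region in REPORT_REGIONS:
        if region == "All":
            grp = q[q["is_methylated"]]
        else:
            ids = {t for t, r in region_of.items() if r == region}
            grp = q[q["transcript_id"].isin(ids)]
        row = dict(region=region, n=len(grp))
        if len(grp) < min_group or len(non) < min_group:
            row.update(p_abundance=np.nan, p_te=np.nan,
                       r_extent_abundance=np.nan, p_extent_abundance=np.nan,
                       r_extent_te=np.nan, p_extent_te=np.nan)
            rows.append(row)
            continue
        _, p_ab, _ = ranksum(grp["fpkm_input"], non["fpkm_input"])
        te_g = grp["te"].dropna()
        te_n = non["te"].dropna()
        _, p_te, _ = ranksum(te_g, te_n)
        r1, p1 = correlate(grp["extent"], grp["fpkm_input"], "spearman")
        r2, p2 = correlate(grp["extent"], grp["te"], "spearman")
        row.update(p_abundance=p_ab, p_te=p_te,
                   r_extent_abundance=r1, p_extent_abundance=p1,
                   r_extent_te=r2, p_extent_te=p2)
        rows.append(row)
    return pd.DataFrame(rows)
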