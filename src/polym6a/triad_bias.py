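"""Homoeolog-triad bias classification on the A:B:D simplex.

A triad's signal values (v_A, v_B, v_D) are normalized to relative
proportions r = v / sum(v) and assigned to the nearest of seven ideal
points by Euclidean distance: Balanced (1/3,1/3,1/3), the three dominant
corners, and the three suppressed edge midpoints.  The same classifier is
applied to each signal (m6A extent, RNA abundance, RNC abundance), and the
per-signal categories are cross-tabulated as row percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = (
    "Balanced",
    "A-dominant", "B-dominant", "D-dominant",
    "A-suppressed", "B-suppressed", "D-suppressed",
)

CENTROIDS: dict[str, np.ndarray] = {
    "Balanced": np.array([1 / 3, 1 / 3, 1 / 3]),
    "A-dominant": np.array([1.0, 0.0, 0.0]),
    "B-dominant": np.array([0.0, 1.0, 0.0]),
    "D-dominant": np.array([0.0, 0.0, 1.0]),
    "A-suppressed": np.array([0.0, 0.5, 0.5]),
    "B-suppressed": np.array([0.5, 0.0, 0.5]),
    "D-suppressed": np.array([0.5, 0.5, 0.0]),
}


@dataclass
class TriadClassification:
    category: str
    r: tuple[float, float, float]
    distance: float
    tie: bool = False


def classify_triad(v) -> TriadClassification:
    """Nearest-centroid category for one (v_A, v_B, v_D) value triple.

    Scale-invariant: classify(k*v) == classify(v) for k > 0.  Ties are
    broken by the fixed category order (Balanced first) and flagged.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (3,) or (v < 0).any():
        raise ValueError(f"need three non-negative values, got {v}")
    total = v.sum()
    if total <= 0:
        raise ValueError("sum of triad values is zero: unclassifiable")
    r = v / total
    dists = {c: float(np.linalg.norm(r - CENTROIDS[c])) for c in CATEGORIES}
    best = min(CATEGORIES, key=lambda c: dists[c])
    d = dists[best]
    tie = sum(1 for c in CATEGORIES if abs(dists[c] - d) < 1e-12) > 1
    return TriadClassification(category=best, r=tuple(r), distance=d, tie=tie)


def classify_triads(triads: pd.DataFrame,
                    values: dict[str, float],
                    signal: str = "m6A",
                    default: float = 0.0) -> pd.DataFrame:
    """Classify every triad in a triad table under one signal.

    ``values`` maps gene_id -> signal value; genes absent from the mapping
    take ``default`` (for the m6A signal, genes with no consensus peak
    enter as extent 0).  Triads with an all-zero triple are excluded with
    a logged count.
    """
    rows = []
    n_zero = 0
    for t in triads.itertuples(index=False):
        v = [values.get(t.gene_A, default),
             values.get(t.gene_B, default),
             values.get(t.gene_D, default)]
        if sum(v) <= 0:
            n_zero += 1
            continue
        c = classify_triad(v)
        rows.append(dict(
            triad_id=t.triad_id, syntenic=bool(t.syntenic), signal=signal,
            v_A=v[0], v_B=v[1], v_D=v[2],
            r_A=c.r[0], r_B=c.r[1], r_D=c.r[2],
            category=c.category, distance=c.distance, tie=c.tie))
    if n_zero:
        logger.info("classify_triads[%s]: %d all-zero triads excluded", signal, n_zero)
    return pd.DataFrame(rows)


def triad_inclusion(triads: pd.DataFrame,
                    methylated_genes: set[str],
                    known_genes: set[str] | None = None) -> pd.DataFrame:
    """Subset of triads with at least one m6A-containing gene.

    A triad qualifies iff >=1 of its three genes carries >=1 consensus
    peak.  Triads naming a gene absent from the annotation are dropped
    with a logged count.
    """
    keep = []
    n_unknown = 0
    for t in triads.itertuples(index=False):
        genes = (t.gene_A, t.gene_B, t.gene_D)
        if known_genes is not None and any(g not in known_genes for g in genes):
            n_unknown += 1
            continue
        if any(g in methylated_genes for g in genes):
            keep.append(t)
    if n_unknown:
        logger.warning("triad_inclusion: %d triads dropped (gene not in annotation)",
                       n_unknown)
    return pd.DataFrame(keep, columns=triads.columns)


def summarize_categories(classified: pd.DataFrame) -> pd.DataFrame:
    """Category x {total, syntenic, non_syntenic} summary with totals row.

    Adds percentage columns for the syntenic split of the grand total.
    """
    rows = []
    for cat in CATEGORIES:
        sub = classified[classified["category"] == cat]
        rows.append(dict(category=cat, total=len(sub),
                         syntenic=int(sub["syntenic"].sum()),
                         non_syntenic=int((~sub["syntenic"]).sum())))
    df = pd.DataFrame(rows)
    total = dict(category="Total", total=int(df["total"].sum()),
                 syntenic=int(df["syntenic"].sum()),
                 non_syntenic=int(df["non_syntenic"].sum()))
    df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    grand = total["total"]
    df["syntenic_pct"] = np.where(grand > 0, 100.0 * df["syntenic"] / grand, 0.0)
    df["non_syntenic_pct"] = np.where(grand > 0, 100.0 * df["non_syntenic"] / grand, 0.0)
    return df


def check_summary_consistency(per_category: dict[str, tuple[int, int]]) -> dict:
    """Recompute totals/percentages from per-category (total, syntenic) counts.

    Returns the implied grand totals, non-syntenic counts and the syntenic /
    non-syntenic percentages — the arithmetic a published triad summary
    table must satisfy internally.
    """
    total = sum(t for t, _ in per_category.values())
    syntenic = sum(s for _, s in per_category.values())
    non_syntenic = total - syntenic
    return dict(
        total=total, syntenic=syntenic, non_syntenic=non_syntenic,
        syntenic_pct=round(100.0 * syntenic / total, 2) if total else 0.0,
        non_syntenic_pct=round(100.0 * non_syntenic / total, 2) if total else 0.0,
    )


def cross_tabulate(cat_a: pd.DataFrame, cat_b: pd.DataFrame) -> pd.DataFrame:
    """Row-percentage matrix of categories under two signals.

    Rows are ``cat_a`` categories (e.g. m6A), columns ``cat_b`` (e.g. RNA);
    each row is rescaled to percentages summing to 100.  Empty rows are
    kept as zeros.
    """
    merged = cat_a.merge(cat_b, on="triad_id", suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("no triads classified under both signals")
    mat = pd.crosstab(merged["category_a"], merged["category_b"])
    mat = mat.reindex(index=CATEGORIES, columns=CATEGORIES, fill_value=0)
    row_sums = mat.sum(axis=1)
    pct = mat.div(row_sums.replace(0, np.nan), axis=0) * 100.0
    return pct.fillna(0.0)
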