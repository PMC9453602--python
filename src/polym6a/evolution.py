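"""Between-homoeolog Ka/Ks and within-population diversity statistics.

Ka/Ks follows Nei & Gojobori (1986): per-codon synonymous/nonsynonymous
site fractions averaged over both sequences, observed differences averaged
with equal weight over all minimal mutational pathways between each codon
pair (pathways through stop codons excluded when any stop-free pathway
exists), and the Jukes-Cantor correction d = -3/4 ln(1 - 4p/3) applied to
both proportions.

Population statistics operate on a biallelic haplotype matrix:
per-site-averaged nucleotide diversity pi, Tajima's (1989) D contrasting
pairwise diversity with Watterson's estimator, and the Weir & Cockerham
(1984) variance-components Fst for haploid allele samples, aggregated per
gene as a ratio of sums and clamped at zero (the raw value is retained for
audit).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .interface_io import HaplotypeMatrix
from .stats import ranksum

_BASES = "ACGT"

_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Seq import Seq
        for c in ("".join(t) for t in itertools.product(_BASES, repeat=3)):
            _CODON_TABLE[c] = str(Seq(c).translate())
    return _CODON_TABLE


def _syn_fraction(codon: str) -> float:
    """Synonymous site count of one codon (0..3).

    Per position, the fraction of the three single-base changes that
    preserve the amino acid; changes creating a stop codon count as
    nonsynonymous.
    """
    table = _codon_table()
    aa = table[codon]
    s = 0.0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if table[alt] != "*" and table[alt] == aa:
                s += 1 / 3
    return s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) between two codons, averaged over minimal pathways.

    Pathways visiting a stop codon are excluded unless every pathway does.
    """
    table = _codon_table()
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if table[nxt] == "*" and nxt != c2:
                blocked = True
            if table[cur] == table[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    open_paths = [(s, n) for s, n, b in paths if not b]
    if not open_paths:
        open_paths = [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in open_paths) / len(open_paths)
    nd = sum(n for _, n in open_paths) / len(open_paths)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class KaKsResult:
    ka: float
    ks: float
    ratio: float | None         # None when Ks == 0 or a correction is undefined
    s_sites: float
    n_sites: float
    sd: float
    nd: float


def kaks_ng86(cds_a: str, cds_b: str) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks for two aligned, gapless coding sequences."""
    cds_a, cds_b = cds_a.upper().replace("U", "T"), cds_b.upper().replace("U", "T")
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences differ in length; align first")
    if len(cds_a) % 3:
        raise ValueError("length not a multiple of 3")
    table = _codon_table()
    codons_a = [cds_a[i:i + 3] for i in range(0, len(cds_a), 3)]
    codons_b = [cds_b[i:i + 3] for i in range(0, len(cds_b), 3)]
    for c in codons_a[:-1] + codons_b[:-1]:
        if table[c] == "*":
            raise ValueError(f"internal stop codon {c}")
    # drop a shared terminal stop if present
    if table[codons_a[-1]] == "*" and table[codons_b[-1]] == "*":
        codons_a, codons_b = codons_a[:-1], codons_b[:-1]

    s_sites = 0.5 * (sum(map(_syn_fraction, codons_a))
                     + sum(map(_syn_fraction, codons_b)))
    n_sites = 3.0 * len(codons_a) - s_sites
    sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        dsd, dnd = _pathway_counts(ca, cb)
        sd += dsd
        nd += dnd
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    ratio: float | None
    if math.isnan(ka) or math.isnan(ks) or ks == 0.0:
        ratio = None
    else:
        ratio = ka / ks
    return KaKsResult(ka=ka, ks=ks, ratio=ratio,
                      s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd)


def align_codons(cds_a: str, cds_b: str) -> tuple[str, str]:
    """Codon-aware pairwise alignment, gap columns removed.

    Sequences are aligned at the protein level with end-gap-free global
    scoring, the alignment is back-projected to codons and every column
    containing a gap is discarded, leaving two equal-length gapless coding
    sequences ready for :func:`kaks_ng86`.
    """
    from Bio.Align import PairwiseAligner
    from Bio.Seq import Seq

    a = cds_a.upper().replace("U", "T")
    b = cds_b.upper().replace("U", "T")
    a = a[: 3 * (len(a) // 3)]
    b = b[: 3 * (len(b) // 3)]
    prot_a = str(Seq(a).translate()).rstrip("*")
    prot_b = str(Seq(b).translate()).rstrip("*")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    aligner.end_gap_score = 0.0
    aln = aligner.align(prot_a, prot_b)[0]
    out_a, out_b = [], []
    ia = ib = 0
    sa, sb = str(aln[0]), str(aln[1])
    for x, y in zip(sa, sb):
        if x != "-" and y != "-":
            out_a.append(a[3 * ia: 3 * ia + 3])
            out_b.append(b[3 * ib: 3 * ib + 3])
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    return "".join(out_a), "".join(out_b)


# ---------------------------------------------------------------------------
# Population statistics
# ---------------------------------------------------------------------------

def _pairwise_heterozygosity(geno: np.ndarray) -> np.ndarray:
    """Per-site expected pairwise difference over complete haplotype pairs."""
    valid = geno >= 0
    n = valid.sum(axis=1).astype(float)
    alt = np.where(valid, geno, 0).sum(axis=1).astype(float)
    ref = n - alt
    pairs = n * (n - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(pairs > 0, ref * alt / pairs, 0.0)
    return h


def pi(haps: HaplotypeMatrix) -> float:
    """Per-site nucleotide diversity over the gene span.

    Mean pairwise difference per site, sites with missing data handled
    pairwise-complete, divided by the span length.
    """
    if haps.n_haplotypes < 2:
        raise ValueError("need >= 2 haplotypes")
    if haps.span <= 0:
        raise ValueError("non-positive span")
    return float(_pairwise_heterozygosity(haps.genotypes).sum()) / haps.span


def tajimas_d(haps: HaplotypeMatrix) -> float | None:
    """Tajima's (1989) D.

    None (undefined, distinct from 0) when there are no segregating sites
    or when the variance term vanishes — which includes the degenerate
    n = 2 case, where c1 = c2 = 0.
    """
    g = haps.genotypes
    n = haps.n_haplotypes
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    ac = haps.allele_counts()
    seg = (ac[:, 0] > 0) & (ac[:, 1] > 0)
    s = int(seg.sum())
    if s == 0:
        return None
    theta_pi = float(_pairwise_heterozygosity(g).sum())
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:
        return None
    return (theta_pi - s / a1) / math.sqrt(var)


def fst_wc(haps: HaplotypeMatrix) -> tuple[float | None, float | None]:
    """Weir-Cockerham (1984) Fst over populations, per-gene ratio of sums.

    Haploid-sample variance components per biallelic site:

        a = (nbar/nc) * [s2 - (pbar*qbar - s2*(r-1)/r)/(nbar-1)]
        b = (nbar/(nbar-1)) * [pbar*qbar - s2*(r-1)/r]

    with the gene estimate sum(a)/sum(a+b).  Returns (raw, clamped>=0);
    (None, None) for a monomorphic gene.
    """
    pops = haps.by_population()
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    mats = list(pops.values())
    r = len(mats)
    sum_a = sum_ab = 0.0
    informative = False
    for site in range(haps.n_sites):
        ns, ps = [], []
        for m in mats:
            g = m.genotypes[site]
            valid = g >= 0
            ni = int(valid.sum())
            if ni < 2:
                break
            ns.append(ni)
            ps.append(float(g[valid].mean()))
        else:
            ns_arr = np.array(ns, dtype=float)
            ps_arr = np.array(ps, dtype=float)
            nbar = ns_arr.mean()
            pbar = float((ns_arr * ps_arr).sum() / ns_arr.sum())
            if pbar in (0.0, 1.0):
                continue
            informative = True
            nc = (ns_arr.sum() - (ns_arr**2).sum() / ns_arr.sum()) / (r - 1)
            s2 = float((ns_arr * (ps_arr - pbar) ** 2).sum() / ((r - 1) * nbar))
            pq = pbar * (1.0 - pbar)
            b = (nbar / (nbar - 1.0)) * (pq - s2 * (r - 1.0) / r)
            a = (nbar / nc) * (s2 - b / nbar) if nc > 0 else 0.0
            sum_a += a
            sum_ab += a + b
    if not informative or sum_ab == 0.0:
        return None, None
    raw = sum_a / sum_ab
    return raw, max(0.0, raw)


def class_compare(values_a: Sequence[float], values_b: Sequence[float],
                  label_a: str = "methylated",
                  label_b: str = "non-methylated") -> dict:
    """Class means/medians and the two-sided rank-sum p between them."""
    a = np.asarray([v for v in values_a if v is not None and not np.isnan(v)])
    b = np.asarray([v for v in values_b if v is not None and not np.isnan(v)])
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both classes must be non-empty")
    stat, p, method = ranksum(a, b)
    return {
        label_a: dict(n=len(a), mean=float(a.mean()), median=float(np.median(a))),
        label_b: dict(n=len(b), mean=float(b.mean()), median=float(np.median(b))),
        "statistic": stat, "p": p, "method": method,
    }
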