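"""Independent brute-force oracles shared by the unit and acceptance suites.

Everything here is deliberately naive (string-based, uncached, O(n^2))
and written separately from the package implementations it checks.
"""

import itertools
import math

import numpy as np
from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_syn_sites(seq: str) -> float:
    s = 0.0
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        for pos in range(3):
            syn = 0
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1:]
                if alt not in STOPS and aa(alt) == aa(codon):
                    syn += 1
            s += syn / 3.0
    return s


def oracle_path_diffs(seq_a: str, seq_b: str) -> tuple[float, float]:
    sd = nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        diff = [p for p in range(3) if ca[p] != cb[p]]
        if not diff:
            continue
        paths = []
        for order in itertools.permutations(diff):
            cur, s, n, blocked = ca, 0, 0, False
            for p in order:
                nxt = cur[:p] + cb[p] + cur[p + 1:]
                if nxt in STOPS and nxt != cb:
                    blocked = True
                if aa(cur) == aa(nxt):
                    s += 1
                else:
                    n += 1
                cur = nxt
            paths.append((s, n, blocked))
        ok = [(s, n) for s, n, b in paths if not b] or [(s, n) for s, n, _ in paths]
        sd += sum(s for s, _ in ok) / len(ok)
        nd += sum(n for _, n in ok) / len(ok)
    return sd, nd


def oracle_kaks(seq_a: str, seq_b: str) -> tuple[float, float]:
    """(Ka, Ks) by full pathway enumeration + Jukes-Cantor."""
    s_sites = 0.5 * (oracle_syn_sites(seq_a) + oracle_syn_sites(seq_b))
    n_sites = len(seq_a) - s_sites
    sd, nd = oracle_path_diffs(seq_a, seq_b)

    def jc(p):
        return -0.75 * math.log(1 - 4 * p / 3)

    return jc(nd / n_sites), jc(sd / s_sites)


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = []
    while len(codons) < n_codons:
        c = "".join("ACGT"[i] for i in rng.integers(0, 4, 3))
        if c not in STOPS:
            codons.append(c)
    return "".join(codons)


def mutate_cds(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    seq = list(seq)
    tried = set()
    done = 0
    while done < n_mut:
        i = int(rng.integers(0, len(seq)))
        if i in tried:
            continue
        tried.add(i)
        b = "ACGT"[rng.integers(0, 4)]
        old = seq[i]
        seq[i] = b
        codon = "".join(seq[3 * (i // 3): 3 * (i // 3) + 3])
        if codon in STOPS or b == old:
            seq[i] = old
            continue
        done += 1
    return "".join(seq)


def oracle_pi(geno: np.ndarray, span: int) -> float:
    """Per-site mean pairwise difference over complete pairs, / span."""
    total = 0.0
    for site in geno:
        vals = [v for v in site if v >= 0]
        pairs = diffs = 0
        for i, j in itertools.combinations(range(len(vals)), 2):
            pairs += 1
            diffs += vals[i] != vals[j]
        if pairs:
            total += diffs / pairs
    return total / span


def oracle_tajima(geno: np.ndarray, span: int):
    """Direct evaluation of the 1989 formula; None when S = 0 or var <= 0."""
    n = geno.shape[1]
    s = sum(1 for site in geno if 0 < sum(site) < n)
    if s == 0:
        return None
    theta_pi = oracle_pi(geno, span) * span
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:
        return None
    return (theta_pi - s / a1) / math.sqrt(var)
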