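"""Synthetic polyploid m6A / translatome / small-RNA datasets with planted truth.

The generator emulates the statistical structure the analysis assumes:

- a triad genome: three homoeologous copies (subgenomes A/B/D) of every
  gene, with configurable per-site coding divergence, spliced two-exon
  gene models and UTR/CDS structure;
- planted m6A peaks: per methylated triad a bias category is drawn and the
  genes' methylation extents are placed at the category's simplex centroid
  (plus noise); each methylated gene gets one peak interval in a chosen
  transcript region, with RRACH motifs written into it;
- IP / input / RNC counts: negative-binomial window counts whose IP mean
  is ``extent x input mean`` inside planted peaks and a small background
  elsewhere; RNC totals follow a planted translation-efficiency model
  log TE = log(mu) + beta_region * extent + srna_effect + noise;
- small RNA reads: background reads plus phased loci on a 21- or 24-nt
  register, and miRNAs that are exact reverse complements of chosen mRNA
  sites (optionally inside peaks);
- population haplotypes: per-gene coalescent simulations (msprime) in a
  two-deme island model, with the methylated gene class given a lower
  scaled mutation rate than the non-methylated class.

Identical seeds give byte-identical outputs; every planted effect is
recorded in :class:`GroundTruth`.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import interface_io
from .interface_io import HaplotypeMatrix, TranscriptModel
from .triad_bias import CATEGORIES, CENTROIDS

REGIONS = ("5'UTR", "start_codon", "CDS", "stop_codon", "3'UTR")
_COMP = str.maketrans("ACGT", "TGCA")
_COMP_MAP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    n_triads: int = 100
    n_methylated_triads: int = 40
    replicates: int = 3
    # transcript structure (nt)
    utr5_range: tuple[int, int] = (160, 320)
    cds_codon_range: tuple[int, int] = (150, 400)
    utr3_range: tuple[int, int] = (200, 450)
    divergence: float = 0.02          # per-site homoeolog divergence
    # planted peaks
    peak_fold: float = 8.0            # IP enrichment over input inside peaks;
                                      # <=1 means a null run (nothing planted)
    peak_width: int = 120
    peak_margin: int = 30             # min distance of a UTR/CDS peak from codons
    extent_log_sd: float = 0.4        # lognormal spread of per-triad extent
    region_weights: dict = field(default_factory=lambda: {
        "5'UTR": 0.1, "start_codon": 0.1, "CDS": 0.45,
        "stop_codon": 0.25, "3'UTR": 0.1})
    category_weights: dict = field(default_factory=lambda: {
        "Balanced": 0.10,
        "A-dominant": 0.20, "B-dominant": 0.20, "D-dominant": 0.20,
        "A-suppressed": 0.10, "B-suppressed": 0.10, "D-suppressed": 0.10})
    triad_noise_sd: float = 0.05      # simplex noise around the centroid
    methylated_r_min: float = 0.1     # r above this gets a planted peak
    # sequencing depth / noise
    window: int = 25
    input_depth: float = 20.0         # mean input fragments per window
    ip_background: float = 0.002      # off-peak IP background relative to input
    nb_dispersion: float = 0.05       # NB variance = mu + disp*mu^2; 0 -> Poisson
    abund_log_sd: float = 0.5         # lognormal spread of per-triad abundance
    # translation-efficiency model
    te_mu: float = 9.0
    beta_region: dict = field(default_factory=lambda: {
        "5'UTR": 0.03, "start_codon": 0.03, "CDS": -0.03,
        "stop_codon": -0.03, "3'UTR": -0.03})
    beta_expr: float = -0.05          # extent -> log input abundance
    te_noise_sd: float = 0.3
    srna_te_effect: float = -0.8      # log-TE shift for sRNA-targeted mRNAs
    srna_m6a_interaction: float = 0.0 # extra shift when both (0 = additive null)
    # small RNA
    n_phased_loci_21: int = 2
    n_phased_loci_24: int = 2
    phased_cycles_occupied: int = 8
    phased_locus_depth: int = 10
    n_background_reads: int = 600
    n_mirna: int = 10
    targets_per_mirna: int = 8
    mirna_length: int = 21
    site_in_peak_prob: float = 0.5
    # population
    n_pops: int = 2
    samples_per_pop: int = 8          # diploid individuals per population
    pop_gene_length: int = 2000
    theta_methylated: float = 0.002   # per-site scaled mutation rate 4*Ne*mu
    theta_nonmethylated: float = 0.003
    fst_target: float = 0.05          # 0 -> panmictic (labels only)
    pop_genes_per_class: int = 100

    def __post_init__(self) -> None:
        if self.n_triads < 1:
            raise ValueError("n_triads must be >= 1")
        if self.samples_per_pop < 1:
            raise ValueError("samples_per_pop must be >= 1")


@dataclass
class GroundTruth:
    """Everything that was planted, for downstream validation."""

    peaks: list = field(default_factory=list)       # dicts: transcript_id, start, end, region, fold
    extent: dict = field(default_factory=dict)      # transcript_id -> planted extent (0 if none)
    peak_region: dict = field(default_factory=dict) # transcript_id -> region
    m6a_category: dict = field(default_factory=dict)
    rna_category: dict = field(default_factory=dict)
    rnc_category: dict = field(default_factory=dict)
    true_te: dict = field(default_factory=dict)     # transcript_id -> planted TE
    beta_region: dict = field(default_factory=dict)
    beta_expr: float = 0.0
    srna_te_effect: float = 0.0
    phased_loci: list = field(default_factory=list) # dicts: chrom, start, end, register
    mirna_targets: list = field(default_factory=list)
    target_ids: set = field(default_factory=set)    # transcript ids with an sRNA site
    site_in_peak_ids: set = field(default_factory=set)
    pop_class: dict = field(default_factory=dict)   # gene_id -> methylated / non-methylated
    pop_theta: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["target_ids"] = sorted(self.target_ids)
        d["site_in_peak_ids"] = sorted(self.site_in_peak_ids)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)


@dataclass
class SyntheticGenome:
    models: dict[str, TranscriptModel]
    chromosomes: dict[str, str]
    triads: pd.DataFrame


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random CDS: ATG + non-stop codons + TAA."""
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3)
        if c not in stops:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _diverge_cds(rng: np.random.Generator, cds: str, rate: float) -> str:
    """Per-site substitution preserving start/stop and avoiding internal stops."""
    stops = {"TAA", "TAG", "TGA"}
    seq = list(cds)
    n = len(seq)
    hits = np.flatnonzero(rng.random(n) < rate)
    for i in hits:
        if i < 3 or i >= n - 3:
            continue
        old = seq[i]
        new = "ACGT"[rng.integers(0, 4)]
        if new == old:
            continue
        seq[i] = new
        codon_start = 3 * (i // 3)
        if "".join(seq[codon_start:codon_start + 3]) in stops:
            seq[i] = old
    return "".join(seq)


def _repair_internal_stops(seq: list[str], cds_span: tuple[int, int]) -> None:
    """Recode any internal stop codon (e.g. created by motif planting)."""
    stops = {"TAA", "TAG", "TGA"}
    for p in range(cds_span[0], cds_span[1] - 3, 3):
        if "".join(seq[p:p + 3]) in stops:
            seq[p] = "C"


def _plant_motifs(rng: np.random.Generator, seq: list[str],
                  start: int, end: int, spacing: int = 25) -> None:
    """Write RRACH 5-mers into seq[start:end] every ``spacing`` nt."""
    motifs = ["GGACT", "GAACA", "AAACA", "AGACC"]
    pos = start + 2
    while pos + 5 <= end:
        m = motifs[rng.integers(0, len(motifs))]
        seq[pos:pos + 5] = list(m)
        pos += spacing


def _draw_simplex(rng: np.random.Generator, category: str, noise_sd: float) -> np.ndarray:
    r = CENTROIDS[category] + rng.normal(0.0, noise_sd, 3)
    r = np.clip(r, 0.0, None)
    if r.sum() == 0:
        r = np.array([1 / 3, 1 / 3, 1 / 3])
    return r / r.sum()


def generate_genome(config: SyntheticConfig) -> tuple[SyntheticGenome, GroundTruth]:
    """Build the triad genome with planted peaks and bias categories."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    truth = GroundTruth(beta_region=dict(config.beta_region),
                        beta_expr=config.beta_expr,
                        srna_te_effect=config.srna_te_effect)

    cats = list(config.category_weights)
    cat_p = np.array([config.category_weights[c] for c in cats], dtype=float)
    cat_p /= cat_p.sum()
    regions = list(config.region_weights)
    reg_p = np.array([config.region_weights[r] for r in regions], dtype=float)
    reg_p /= reg_p.sum()

    null_run = config.peak_fold <= 1.0
    methylated_triads = set(
        rng.choice(config.n_triads, size=min(config.n_methylated_triads,
                                             config.n_triads), replace=False))

    models: dict[str, TranscriptModel] = {}
    chrom_parts: dict[str, list[str]] = {f"chr1{s}": [] for s in "ABD"}
    chrom_offsets: dict[str, int] = {f"chr1{s}": 0 for s in "ABD"}
    triad_rows = []

    for ti in range(config.n_triads):
        utr5 = int(rng.integers(*config.utr5_range))
        n_codons = int(rng.integers(*config.cds_codon_range))
        utr3 = int(rng.integers(*config.utr3_range))
        cds_a = _random_cds(rng, n_codons)
        tlen = utr5 + len(cds_a) + utr3
        syntenic = bool(rng.random() < 0.9)

        # per-triad m6A plan
        if not null_run and ti in methylated_triads:
            m6a_cat = str(rng.choice(cats, p=cat_p))
            r_m6a = _draw_simplex(rng, m6a_cat, config.triad_noise_sd)
        else:
            m6a_cat, r_m6a = None, np.zeros(3)
        rna_cat = str(rng.choice(cats, p=cat_p))
        r_rna = _draw_simplex(rng, rna_cat, config.triad_noise_sd)
        # shared within the triad so the planted relative triples survive
        extent_mult = math.exp(rng.normal(0.0, config.extent_log_sd))
        abund_mult = math.exp(rng.normal(0.0, config.abund_log_sd))

        gene_ids = []
        for si, sub in enumerate("ABD"):
            gid = f"Tsyn{ti + 1:04d}{sub}"
            tid = f"{gid}.1"
            gene_ids.append(gid)
            cds = cds_a if si == 0 else _diverge_cds(rng, cds_a, config.divergence)
            seq = list(_random_seq(rng, utr5) + cds + _random_seq(rng, utr3))
            cds_span = (utr5, utr5 + len(cds))

            extent = 0.0
            if m6a_cat is not None and r_m6a[si] > config.methylated_r_min:
                extent = 3.0 * r_m6a[si] * config.peak_fold * extent_mult
                region = str(rng.choice(regions, p=reg_p))
                mg = config.peak_margin
                anchor = {
                    "5'UTR": (0, utr5 - mg),
                    "start_codon": (cds_span[0], cds_span[0] + 3),
                    "CDS": (cds_span[0] + 3 + mg, cds_span[1] - 3 - mg),
                    "stop_codon": (cds_span[1] - 3, cds_span[1]),
                    "3'UTR": (cds_span[1] + mg, tlen),
                }[region]
                width = min(config.peak_width, tlen)
                if region in ("start_codon", "stop_codon"):
                    mid = anchor[0] + 1
                else:
                    lo = anchor[0] + width // 2
                    hi = max(lo + 1, anchor[1] - width // 2)
                    mid = int(rng.integers(lo, hi))
                p0 = max(0, mid - width // 2)
                p1 = min(tlen, p0 + width)
                p0 = max(0, p1 - width)
                _plant_motifs(rng, seq, p0, p1)
                _repair_internal_stops(seq, cds_span)
                truth.peaks.append(dict(transcript_id=tid, start=p0, end=p1,
                                        region=region, fold=extent))
                truth.peak_region[tid] = region
            truth.extent[tid] = extent

            # genomic layout: two exons separated by an intron
            strand = "+" if rng.random() < 0.5 else "-"
            e1 = int(rng.integers(tlen // 4, 3 * tlen // 4))
            intron = _random_seq(rng, int(rng.integers(60, 200)))
            tseq = "".join(seq)
            chrom = f"chr1{sub}"
            off = chrom_offsets[chrom] + 100
            if strand == "+":
                chunk = tseq[:e1] + intron + tseq[e1:]
                exons = [(off, off + e1),
                         (off + e1 + len(intron), off + len(tseq) + len(intron))]
            else:
                chunk = _revcomp(tseq[e1:]) + intron + _revcomp(tseq[:e1])
                exons = [(off, off + (tlen - e1)),
                         (off + (tlen - e1) + len(intron),
                          off + tlen + len(intron))]
            chrom_parts[chrom].append("N" * 100 + chunk)
            chrom_offsets[chrom] = off + len(chunk)

            models[tid] = TranscriptModel(
                transcript_id=tid, gene_id=gid, chromosome=chrom,
                strand=strand, exons=exons, cds_span=cds_span,
                sequence=tseq, subgenome=sub)

        if m6a_cat is not None:
            truth.m6a_category[f"triad{ti + 1:04d}"] = m6a_cat
        truth.rna_category[f"triad{ti + 1:04d}"] = rna_cat
        truth.rnc_category[f"triad{ti + 1:04d}"] = rna_cat  # RNC follows RNA
        triad_rows.append(dict(
            triad_id=f"triad{ti + 1:04d}", gene_A=gene_ids[0],
            gene_B=gene_ids[1], gene_D=gene_ids[2], syntenic=syntenic,
            r_rna_A=r_rna[0], r_rna_B=r_rna[1], r_rna_D=r_rna[2],
            abund_mult=abund_mult))

    chromosomes = {c: "".join(parts) for c, parts in chrom_parts.items()}
    triads = pd.DataFrame(triad_rows)
    return SyntheticGenome(models=models, chromosomes=chromosomes,
                           triads=triads), truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, disp: float) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    if disp <= 1e-9:
        return rng.poisson(mean)
    n = 1.0 / disp
    return rng.negative_binomial(n, n / (n + mean))


def generate_counts(config: SyntheticConfig, genome: SyntheticGenome,
                    truth: GroundTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(window_counts, transcript_counts) for IP/input/RNC x replicates."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    w = config.window

    planted = {p["transcript_id"]: (p["start"], p["end"]) for p in truth.peaks}
    r_rna, tri_mult = {}, {}
    for t in genome.triads.itertuples(index=False):
        for sub, gene in (("A", t.gene_A), ("B", t.gene_B), ("D", t.gene_D)):
            tid = f"{gene}.1"
            r_rna[tid] = getattr(t, f"r_rna_{sub}")
            tri_mult[tid] = getattr(t, "abund_mult", 1.0)

    # per-gene expected input fragments per window
    abund = {}
    for tid, model in genome.models.items():
        e = truth.extent.get(tid, 0.0)
        abund[tid] = (config.input_depth * 3.0 * max(r_rna.get(tid, 1 / 3), 0.05)
                      * tri_mult.get(tid, 1.0)
                      * math.exp(config.beta_expr * e))
        # planted TE
        log_te = math.log(config.te_mu) + rng.normal(0.0, config.te_noise_sd)
        region = truth.peak_region.get(tid)
        if region is not None:
            log_te += config.beta_region[region] * e
        if tid in truth.target_ids:
            log_te += config.srna_te_effect
            if region is not None:
                log_te += config.srna_m6a_interaction
        truth.true_te[tid] = math.exp(log_te)

    win_rows = {k: [] for k in ("transcript_id", "start", "end",
                                "replicate", "library", "count")}
    tx_rows = {k: [] for k in ("transcript_id", "replicate", "library", "count")}

    for rep in range(1, config.replicates + 1):
        for tid, model in genome.models.items():
            L = model.length
            starts = np.arange(0, L, w)
            ends = np.minimum(starts + w, L)
            a = abund[tid]
            in_mean = np.full(len(starts), a)
            ip_mean = np.full(len(starts), config.ip_background * a)
            if tid in planted:
                p0, p1 = planted[tid]
                inside = (starts < p1) & (ends > p0)
                ip_mean[inside] = truth.extent[tid] * a
            in_counts = _nb_draw(rng, in_mean, config.nb_dispersion)
            ip_counts = _nb_draw(rng, ip_mean, config.nb_dispersion)
            for lib, cnts in (("input", in_counts), ("IP", ip_counts)):
                nw = len(starts)
                win_rows["transcript_id"].extend([tid] * nw)
                win_rows["start"].extend(starts.tolist())
                win_rows["end"].extend(ends.tolist())
                win_rows["replicate"].extend([rep] * nw)
                win_rows["library"].extend([lib] * nw)
                win_rows["count"].extend(cnts.tolist())
                tx_rows["transcript_id"].append(tid)
                tx_rows["replicate"].append(rep)
                tx_rows["library"].append(lib)
                tx_rows["count"].append(int(cnts.sum()))
            n_win = len(starts)
            rnc_mean = a * n_win * truth.true_te[tid] / config.te_mu
            rnc = int(_nb_draw(rng, np.array([rnc_mean]), config.nb_dispersion)[0])
            tx_rows["transcript_id"].append(tid)
            tx_rows["replicate"].append(rep)
            tx_rows["library"].append("RNC")
            tx_rows["count"].append(rnc)

    return pd.DataFrame(win_rows), pd.DataFrame(tx_rows)


def generate_smallrna(config: SyntheticConfig, genome: SyntheticGenome,
                      truth: GroundTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(small-RNA read table, miRNA table); designates target mRNAs in truth.

    Must run before :func:`generate_counts` so the planted sRNA effect on
    TE is applied to the targeted transcripts.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    rows = []
    chrom_lists: dict[str, list[str]] = {}

    # background reads on a dedicated scaffold
    scaffold = "sRNA_scaffold"
    span = 100_000
    lengths = rng.choice([21, 22, 23, 24, 25],
                         p=[0.15, 0.05, 0.05, 0.70, 0.05],
                         size=config.n_background_reads)
    for i in range(config.n_background_reads):
        rows.append(dict(sequence=_random_seq(rng, int(lengths[i])),
                         length=int(lengths[i]), chrom=scaffold,
                         position=int(rng.integers(0, span)),
                         strand="+", count=int(rng.integers(1, 5))))

    # phased loci
    occupied = config.phased_cycles_occupied
    locus_positions = rng.choice(np.arange(5_000, span - 5_000, 500),
                                 size=config.n_phased_loci_21 + config.n_phased_loci_24,
                                 replace=False)
    registers = ([21] * config.n_phased_loci_21 + [24] * config.n_phased_loci_24)
    for start, register in zip(locus_positions, registers):
        start = int(start)
        cycles = rng.permutation(9)[:occupied]
        for c in sorted(cycles):
            pos = start + int(c) * register
            rows.append(dict(sequence=_random_seq(rng, register),
                             length=register, chrom=scaffold, position=pos,
                             strand="+",
                             count=int(rng.poisson(config.phased_locus_depth)) + 1))
        truth.phased_loci.append(dict(chrom=scaffold, start=start,
                                      end=start + 9 * register,
                                      register=register))

    # miRNAs as exact reverse complements of chosen mRNA sites
    tids = sorted(genome.models)
    planted_peaks = {p["transcript_id"]: (p["start"], p["end"]) for p in truth.peaks}
    mirna_rows = []
    for mi in range(config.n_mirna):
        n_t = min(config.targets_per_mirna, len(tids))
        chosen = rng.choice(len(tids), size=n_t, replace=False)
        # anchor the miRNA on the first chosen transcript's site
        mirna_seq = None
        mid = f"miR{mi + 1:03d}"
        for j, idx in enumerate(chosen):
            tid = tids[idx]
            model = genome.models[tid]
            L = config.mirna_length
            if model.length <= L + 2 or model.cds_span is None:
                continue
            peak = planted_peaks.get(tid)
            if j == 0 or mirna_seq is None:
                # the anchor site defines the miRNA as an exact complement
                if (peak is not None and peak[1] - peak[0] > L + 2
                        and rng.random() < config.site_in_peak_prob):
                    s0 = int(rng.integers(peak[0], peak[1] - L))
                else:
                    s0 = int(rng.integers(0, model.length - L))
                mirna_seq = _revcomp(model.sequence[s0:s0 + L])
            else:
                # additional targets: rewrite a 3'UTR site (keeps the ORF intact)
                utr3 = model.three_utr
                if utr3 is None or utr3[1] - utr3[0] <= L + 2:
                    continue
                s0 = int(rng.integers(utr3[0], utr3[1] - L))
                seq = list(model.sequence)
                seq[s0:s0 + L] = list(_revcomp(mirna_seq))
                model.sequence = "".join(seq)
                # keep the genomic FASTA in sync with the edited transcript
                chrom_seq = chrom_lists.setdefault(
                    model.chromosome, list(genome.chromosomes[model.chromosome]))
                for tpos in range(s0, s0 + L):
                    g = model.transcript_to_genomic(tpos)
                    base = model.sequence[tpos]
                    chrom_seq[g] = (base if model.strand == "+"
                                    else _COMP_MAP[base])
            in_peak = bool(peak and s0 >= peak[0] and s0 + L <= peak[1])
            truth.mirna_targets.append(dict(srna_id=mid, mrna_id=tid,
                                            start=s0, end=s0 + L,
                                            in_peak=in_peak))
            truth.target_ids.add(tid)
            if in_peak:
                truth.site_in_peak_ids.add(tid)
        if mirna_seq is not None:
            mirna_rows.append(dict(srna_id=mid, sequence=mirna_seq,
                                   length=len(mirna_seq),
                                   count=int(rng.integers(10, 60))))
            rows.append(dict(sequence=mirna_seq, length=len(mirna_seq),
                             chrom=scaffold, position=int(rng.integers(0, span)),
                             strand="+", count=mirna_rows[-1]["count"]))
    for chrom, lst in chrom_lists.items():
        genome.chromosomes[chrom] = "".join(lst)
    reads = pd.DataFrame(rows)
    return reads, pd.DataFrame(mirna_rows)


def generate_population(config: SyntheticConfig, genome: SyntheticGenome,
                        truth: GroundTruth
                        ) -> tuple[dict[str, HaplotypeMatrix], dict[str, str]]:
    """Per-gene haplotype matrices from two-deme coalescent simulations.

    Genes with a planted peak form the methylated class (scaled mutation
    rate ``theta_methylated`` per site), an equal-sized sample of
    peak-free genes the non-methylated class.  ``fst_target`` sets the
    island-model migration rate (0 means one panmictic population with
    split labels).  Returns (gene -> HaplotypeMatrix, sample -> population).
    """
    import msprime

    if config.samples_per_pop <= 0:
        raise ValueError("zero samples per population")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    methylated = sorted({p["transcript_id"].rsplit(".", 1)[0] for p in truth.peaks})
    all_genes = sorted({m.gene_id for m in genome.models.values()})
    non_methylated = [g for g in all_genes if g not in set(methylated)]
    n_per = config.pop_genes_per_class
    meth_sel = methylated[:n_per]
    non_sel = non_methylated[:n_per]
    if not meth_sel:  # null runs have no planted peaks: split arbitrarily
        meth_sel = all_genes[:n_per]
        non_sel = all_genes[n_per:2 * n_per]

    ne = 1e4
    n_dip = config.samples_per_pop
    demography = msprime.Demography()
    panmictic = config.fst_target <= 0
    if panmictic:
        demography.add_population(name="pop0", initial_size=ne)
        sample_spec = {"pop0": 2 * n_dip}
    else:
        # two-deme island model: Fst ~ 1 / (1 + 8*N*m)
        nm = (1.0 / config.fst_target - 1.0) / 8.0
        m = nm / ne
        for i in range(config.n_pops):
            demography.add_population(name=f"pop{i}", initial_size=ne)
        demography.set_migration_rate("pop0", "pop1", m)
        demography.set_migration_rate("pop1", "pop0", m)
        sample_spec = {f"pop{i}": n_dip for i in range(config.n_pops)}

    truth.pop_theta = {"methylated": config.theta_methylated,
                       "non-methylated": config.theta_nonmethylated}
    samples = [f"s{i}" for i in range(config.n_pops * n_dip)]
    pop_labels = {s: f"pop{0 if panmictic and i < n_dip else i // n_dip}"
                  for i, s in enumerate(samples)}
    if panmictic:
        pop_labels = {s: f"pop{i // n_dip}" for i, s in enumerate(samples)}

    matrices: dict[str, HaplotypeMatrix] = {}
    per_hap_pops = []
    for s in samples:
        per_hap_pops.extend([pop_labels[s]] * 2)

    for cls, genes, theta in (("methylated", meth_sel, config.theta_methylated),
                              ("non-methylated", non_sel, config.theta_nonmethylated)):
        mu = theta / (4.0 * ne)
        for gid in genes:
            seed1 = int(rng.integers(1, 2**31 - 1))
            seed2 = int(rng.integers(1, 2**31 - 1))
            ts = msprime.sim_ancestry(
                samples=sample_spec, demography=demography,
                sequence_length=config.pop_gene_length,
                recombination_rate=0.0, random_seed=seed1)
            ts = msprime.sim_mutations(ts, rate=mu, random_seed=seed2,
                                       model=msprime.BinaryMutationModel())
            geno = ts.genotype_matrix().astype(np.int8)
            keep = [i for i in range(geno.shape[0])
                    if len(np.unique(geno[i])) <= 2 and geno[i].max() <= 1]
            geno = geno[keep]
            positions = np.array([int(ts.site(i).position) + 1 for i in keep])
            matrices[gid] = HaplotypeMatrix(
                genotypes=geno, positions=positions, samples=samples,
                populations=list(per_hap_pops), span=config.pop_gene_length)
            truth.pop_class[gid] = cls
    return matrices, pop_labels


def write_vcf(matrices: dict[str, HaplotypeMatrix],
              pop_labels: dict[str, str],
              vcf_path: str | Path, pops_path: str | Path) -> None:
    """Write the per-gene matrices as one plain-text VCF (contig = gene)."""
    genes = sorted(matrices)
    samples = matrices[genes[0]].samples
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for g in genes:
            fh.write(f"##contig=<ID={g},length={matrices[g].span}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for g in genes:
            m = matrices[g]
            for i in range(m.n_sites):
                gts = []
                for s in range(len(samples)):
                    a, b = m.genotypes[i, 2 * s], m.genotypes[i, 2 * s + 1]
                    gts.append(f"{'.' if a < 0 else a}|{'.' if b < 0 else b}")
                fh.write(f"{g}\t{m.positions[i]}\t.\tA\tT\t.\tPASS\t.\tGT\t"
                         + "\t".join(gts) + "\n")
    with open(pops_path, "w") as fh:
        fh.write("sample\tpopulation\n")
        for s in samples:
            fh.write(f"{s}\t{pop_labels[s]}\n")


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: SyntheticGenome
    truth: GroundTruth
    window_counts: pd.DataFrame
    transcript_counts: pd.DataFrame
    smallrna: pd.DataFrame
    mirnas: pd.DataFrame
    population: dict[str, HaplotypeMatrix] | None = None
    pop_labels: dict[str, str] | None = None

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        interface_io.write_annotation(self.genome.models.values(),
                                      out / "annotation.gff3")
        with open(out / "genome.fasta", "w") as fh:
            for chrom in sorted(self.genome.chromosomes):
                fh.write(f">{chrom}\n")
                seq = self.genome.chromosomes[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        triads = self.genome.triads[["triad_id", "gene_A", "gene_B",
                                     "gene_D", "syntenic"]]
        triads.to_csv(out / "triads.tsv", sep="\t", index=False)
        self.window_counts.to_csv(out / "window_counts.tsv", sep="\t", index=False)
        self.transcript_counts.to_csv(out / "transcript_counts.tsv",
                                      sep="\t", index=False)
        self.smallrna.to_csv(out / "smallrna.tsv", sep="\t", index=False)
        self.mirnas.to_csv(out / "mirnas.tsv", sep="\t", index=False)
        if self.population:
            write_vcf(self.population, self.pop_labels or {},
                      out / "population.vcf", out / "populations.tsv")
        self.truth.to_json(out / "ground_truth.json")


def simulate(config: SyntheticConfig,
             with_population: bool = True) -> SyntheticDataset:
    """Run the full generator: genome, small RNAs, counts, population."""
    genome, truth = generate_genome(config)
    smallrna, mirnas = generate_smallrna(config, genome, truth)
    window_counts, transcript_counts = generate_counts(config, genome, truth)
    population = pop_labels = None
    if with_population:
        population, pop_labels = generate_population(config, genome, truth)
    return SyntheticDataset(config=config, genome=genome, truth=truth,
                            window_counts=window_counts,
                            transcript_counts=transcript_counts,
                            smallrna=smallrna, mirnas=mirnas,
                            population=population, pop_labels=pop_labels)
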