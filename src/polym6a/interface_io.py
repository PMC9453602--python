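"""Standard-format I/O and coordinate projection.

Internal coordinates are 0-based half-open everywhere.  GFF3 (1-based
closed) and BED (0-based half-open) are converted at the boundary, so no
other module ever performs an off-by-one adjustment.

All peak and topology analyses run in transcript (sense-strand)
coordinates; :class:`TranscriptModel` owns the total genomic<->transcript
bijection over exonic bases.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

SUBGENOMES = ("A", "B", "D")


# ---------------------------------------------------------------------------
# TranscriptModel
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """One transcript's exon/CDS/UTR structure with its coordinate map.

    ``exons`` are genomic 0-based half-open intervals sorted by genomic
    start; ``cds_span``, ``five_utr``, ``three_utr``, ``start_codon`` and
    ``stop_codon`` are transcript-coordinate intervals on the sense strand.
    ``sequence`` is the sense-strand nucleotide string (may be empty when no
    genome FASTA was supplied).
    """

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds_span: tuple[int, int] | None = None
    sequence: str = ""
    subgenome: str = "other"
    cds_frame_ok: bool = True

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if b <= a:
                raise ValueError(f"{self.transcript_id}: empty exon [{a},{b})")
        for (_, b), (a2, _) in zip(self.exons, self.exons[1:]):
            if a2 < b:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if self.sequence and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} != "
                f"exon total {self.length}"
            )

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.exons)

    # -- coordinate projection ------------------------------------------------

    def genomic_to_transcript(self, g: int) -> int:
        """Project a genomic (0-based) exonic position to transcript space."""
        offset = 0
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        for a, b in exons:
            if a <= g < b:
                return offset + (g - a if self.strand == "+" else b - 1 - g)
            offset += b - a
        raise ValueError(f"{self.transcript_id}: genomic {g} not exonic")

    def transcript_to_genomic(self, t: int) -> int:
        if not 0 <= t < self.length:
            raise ValueError(f"{self.transcript_id}: transcript pos {t} out of range")
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        offset = t
        for a, b in exons:
            if offset < b - a:
                return a + offset if self.strand == "+" else b - 1 - offset
            offset -= b - a
        raise AssertionError("unreachable")

    # -- derived regions ------------------------------------------------------

    @property
    def start_codon(self) -> tuple[int, int] | None:
        if self.cds_span is None:
            return None
        return (self.cds_span[0], self.cds_span[0] + 3)

    @property
    def stop_codon(self) -> tuple[int, int] | None:
        if self.cds_span is None:
            return None
        return (self.cds_span[1] - 3, self.cds_span[1])

    @property
    def five_utr(self) -> tuple[int, int] | None:
        if self.cds_span is None or self.cds_span[0] == 0:
            return None
        return (0, self.cds_span[0])

    @property
    def three_utr(self) -> tuple[int, int] | None:
        if self.cds_span is None or self.cds_span[1] == self.length:
            return None
        return (self.cds_span[1], self.length)

    @property
    def cds_sequence(self) -> str:
        if self.cds_span is None:
            return ""
        return self.sequence[self.cds_span[0]:self.cds_span[1]]


def infer_subgenome(chromosome: str) -> str:
    """A/B/D from a wheat-style chromosome name (``chr1A`` ... ``7D``)."""
    tail = chromosome.rstrip()[-1].upper() if chromosome else ""
    return tail if tail in SUBGENOMES else "other"


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _gff_attrs(s: str) -> dict[str, str]:
    out = {}
    for part in s.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_annotation(gff3_path: str | Path,
                    genome_fasta: str | Path | None = None) -> list[TranscriptModel]:
    """Read gene models from a GFF3 file (1-based closed coordinates).

    Requires gene/mRNA/exon/CDS features; UTRs are derived from the CDS
    extent projected onto transcript coordinates.  Transcripts whose CDS
    length is not a multiple of 3 are kept but flagged
    (``cds_frame_ok=False``); transcripts with no exon features are
    rejected with a logged reason.

    When ``genome_fasta`` is given, sense-strand transcript sequences are
    spliced out of it.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq

    genome: dict[str, str] = {}
    if genome_fasta is not None:
        genome = {rec.id: str(rec.seq).upper()
                  for rec in SeqIO.parse(str(genome_fasta), "fasta")}

    mrna: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    with open(gff3_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = f[:9]
            a, b = int(start) - 1, int(end)  # to 0-based half-open
            at = _gff_attrs(attrs)
            if ftype in ("mRNA", "transcript"):
                tid = at.get("ID", "")
                mrna[tid] = {"chrom": chrom, "strand": strand,
                             "gene": at.get("Parent", tid)}
            elif ftype == "exon":
                exons.setdefault(at.get("Parent", ""), []).append((a, b))
            elif ftype == "CDS":
                cds.setdefault(at.get("Parent", ""), []).append((a, b))

    models: list[TranscriptModel] = []
    for tid, info in mrna.items():
        if tid not in exons:
            logger.warning("transcript %s rejected: no exon features", tid)
            continue
        model = TranscriptModel(
            transcript_id=tid, gene_id=info["gene"],
            chromosome=info["chrom"], strand=info["strand"],
            exons=exons[tid], subgenome=infer_subgenome(info["chrom"]),
        )
        if tid in cds:
            tpos = []
            for a, b in cds[tid]:
                tpos.append(model.genomic_to_transcript(a))
                tpos.append(model.genomic_to_transcript(b - 1))
            lo, hi = min(tpos), max(tpos) + 1
            model.cds_span = (lo, hi)
            if (hi - lo) % 3 != 0:
                logger.warning("transcript %s: CDS length %d not a multiple of 3",
                               tid, hi - lo)
                model.cds_frame_ok = False
        if genome and info["chrom"] in genome:
            chrom_seq = genome[info["chrom"]]
            spliced = "".join(chrom_seq[a:b] for a, b in model.exons)
            if model.strand == "-":
                spliced = str(Seq(spliced).reverse_complement())
            model.sequence = spliced
        models.append(model)
    return models


def collapse_longest(models: Iterable[TranscriptModel]) -> list[TranscriptModel]:
    """One representative transcript per gene: the longest annotated one."""
    best: dict[str, TranscriptModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if cur is None or (m.length, m.transcript_id) > (cur.length, cur.transcript_id):
            best[m.gene_id] = m
    return sorted(best.values(), key=lambda m: m.transcript_id)


def write_annotation(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write models back to GFF3 (retained fields only)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.chromosome, m.exons[0][0])):
            g0 = m.exons[0][0] + 1
            g1 = m.exons[-1][1]
            fh.write(f"{m.chromosome}\tpolym6a\tgene\t{g0}\t{g1}\t.\t{m.strand}\t.\t"
                     f"ID={m.gene_id}\n")
            fh.write(f"{m.chromosome}\tpolym6a\tmRNA\t{g0}\t{g1}\t.\t{m.strand}\t.\t"
                     f"ID={m.transcript_id};Parent={m.gene_id}\n")
            for a, b in m.exons:
                fh.write(f"{m.chromosome}\tpolym6a\texon\t{a + 1}\t{b}\t.\t{m.strand}\t.\t"
                         f"Parent={m.transcript_id}\n")
            if m.cds_span is not None:
                # project CDS back to genomic exon chunks
                tpos = range(m.cds_span[0], m.cds_span[1])
                gpos = sorted(m.transcript_to_genomic(t) for t in tpos)
                runs: list[list[int]] = []
                for g in gpos:
                    if runs and g == runs[-1][1] + 1:
                        runs[-1][1] = g
                    else:
                        runs.append([g, g])
                for a, b in runs:
                    fh.write(f"{m.chromosome}\tpolym6a\tCDS\t{a + 1}\t{b + 1}\t.\t"
                             f"{m.strand}\t.\tParent={m.transcript_id}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_peaks_bed(peaks: Sequence, path: str | Path,
                    models: Mapping[str, TranscriptModel] | None = None) -> None:
    """Write peak calls as BED6 (0-based half-open).

    Score column is -log10 of the peak q-value, capped at 1000 (q=0 maps to
    the cap).  With ``models``, transcript intervals are projected to the
    genomic span; otherwise the transcript itself is the BED "chromosome".
    """
    with open(path, "w") as fh:
        fh.write('track name="m6A_peaks"\n')
        for i, p in enumerate(peaks):
            q = getattr(p, "q_min", 1.0)
            score = 1000.0 if q <= 0 else min(1000.0, -math.log10(q))
            start, end = p.interval
            chrom = p.transcript_id
            strand = "."
            if models is not None and p.transcript_id in models:
                m = models[p.transcript_id]
                g = [m.transcript_to_genomic(start), m.transcript_to_genomic(end - 1)]
                start, end = min(g), max(g) + 1
                chrom, strand = m.chromosome, m.strand
            name = f"{p.transcript_id}_peak{i + 1}"
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:.4g}\t{strand}\n")


# ---------------------------------------------------------------------------
# VCF -> HaplotypeMatrix
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeMatrix:
    """Biallelic haplotype matrix with population labels.

    ``genotypes`` has shape (n_sites, n_haplotypes) with entries 0/1 and -1
    for missing; columns come in sample order, two haplotypes per diploid
    sample.  ``span`` is the sequence length the sites were ascertained on
    (needed for per-site diversity).
    """

    genotypes: np.ndarray
    positions: np.ndarray
    samples: list[str]
    populations: list[str]          # per haplotype column
    span: int

    @property
    def n_haplotypes(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    def allele_counts(self) -> np.ndarray:
        """Per-site [ref, alt] counts over non-missing haplotypes."""
        g = self.genotypes
        alt = (g == 1).sum(axis=1)
        ref = (g == 0).sum(axis=1)
        return np.stack([ref, alt], axis=1)

    def by_population(self) -> dict[str, "HaplotypeMatrix"]:
        pops = sorted(set(self.populations))
        out = {}
        for p in pops:
            cols = [i for i, q in enumerate(self.populations) if q == p]
            out[p] = HaplotypeMatrix(
                self.genotypes[:, cols], self.positions,
                samples=[], populations=[p] * len(cols), span=self.span)
        return out


def read_vcf(vcf_path: str | Path,
             pop_labels: Mapping[str, str],
             span: int | None = None) -> HaplotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`HaplotypeMatrix`.

    Multiallelic sites are skipped (count logged).  Missing genotypes are
    masked as -1.  Every population named in ``pop_labels`` must have at
    least one sample present in the VCF.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    present_pops = {pop_labels[s] for s in samples if s in pop_labels}
    for pop in sorted(set(pop_labels.values())):
        if pop not in present_pops:
            raise ValueError(f"population {pop!r} has no samples in {vcf_path}")

    rows, positions = [], []
    n_multi = 0
    max_pos = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = var.genotype.array()  # (n_samples, ploidy+1)
        hap = []
        for s in range(len(samples)):
            for a in gts[s][:-1]:
                hap.append(-1 if a < 0 else int(a))
        rows.append(hap)
        positions.append(var.POS)
        max_pos = max(max_pos, var.POS)
    if n_multi:
        logger.info("read_vcf: skipped %d multiallelic sites", n_multi)

    geno = (np.array(rows, dtype=np.int8) if rows
            else np.zeros((0, 2 * len(samples)), dtype=np.int8))
    populations = []
    for s in samples:
        populations.extend([pop_labels.get(s, "pop")] * 2)
    return HaplotypeMatrix(
        genotypes=geno, positions=np.array(positions, dtype=int),
        samples=samples, populations=populations,
        span=span if span is not None else max(max_pos, 1))


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

COUNT_COLUMNS = ["transcript_id", "replicate", "library", "count"]
LIBRARIES = ("IP", "input", "RNC", "sRNA")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a long-format count table (TSV).

    Required columns: ``transcript_id``, ``replicate``, ``library`` (one of
    IP/input/RNC/sRNA) and ``count``; window-level tables additionally carry
    ``start`` and ``end`` (transcript coordinates, 0-based half-open).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing count columns {missing}")
    bad = set(df["library"]) - set(LIBRARIES)
    if bad:
        raise ValueError(f"{path}: unknown libraries {sorted(bad)}")
    return df


def read_triad_table(path: str | Path) -> pd.DataFrame:
    """Triad table: triad_id, gene_A, gene_B, gene_D, syntenic (bool)."""
    df = pd.read_csv(path, sep="\t")
    need = ["triad_id", "gene_A", "gene_B", "gene_D"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing triad columns {missing}")
    if "syntenic" not in df.columns:
        df["syntenic"] = True
    df["syntenic"] = df["syntenic"].astype(bool)
    return df


def read_term_table(path: str | Path) -> pd.DataFrame:
    """Term->gene annotation table: term_id, term_name, gene_id."""
    df = pd.read_csv(path, sep="\t")
    need = ["term_id", "gene_id"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing term columns {missing}")
    if "term_name" not in df.columns:
        df["term_name"] = df["term_id"]
    return df


def read_smallrna_table(path: str | Path) -> pd.DataFrame:
    """Small-RNA read table: sequence, length, chrom, position, strand, count."""
    df = pd.read_csv(path, sep="\t")
    need = ["sequence", "length", "chrom", "position", "strand", "count"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing small-RNA columns {missing}")
    return df


# ---------------------------------------------------------------------------
# RunConfig
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Every tunable parameter of the pipeline, with its default.

    Round-trips losslessly through YAML (:meth:`to_yaml` / :meth:`from_yaml`).
    """

    seed: int = 0
    # peak calling
    window: int = 25                 # nt, IP/input test window
    step: int = 25                   # nt, window stride
    max_gap: int = 50                # nt, max gap when merging significant windows
    min_peak_len: int = 100          # nt, shorter runs dropped
    q_threshold: float = 0.05        # BH FDR for significant windows
    lambda_floor: float = 0.25       # floor on the Poisson null mean
    consensus_min: int = 2           # replicates that must support a peak
    # quantification
    mfpkm_mode: str = "divide"       # "divide" or "multiply" by covered fraction
    te_inverted: bool = False        # sensitivity switch: TE = RNA/RNC instead
    fpkm_input_floor: float = 0.1    # below this a transcript is not quantifiable
    # topology
    motif_top_n: int = 1000          # peaks entering the RRACH census
    # small RNA
    phase_cycles: int = 9            # cycles per scoring window
    phase_tolerance: int = 1         # nt tolerance around the register lattice
    phase_k_min: int = 4             # min occupied cycle positions
    phase_threshold_21: float = 10.0
    phase_threshold_24: float = 15.0
    target_cutoff: float = 5.0       # max expectation score for a target site
    top_phasirna: int = 300          # most-abundant distinct phasiRNA sequences
    # enrichment
    fdr_threshold: float = 0.05
    # io
    gff3: str = ""
    fasta: str = ""
    counts: str = ""
    triads: str = ""
    vcf: str = ""
    smallrna: str = ""
    terms: str = ""
    outdir: str = "polym6a_out"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
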