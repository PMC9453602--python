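# polym6a

Integrated analysis of the m6A epitranscriptome, the translatome, and the
small-RNA complement of a polyploid (A/B/D-subgenome) transcriptome — the
kind of dataset produced when m6A-seq (MeRIP-seq), RNA-seq, RNC-seq
(ribosome–nascent-chain sequencing) and small-RNA-seq libraries are made
from the same tissue of allohexaploid wheat.

The package is aimed at analysts who start from per-window / per-transcript
count tables (alignment is upstream and out of scope) and want a tested,
reproducible implementation of every downstream step, plus a synthetic-data
generator that plants each effect the analysis is supposed to detect, so
the whole pipeline can be validated end to end against ground truth.

## What it computes

**Peak calling.** Per replicate, each 25-nt transcript window is tested for
IP enrichment against a Poisson null with mean
λ = input · (IP library / input library), floored at 0.25;
p = P(X ≥ ip_count) with Benjamini–Hochberg correction across all windows
of the replicate. Significant windows (q < 0.05) merge into peaks
(gap ≤ 50 nt, length ≥ 100 nt), and peaks supported by ≥ 2 of 3
replicates (≥ 1 nt overlap) form the consensus set.

**Quantification.** FPKM = count / ((L/10³)(N/10⁶));
MFPKM = FPKM_IP / (covered fraction of the transcript);
methylation extent E = MFPKM / FPKM_input; translation efficiency
TE = FPKM_RNC / FPKM_input. Under library-size normalization both E and TE
are relative measures (scaled by the ratio of library sizes); all
downstream statistics are rank- or group-based and unaffected.

**Topology.** Each consensus peak is assigned to one of 5′UTR, start
codon, CDS, stop codon, 3′UTR (any overlap with the smaller element wins:
start codon > stop codon > 5′UTR > 3′UTR > CDS); per-region density is
peaks per kb of region, which is what exposes the start/stop-codon
enrichment; the RRACH census (R = A/G, H = A/C/T) counts all overlapping
5-mer matches in the top-1000 most significant peaks.

**Triad bias.** For each homoeolog triad, the value triple
v = (v_A, v_B, v_D) is normalized to r = v/Σv and assigned to the nearest
of seven centroids on the simplex: Balanced (⅓,⅓,⅓), A/B/D-dominant
(corners), A/B/D-suppressed (edge midpoints). The same classifier runs on
m6A extent, RNA abundance, and RNC abundance, with cross-tabulation of the
resulting categories.

**Evolution.** Nei–Gojobori (1986) Ka/Ks between homoeologs (equal-weight
pathway counting, Jukes–Cantor correction); per-gene nucleotide diversity
π, Tajima's D, and Weir–Cockerham Fst (ratio-of-sums across sites, clamped
at 0 with the raw value retained) from VCF haplotypes, compared between
methylated and non-methylated gene classes with rank-sum tests.

**Small RNA.** Length profiles; phasiRNA loci by a Howell-style phasing
score P = (k−2)·ln(1 + 10·n_phased/(1+n_unphased)) over 9-cycle windows at
21- or 24-nt registers; a psRNATarget-style expectation score for
miRNA/phasiRNA target sites (mismatch 1.0, G:U 0.5, gap 2.0, doubled at
sRNA positions 2–13, site cutoff 5.0); and the m6A × small-RNA synergy
comparison of translation efficiencies.

**Statistics.** Upper-tail hypergeometric term enrichment with BH FDR,
exact/asymptotic Wilcoxon rank-sum, Pearson/Spearman correlation, and the
per-region comparison table (abundance and TE vs the non-methylated set,
extent correlations within each region group).

## Worked example

```python
from polym6a import synthetic_data as sd, peak_calling as pc, quantify as qt

cfg = sd.SyntheticConfig(seed=7, n_triads=67, n_methylated_triads=40)
ds  = sd.simulate(cfg, with_population=False)     # 201 transcripts, 55 planted peaks
cons, per_rep = pc.call_peaks(ds.window_counts)   # -> 55 consensus peaks

lengths = {t: m.length for t, m in ds.genome.models.items()}
prof = qt.profile_transcripts(ds.window_counts, ds.transcript_counts, lengths,
                              methylated_ids={p.transcript_id for p in cons})
print(prof[prof.is_methylated].iloc[0])
```

```
transcript_id     Tsyn0002A.1
fpkm_ip            9251.39973
fpkm_input         260.149512
fpkm_rnc            65.245968
cov_frac             0.150286
mfpkm            61558.813802
extent             236.628596
te                   0.250802
```

`Tsyn0002A.1` carries a consensus peak at transcript interval (900, 1050)
(summit 912, q ≈ 2.2e-232, supported by all three replicates) overlapping
the 3′UTR interval planted at (920, 1040). Only 15% of the transcript is
covered by IP fragments, so MFPKM concentrates the IP density onto the
methylated portion; the extent and TE columns are the relative measures
used by every downstream comparison. The same run recovers all 55 planted
peaks with no false positives, and the RRACH census finds a motif in 100%
of them.

A thin CLI wraps the same calls:

```bash
polym6a simulate --seed 7 --n-triads 67 --outdir sim/
polym6a call-peaks --windows sim/window_counts.tsv --out peaks.bed
polym6a run --seed 7 --outdir out/          # end-to-end synthetic run
```

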