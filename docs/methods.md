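# Methods

This note records the models, parameter choices and numerical conventions
behind `polym6a`, and what the synthetic validation does and does not
establish about real data.

## Coordinates and gene models

All internal coordinates are 0-based half-open; GFF3 (1-based closed) and
BED (0-based half-open) are converted only at the I/O boundary. Peak and
topology analyses run in transcript (sense-strand) space: after splicing,
region assignment and metagene distances are unambiguous there, whereas
genome-space peaks on spliced genes are not. Multi-isoform genes are
collapsed to the longest annotated transcript per gene
(`interface_io.collapse_longest`); any other deterministic rule slots in at
the same point.

UTRs are derived from the CDS extent projected into transcript
coordinates: 5′UTR = [0, cds_start), start codon = first 3 nt of the CDS,
stop codon = last 3 nt, 3′UTR = [cds_end, length). A CDS whose length is
not a multiple of 3 is kept but flagged (`cds_frame_ok=False`) so that
codon-based analyses can exclude it.

## Peak calling

The window test is a ChIP-seq-style local-λ Poisson test: for each 25-nt
window, λ = input count × (IP library size / input library size), floored
at `lambda_floor = 0.25` so that windows with zero input coverage cannot
produce spuriously tiny p-values; p = P(Pois(λ) ≥ IP count), BH-corrected
across all windows of one replicate. Defaults: window = step = 25 nt,
merge gap ≤ 50 nt, minimum peak length 100 nt, q < 0.05, consensus from
≥ 2 replicates with ≥ 1 nt overlap, consensus interval = union of the
supporting intervals (the union is a deliberate choice: it preserves the
full enriched extent; an intersection rule would shrink peaks toward the
best-covered replicate). Every constant is in `RunConfig`.

The null is Poisson while the synthetic counts are negative-binomial
(dispersion 0.05 by default); this mismatch is intentional — it stresses
the approximation the same way real overdispersed libraries would. The
transcript-level false-positive rate under a null simulation stays at the
per-window FDR or below because a false peak needs a run of ≥ 4
significant windows in ≥ 2 replicates.

## Quantification

MFPKM divides the IP FPKM by the fraction of the transcript covered by IP
fragments. The motivating description ("normalizing FPKM to the
percentage covered") is directionally ambiguous; division is adopted
because it converts transcript-wide density into density over the
methylated portion, and the choice is isolated in `quantify.mfpkm` with a
`mfpkm_mode={divide,multiply}` switch. Extent E = MFPKM / FPKM_input and
TE = FPKM_RNC / FPKM_input. TE as RNC-over-RNA is the primary definition;
a `te_inverted` switch computes the reciprocal for sensitivity analysis,
since the opposite ratio also circulates in the literature. Transcripts
with FPKM_input < 0.1 are flagged non-quantifiable rather than allowed to
blow up the ratios; the count of exclusions is logged.

Because each library is normalized by its own size, E and TE are relative
quantities (a global factor equal to a library-size ratio multiplies each
of them). Every downstream statistic is rank-based, group-based or a
correlation, so this scale factor is irrelevant; absolute extents should
not be compared across datasets.

## Topology

Overlap priority start codon > stop codon > 5′UTR > 3′UTR > CDS: the
smallest, most specific element claims the peak. This is required for
3-nt codons to capture an appreciable share of peaks at all — under a
"majority of overlap" rule they could capture none. Metagene distances are
measured from the peak summit (midpoint of the best window) to the first
base of the start/stop codon; the summit-vs-midpoint choice is
configurable. All matching is on the DNA alphabet with U≡T.

## Triad classification

Plain nearest-centroid (Euclidean) on the 2-simplex over the seven ideal
points, without the bootstrap confidence interval some variants add; ties
are broken by a fixed category order (Balanced first) and flagged. The
m6A value of a gene is its extent, with 0 for genes lacking a consensus
peak — so a triad methylated only on A is (E_A, 0, 0), which is exactly
the A-dominant corner. The classifier is scale-invariant and equivariant
under subgenome relabelling (both property-tested).

## Evolution

Ka/Ks is Nei–Gojobori (1986): per-codon synonymous-site fractions
(mutations to stop codons count as nonsynonymous), averaged over both
sequences; observed differences averaged with equal weight over all
minimal pathways between codon pairs, excluding pathways through stop
codons unless every pathway is blocked; Jukes–Cantor correction
d = −¾ ln(1 − 4p/3), undefined (flagged) at p ≥ ¾. No
transition/transversion weighting — NG86 is fully specifiable and is
checked codon-by-codon against a brute-force pathway-enumeration oracle to
1e-12. Homoeolog pairs are pre-aligned at the protein level (end-gap-free
global alignment), back-projected to codons, and gap columns are removed.

π is the per-site mean pairwise difference over the gene span with
missing data handled pairwise-complete per site. Tajima's D uses the 1989
constants; it is undefined (None, distinct from 0) when S = 0 and when the
variance term vanishes, which includes n = 2 (c1 = c2 = 0). Fst is the
Weir–Cockerham (1984) haploid-sample estimator, aggregated per gene as
Σa / Σ(a+b) across sites, with negatives clamped to zero after
aggregation and the raw value retained for audit. Whether diversity is
computed per gene or pooled genome-wide was an open choice; per-gene
values with class-wise means and rank-sum comparison are used because the
class contrast is the scientific question.

## Small RNA

The phasing score is Howell-style:
P = (k − 2) · ln(1 + 10 · n_phased / (1 + n_unphased)) for k ≥ 3 occupied
cycle positions, else 0; windows span 9 cycles of the register (21 or
24 nt) with ±1 nt lattice tolerance, and are anchored at observed 5′ ends
so the lattice phase is defined by a read rather than an arbitrary origin.
Locus thresholds: P ≥ 15 (24-nt) and P ≥ 10 (21-nt), k ≥ 4; under uniform
random read starts the 21-nt threshold is exceeded in well under 5% of
windows (calibration is part of the acceptance run). The target scorer is
a psRNATarget-style approximation — penalties mismatch 1.0, G:U wobble
0.5, gap 2.0, doubled at sRNA positions 2–13, site cutoff 5.0 — not a
reproduction of any web service; all constants are config-exposed.
"Top 300 abundant phasiRNAs" ranks distinct sequences by summed count
(sequence-level, not locus-level).

## Synthetic data: what it emulates, what it does not

The generator plants every effect the analysis measures and records it in
`GroundTruth`:

- **Genome**: `n_triads` homoeolog triples on chromosomes 1A/1B/1D,
  two-exon gene models (strand randomized) with 160–320 nt 5′UTRs,
  150–400 codon CDSs and 200–450 nt 3′UTRs; homoeologs diverge at 2% of
  coding sites (stop codons repaired so ORFs stay valid).
- **Peaks**: per methylated triad a bias category is drawn; genes with
  relative share r > 0.1 get one 120-nt peak whose extent is
  3·r·fold·(shared triad multiplier, lognormal σ=0.4), with RRACH 5-mers
  written into the peak every 25 nt. `peak_fold ≤ 1` switches the run to
  a null with nothing planted. Peaks keep a 30-nt margin from codon
  boundaries (except codon-planted peaks) so that planted and assigned
  regions coincide; the called peak still extends up to one window beyond
  the planted interval.
- **Counts**: negative-binomial per window; input mean = abundance,
  IP mean = extent × abundance inside the peak and 0.002 × abundance
  outside. The sparse off-peak background reflects an antibody-enriched
  library at desk-scale depth and is what lets the covered-fraction
  estimator track the planted extent (Spearman ≥ 0.9 at default depth);
  with a dense background the covered fraction saturates and MFPKM loses
  its meaning, which is a real limitation of the measure, not of the
  implementation. Abundance and extent multipliers are shared within a
  triad so the planted relative triples survive into the observed data.
- **TE**: log TE = log μ + β_region·extent + sRNA effect + N(0, 0.3),
  with β = +0.03 for 5′UTR/start-codon and −0.03 for CDS/stop-codon/3′UTR
  peaks, β_expr = −0.05 on log abundance, and −0.8 on log TE for
  sRNA-targeted transcripts (interaction 0 by default — the additive
  null). These values put the average m6A repression (~0.6×) below the
  sRNA repression (~0.45×), the qualitative ordering expected of the two
  machineries, while keeping per-group sign recovery comfortably
  significant at n ≈ 300 per region group.
- **Small RNA**: a 24-nt-dominated background (70%), phased loci with 8
  of 9 cycles occupied at ~10 reads per position, and miRNAs defined as
  exact reverse complements of chosen mRNA sites (additional target sites
  are written into 3′UTRs so ORFs are untouched; the genomic FASTA is
  patched in sync).
- **Population**: per-gene coalescent simulations (msprime, two-deme
  island model, Ne = 10⁴, migration set from the target Fst via
  Fst ≈ 1/(1+8Nm); `fst_target = 0` means one panmictic population with
  split labels). Scaled mutation rates θ = 0.002 (methylated) vs 0.003
  (non-methylated): the class ratio is deliberately stronger than the
  subtle real-data contrast so the ordering is detectable at a few
  hundred genes per class instead of tens of thousands.

What passing tests show: the estimators recover exactly the structures
they assume, at desk-scale sizes, under NB count noise and coalescent
sampling noise. What they do not show: robustness to alignment artefacts,
isoform mixtures, fragment-length effects, PCR duplication, reference
bias, or real linkage patterns — none of which the generator emulates.

## Problem sizes and determinism

Test and acceptance runs use 30–600 triads, 3 replicates, ~20 input
fragments per 25-nt window, 8 diploid samples per population and 100–300
genes per diversity class; these sizes make every validation statistic
stable across seeds while the full suite plus acceptance script completes
in well under a minute. All randomness flows from a single integer seed
through `numpy.random.SeedSequence` spawns (and msprime seeds drawn below
2³¹), and a fixed seed reproduces every output byte-for-byte — verified by
hashing the written files twice per run.

## Known limitations

- The Poisson window test ignores overdispersion; with very deep
  libraries and high dispersion the per-window FDR is approximate (the
  replicate-consensus requirement is the practical guard).
- MFPKM's covered-fraction denominator is estimated from 25-nt window
  occupancy, not per-base coverage; at extreme depth every window is
  touched and the extent estimate compresses.
- The nearest-centroid triad classifier has no "unassigned" zone;
  borderline triads are always given their nearest category (with the
  distance reported so callers can threshold).
- The target scorer is gapless per window; gapped sites are approximated
  by adjacent window matches rather than explicit indel alignment.
- Fst between two small demes is upward-biased for low true
  differentiation; the clamping rule makes the reported per-gene values
  conservative at the low end.
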