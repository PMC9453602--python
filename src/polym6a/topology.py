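"""Peak topology over the five transcript regions and the RRACH census.

Every consensus peak on an mRNA is assigned to exactly one of 5'UTR,
start codon, CDS, stop codon, 3'UTR.  When a peak overlaps several
elements the smallest, most specific element wins (start codon > stop
codon > 5'UTR > 3'UTR > CDS): a 3-nt codon can only capture a realistic
share of peaks if any overlap claims the peak.  Metagene distances are
measured from the peak summit to the first base of the start and stop
codons.  The RRACH (R=A/G, H=A/C/T on the DNA alphabet) census counts all
overlapping matches inside the top-N most significant peaks.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .interface_io import TranscriptModel
from .peak_calling import PeakCall

REGIONS = ("5'UTR", "start_codon", "CDS", "stop_codon", "3'UTR")
_PRIORITY = ("start_codon", "stop_codon", "5'UTR", "3'UTR", "CDS")

RRACH_RE = re.compile(r"(?=([AG][AG]AC[ACT]))")
RRACH_VARIANTS = tuple(
    r1 + r2 + "AC" + h for r1 in "AG" for r2 in "AG" for h in "ACT")


@dataclass
class RegionAssignment:
    peak: PeakCall
    region: str
    dist_to_start: int
    dist_to_stop: int


@dataclass
class MotifCensus:
    """RRACH occurrence summary over the selected peaks."""

    variant_counts: dict[str, int]
    n_peaks: int
    n_peaks_with_match: int
    pfm: np.ndarray                 # 4 x 5 position-frequency matrix (ACGT rows)

    @property
    def fraction_with_match(self) -> float:
        return self.n_peaks_with_match / self.n_peaks if self.n_peaks else 0.0

    @property
    def total_matches(self) -> int:
        return sum(self.variant_counts.values())


def _regions_of(model: TranscriptModel) -> dict[str, tuple[int, int] | None]:
    return {
        "5'UTR": model.five_utr,
        "start_codon": model.start_codon,
        "CDS": model.cds_span,
        "stop_codon": model.stop_codon,
        "3'UTR": model.three_utr,
    }


def assign_region(peak: PeakCall, model: TranscriptModel) -> RegionAssignment:
    """Assign a consensus peak to one of the five transcript regions."""
    if model.cds_span is None:
        raise ValueError(f"{model.transcript_id}: no annotated CDS")
    start, end = peak.interval
    if start < 0 or end > model.length:
        raise ValueError(
            f"peak {peak.interval} outside transcript bounds [0,{model.length})")
    regions = _regions_of(model)
    region = None
    for name in _PRIORITY:
        iv = regions[name]
        if iv is not None and start < iv[1] and end > iv[0]:
            region = name
            break
    if region is None:  # pragma: no cover - the five regions tile the transcript
        region = "CDS"
    return RegionAssignment(
        peak=peak, region=region,
        dist_to_start=peak.summit - model.start_codon[0],
        dist_to_stop=peak.summit - model.stop_codon[0])


def region_density(assignments: list[RegionAssignment],
                   models: dict[str, TranscriptModel]) -> pd.DataFrame:
    """Peaks per kb of each region, totalled over the transcriptome.

    Normalizing by total region length is what reveals codon enrichment:
    raw counts favour the long CDS regions.
    """
    counts = Counter(a.region for a in assignments)
    lengths = Counter()
    for m in models.values():
        if m.cds_span is None:
            continue
        for name, iv in _regions_of(m).items():
            if iv is not None:
                lengths[name] += iv[1] - iv[0]
    rows = []
    for name in REGIONS:
        kb = lengths[name] / 1e3
        if kb == 0:
            continue
        n = counts.get(name, 0)
        rows.append(dict(region=name, n_peaks=n, region_kb=kb,
                         density_per_kb=n / kb))
    total = sum(r["n_peaks"] for r in rows)
    for r in rows:
        r["fraction"] = r["n_peaks"] / total if total else 0.0
    return pd.DataFrame(rows)


def motif_census(peaks: list[PeakCall],
                 models: dict[str, TranscriptModel],
                 top_n: int = 1000) -> MotifCensus:
    """RRACH census over the ``top_n`` most significant peaks.

    All overlapping matches inside each peak interval are counted; the PFM
    is accumulated over match occurrences (ACGT rows, 5 columns).
    """
    ranked = sorted(peaks, key=lambda p: (p.q_min, p.transcript_id))[:top_n]
    base_idx = {b: i for i, b in enumerate("ACGT")}
    counts: Counter = Counter()
    pfm = np.zeros((4, 5), dtype=float)
    n_with = 0
    for p in ranked:
        seq = models[p.transcript_id].sequence[p.interval[0]:p.interval[1]].upper()
        seq = seq.replace("U", "T")
        if re.search(r"[^ACGTN]", seq):
            raise ValueError(f"{p.transcript_id}: non-ACGTN base in peak sequence")
        hits = [m.group(1) for m in RRACH_RE.finditer(seq)]
        if hits:
            n_with += 1
        for h in hits:
            counts[h] += 1
            for j, b in enumerate(h):
                pfm[base_idx[b], j] += 1
    return MotifCensus(variant_counts=dict(counts), n_peaks=len(ranked),
                       n_peaks_with_match=n_with, pfm=pfm)


def write_pfm(census: MotifCensus, path: str) -> None:
    """Plain-text position-frequency matrix (transfac-like layout)."""
    with open(path, "w") as fh:
        fh.write("PO\t" + "\t".join(str(i + 1) for i in range(5)) + "\n")
        for i, b in enumerate("ACGT"):
            fh.write(b + "\t" + "\t".join(f"{census.pfm[i, j]:.0f}"
                                          for j in range(5)) + "\n")
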