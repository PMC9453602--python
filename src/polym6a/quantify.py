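"""Per-transcript quantification: FPKM, MFPKM, methylation extent, TE.

MFPKM rescales the IP-library FPKM by the fraction of the transcript
covered by IP fragments, turning transcript-wide density into density over
the methylated portion; methylation extent E is MFPKM over the input FPKM
and translation efficiency TE is the RNC-seq FPKM over the input FPKM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class MethylationProfile:
    transcript_id: str
    fpkm_ip: float
    fpkm_input: float
    fpkm_rnc: float
    cov_frac: float
    mfpkm: float
    extent: float | None        # None when not quantifiable
    te: float | None
    is_methylated: bool = False
    quantifiable: bool = True


def fpkm(count: float, length: int, library_size: int) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if length <= 0:
        raise ValueError(f"non-positive transcript length {length}")
    if library_size <= 0:
        raise ValueError(f"non-positive library size {library_size}")
    return count / ((length / 1e3) * (library_size / 1e6))


def mfpkm(fpkm_ip: float, cov_frac: float, mode: str = "divide") -> float:
    """IP FPKM normalized to the covered fraction of the transcript.

    ``mode="divide"`` (default) converts whole-transcript density to
    density over the covered portion; ``"multiply"`` is provided as a
    sensitivity switch for the opposite reading of the normalization.
    """
    if fpkm_ip == 0:
        return 0.0
    if not 0 < cov_frac <= 1:
        raise ValueError(f"fpkm_ip={fpkm_ip} > 0 but cov_frac={cov_frac}")
    if mode == "divide":
        return fpkm_ip / cov_frac
    if mode == "multiply":
        return fpkm_ip * cov_frac
    raise ValueError(f"unknown mfpkm mode {mode!r}")


def extent_and_te(mfpkm_val: float, fpkm_input: float, fpkm_rnc: float,
                  input_floor: float = 0.1,
                  te_inverted: bool = False) -> tuple[float | None, float | None]:
    """(methylation extent, translation efficiency) or None when undefined.

    Transcripts whose input FPKM falls below ``input_floor`` are not
    quantifiable (ratio blow-up) and both values are None.
    """
    if fpkm_input < input_floor or fpkm_input <= 0:
        return None, None
    extent = mfpkm_val / fpkm_input
    if te_inverted:
        te = fpkm_input / fpkm_rnc if fpkm_rnc > 0 else None
    else:
        te = fpkm_rnc / fpkm_input
    return extent, te


def profile_transcripts(window_counts: pd.DataFrame,
                        transcript_counts: pd.DataFrame,
                        lengths: dict[str, int],
                        methylated_ids: set[str] | None = None,
                        mfpkm_mode: str = "divide",
                        input_floor: float = 0.1,
                        te_inverted: bool = False) -> pd.DataFrame:
    """Replicate-mean methylation profiles for all transcripts.

    ``window_counts`` (transcript_id, start, end, replicate, library,
    count) provides IP fragment placement for the covered fraction;
    ``transcript_counts`` (transcript_id, replicate, library, count)
    provides totals for IP, input and RNC libraries.  FPKMs are computed
    per replicate against that replicate's library size and then averaged.
    """
    methylated_ids = methylated_ids or set()
    rows = []

    totals = (transcript_counts
              .groupby(["transcript_id", "library"])["count"].mean())
    libsizes = (transcript_counts
                .groupby(["library", "replicate"])["count"].sum()
                .groupby("library").mean())

    # covered fraction from IP window occupancy, averaged over replicates
    ipw = window_counts[window_counts["library"] == "IP"]
    cov = {}
    if len(ipw):
        occ = ipw.assign(hit=(ipw["count"] > 0)
                         * (ipw["end"] - ipw["start"]))
        per_rep = occ.groupby(["transcript_id", "replicate"])["hit"].sum()
        cov = per_rep.groupby("transcript_id").mean().to_dict()

    n_excluded = 0
    for tid, length in lengths.items():
        def _get(lib: str) -> float:
            try:
                return float(totals.loc[(tid, lib)])
            except KeyError:
                return 0.0

        f_ip = fpkm(_get("IP"), length, int(libsizes.get("IP", 1)) or 1)
        f_in = fpkm(_get("input"), length, int(libsizes.get("input", 1)) or 1)
        f_rnc = fpkm(_get("RNC"), length, int(libsizes.get("RNC", 1)) or 1)
        cf = min(1.0, cov.get(tid, 0.0) / length) if length else 0.0
        if f_ip > 0 and cf == 0:
            # counts without window placement: treat as fully covered
            cf = 1.0
        m = mfpkm(f_ip, cf if cf > 0 else 1.0, mode=mfpkm_mode) if f_ip > 0 else 0.0
        extent, te = extent_and_te(m, f_in, f_rnc, input_floor=input_floor,
                                   te_inverted=te_inverted)
        if extent is None:
            n_excluded += 1
        rows.append(dict(
            transcript_id=tid, fpkm_ip=f_ip, fpkm_input=f_in, fpkm_rnc=f_rnc,
            cov_frac=cf, mfpkm=m, extent=extent, te=te,
            is_methylated=tid in methylated_ids,
            quantifiable=extent is not None))
    if n_excluded:
        logger.info("profile_transcripts: %d transcripts below input floor", n_excluded)
    return pd.DataFrame(rows)
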