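"""Frequency-matched background-SNP empirical test for |iHS| outliers.

Recent admixture introduces long novel haplotypes genome-wide, which can
mimic sweep signals in haplotype-based scans.  The control: compare the
target SNP's |iHS| not against all SNPs but against background SNPs that
(1) segregate at the same frequency as the target in the putative source
population, (2) are absent from an outgroup African population (so they too
plausibly arrived by the same admixture), and (3) are common enough in the
focal population to have been scanned (MAF above the scan filter).  The
empirical P is then the fraction of background |iHS| values at least as
extreme as the target's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BackgroundCriteria", "select_background", "matched_empirical_p"]


@dataclass
class BackgroundCriteria:
    """Matching conditions for background-SNP selection."""

    source_freq_target: float
    source_tolerance: float = 0.01
    outgroup_max_freq: float = 0.0
    focal_min_maf: float = 0.05

    def __post_init__(self) -> None:
        if self.source_tolerance < 0 or self.outgroup_max_freq < 0:
            raise ValueError("tolerances must be non-negative")
        if not 0.0 <= self.focal_min_maf <= 0.5:
            raise ValueError("focal_min_maf must be in [0, 0.5]")


def select_background(
    source_freqs: pd.Series,
    outgroup_freqs: pd.Series,
    focal_freqs: pd.Series,
    target_site,
    criteria: BackgroundCriteria,
) -> pd.Index:
    """Sites passing all three matching conditions, excluding the target.

    The three series must share a site index.  Raises on an empty selection,
    reporting how many sites each condition passed individually so the
    limiting condition is visible.
    """
    idx = source_freqs.index
    if not (idx.equals(outgroup_freqs.index) and idx.equals(focal_freqs.index)):
        raise ValueError("frequency tables must share one site index")
    if target_site not in idx:
        raise KeyError(f"target site {target_site!r} not in the site index")
    src = source_freqs.to_numpy(dtype=float)
    out = outgroup_freqs.to_numpy(dtype=float)
    foc = focal_freqs.to_numpy(dtype=float)
    focal_maf = np.minimum(foc, 1.0 - foc)
    c1 = np.abs(src - criteria.source_freq_target) <= criteria.source_tolerance
    c2 = out <= criteria.outgroup_max_freq
    c3 = focal_maf > criteria.focal_min_maf
    keep = c1 & c2 & c3 & (idx != target_site)
    if not keep.any():
        raise ValueError(
            "no background SNPs satisfy all conditions "
            f"(source-frequency match: {int(c1.sum())}, "
            f"outgroup absence: {int(c2.sum())}, "
            f"focal MAF: {int(c3.sum())} of {len(idx)} sites)"
        )
    return idx[keep]


def matched_empirical_p(background_abs_ihs, target_abs_ihs: float) -> float:
    """Upper-tail empirical P of the target |iHS| in the matched background."""
    bg = np.asarray(background_abs_ihs, dtype=float)
    bg = bg[~np.isnan(bg)]
    if bg.size == 0:
        raise ValueError("matched background is empty")
    return float((bg >= target_abs_ihs).sum() / bg.size)
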