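"""Local-ancestry summaries, enrichment testing, and admixture-time utilities.

The input is an H x L binary matrix of per-haplotype, per-site ancestry
labels (0 = African, 1 = non-African), the shape of an RFmix-style local
ancestry output.  The enrichment test asks whether the proportion of
non-African haplotypes at a focal site is extreme relative to the genome-wide
empirical distribution (optionally restricted to background sites of similar
minor allele frequency); the answer is an upper-tail empirical P.

Tract utilities invert the exponential approximation for single-pulse
admixture-tract lengths: tracts of the ancestry present at fraction f have
mean genetic length 1/((1 - f) T) Morgans after T generations, so
T_hat = 1/(mean_length (1 - f)).  Terminal tracts (truncated by the ends of
the region) are censored out of the mean-length estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AncestryMatrix",
    "AdmixtureTiming",
    "site_ancestry_proportion",
    "ancestry_enrichment_p",
    "tract_admixture_time",
    "mean_tract_length",
    "generations_to_years",
]


@dataclass
class AncestryMatrix:
    """Per-haplotype, per-site binary ancestry labels with coordinates."""

    haplotype_ids: list[str]
    chrom: str
    positions_bp: np.ndarray
    labels: np.ndarray
    genetic_pos_cM: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        if self.labels.shape != (len(self.haplotype_ids), self.positions_bp.size):
            raise ValueError("label matrix shape must be (n_haplotypes, n_sites)")
        if self.genetic_pos_cM is not None:
            self.genetic_pos_cM = np.asarray(self.genetic_pos_cM, dtype=float)

    def tracts(self) -> pd.DataFrame:
        """Maximal constant-label runs per haplotype as half-open intervals.

        Interior tract boundaries are placed at the midpoint between the two
        sites where the label changes (unbiased for lengths when sites are
        dense relative to tracts); terminal tracts end at the outermost sites
        and are marked ``terminal`` so length-based estimators can censor
        them.  Genetic lengths (Morgans) are included when genetic positions
        are available.
        """
        pos0 = self.positions_bp.astype(float) - 1.0  # 0-based site coordinates
        gp = self.genetic_pos_cM
        rows = []
        for h, hid in enumerate(self.haplotype_ids):
            lab = self.labels[h]
            change = np.nonzero(np.diff(lab))[0]  # boundary between i and i+1
            starts = np.concatenate([[0], change + 1])
            ends = np.concatenate([change, [lab.size - 1]])  # inclusive site spans
            for k, (a, b) in enumerate(zip(starts, ends)):
                # interior boundaries sit at the midpoint between flanking sites
                # (ceil keeps the half-open intervals tiling the covered sites)
                start_bp = pos0[a] if k == 0 else np.ceil((pos0[a - 1] + pos0[a]) / 2.0)
                end_bp = (
                    pos0[b] + 1.0
                    if k == len(starts) - 1
                    else np.ceil((pos0[b] + pos0[b + 1]) / 2.0)
                )
                rec = {
                    "haplotype_id": hid,
                    "chrom": self.chrom,
                    "start_bp": int(start_bp),
                    "end_bp": int(end_bp),
                    "label": int(lab[a]),
                    "terminal": k == 0 or k == len(starts) - 1,
                }
                if gp is not None:
                    g0 = gp[a] if k == 0 else (gp[a - 1] + gp[a]) / 2.0
                    g1 = gp[b] if k == len(starts) - 1 else (gp[b] + gp[b + 1]) / 2.0
                    rec["morgans"] = (g1 - g0) / 100.0
                rows.append(rec)
        return pd.DataFrame(rows)


@dataclass
class AdmixtureTiming:
    """Admixture time in generations and (exactly converted) years."""

    T_generations: float
    generation_time_years: float = 30.0

    def __post_init__(self) -> None:
        if self.T_generations < 0:
            raise ValueError("T must be non-negative")

    @property
    def T_years(self) -> float:
        return self.T_generations * self.generation_time_years


def site_ancestry_proportion(matrix: AncestryMatrix | np.ndarray) -> np.ndarray:
    """Per-site proportion of haplotypes labelled non-African (label 1)."""
    labels = matrix.labels if isinstance(matrix, AncestryMatrix) else np.asarray(matrix)
    if labels.shape[0] < 1:
        raise ValueError("need at least one haplotype")
    return labels.mean(axis=0)


def ancestry_enrichment_p(
    proportions: np.ndarray,
    focal_site: int,
    maf_match: tuple[np.ndarray, float] | None = None,
    min_background: int = 100,
) -> float:
    """Upper-tail empirical P of the focal site's non-African proportion.

    Background = all other sites, optionally restricted to sites whose
    focal-population MAF is within ``tolerance`` of the focal site's MAF
    (``maf_match = (per-site frequencies, tolerance)``; frequencies are
    folded to MAF internally).
    """
    props = np.asarray(proportions, dtype=float)
    if not 0 <= focal_site < props.size:
        raise IndexError("focal site out of range")
    keep = np.ones(props.size, dtype=bool)
    keep[focal_site] = False
    if maf_match is not None:
        freqs, tol = maf_match
        maf = np.minimum(np.asarray(freqs, dtype=float), 1.0 - np.asarray(freqs, dtype=float))
        keep &= np.abs(maf - maf[focal_site]) <= tol
    bg = props[keep]
    if bg.size == 0:
        raise ValueError("no background sites remain after MAF matching")
    if bg.size < min_background:
        raise ValueError(
            f"only {bg.size} background sites after matching; need >= {min_background}"
        )
    return float((bg >= props[focal_site]).sum() / bg.size)


def mean_tract_length(tracts: pd.DataFrame, label: int) -> float:
    """Mean genetic length (Morgans) of non-terminal tracts with ``label``."""
    if "morgans" not in tracts.columns:
        raise ValueError("tract table lacks genetic lengths; provide genetic positions")
    sel = tracts[(tracts["label"] == label) & (~tracts["terminal"])]
    if sel.empty:
        raise ValueError(f"no interior tracts with label {label}")
    return float(sel["morgans"].mean())


def tract_admixture_time(mean_tract_length_morgans: float, ancestry_fraction: float) -> float:
    """Pulse-admixture time from the mean tract length of one ancestry.

    Under a single pulse T generations ago, tracts of the ancestry at
    fraction f are approximately exponential with mean 1/((1 - f) T)
    Morgans; inverting gives T_hat = 1/(mean (1 - f)).
    """
    if mean_tract_length_morgans <= 0:
        raise ValueError("mean tract length must be positive")
    f = ancestry_fraction
    if not 0.0 < f < 1.0:
        raise ValueError("ancestry fraction must lie strictly in (0, 1)")
    return 1.0 / (mean_tract_length_morgans * (1.0 - f))


def generations_to_years(T: float, generation_time: float = 30.0) -> float:
    """Exact product T * generation_time; rounding is the caller's concern."""
    if T < 0:
        raise ValueError("T must be non-negative")
    return float(T) * float(generation_time)
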