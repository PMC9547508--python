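"""Extended haplotype homozygosity (EHH), iHH, and the integrated haplotype score.

EHH at a marker x, for the haplotypes carrying a given core allele, is the
probability that two randomly chosen carriers are identical at every site
from the core out to x:

    EHH(x) = sum_g C(n_g, 2) / C(n_core, 2)

where the groups g partition carriers by their haplotype between core and x.
iHH is the trapezoidal integral over genetic distance of (EHH - cutoff)
clipped at zero, truncated on each flank at the first marker where EHH drops
below the cutoff; iHS_unstd = ln(iHH_ancestral / iHH_derived), standardized
to zero mean / unit variance within 1% derived-allele-frequency bins.

Conventions follow the standard scan tooling where the underlying study is
silent: EHH cutoff 0.05, maximum marker gap 200 kb (larger gaps flag the
core), cores whose EHH never decays below the cutoff before the chromosome
edge are flagged ``edge_truncated`` and by default dropped from
standardization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GeneticMap, HaplotypePanel

__all__ = [
    "interpolate_genetic_map",
    "ehh",
    "ihh",
    "ihs_scan",
    "standardize_ihs",
    "EHHCurve",
]

QC_OK = "ok"
QC_EDGE = "edge_truncated"
QC_GAP = "gap"
QC_LOW_MAF = "low_maf"
QC_UNPOLARIZED = "unpolarized"
QC_ZERO_IHH = "zero_ihh"
QC_FEW_CARRIERS = "too_few_carriers"


def interpolate_genetic_map(positions_bp, gmap: GeneticMap) -> np.ndarray:
    """Genetic positions (cM) for physical positions by linear interpolation.

    Between map points the cumulative cM column is interpolated linearly;
    beyond either end, positions are extrapolated at the terminal interval's
    rate (the slope of the outermost cumulative-cM segment).
    """
    q = np.asarray(positions_bp, dtype=float)
    mp = gmap.positions_bp.astype(float)
    mc = gmap.cum_cM
    out = np.interp(q, mp, mc)
    lo_rate = (mc[1] - mc[0]) / (mp[1] - mp[0])
    hi_rate = (mc[-1] - mc[-2]) / (mp[-1] - mp[-2])
    left = q < mp[0]
    right = q > mp[-1]
    out[left] = mc[0] - (mp[0] - q[left]) * lo_rate
    out[right] = mc[-1] + (q[right] - mp[-1]) * hi_rate
    return out


@dataclass
class EHHCurve:
    """EHH decay away from a core allele, one point per marker on each flank.

    ``left``/``right`` are (n_markers, 2) arrays of (genetic_pos_cM, EHH)
    ordered outward from the core; both include the core point where EHH = 1.
    ``*_bp`` carry the matching physical positions for gap detection.
    """

    core_site: int
    allele: int
    n_core: int
    left: np.ndarray
    right: np.ndarray
    left_bp: np.ndarray
    right_bp: np.ndarray


def _ehh_one_flank(
    hap: np.ndarray,
    carriers: np.ndarray,
    order: np.ndarray,
    gpos: np.ndarray,
    pos_bp: np.ndarray,
    stop_below: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """EHH values walking outward over the marker indices in ``order``.

    Carriers are progressively partitioned into identity groups by refining
    integer group ids with each new marker column.  If ``stop_below`` is
    given, the walk stops after the first marker whose EHH falls below it.
    """
    n = carriers.size
    pairs_total = n * (n - 1) / 2.0
    sub = hap[carriers]
    ids = np.zeros(n, dtype=np.int64)
    n_groups = 1
    points = []
    bps = []
    for m in order:
        key = ids * 2 + sub[:, m]
        counts = np.bincount(key, minlength=2 * n_groups)
        nz = np.nonzero(counts)[0]
        ids = np.searchsorted(nz, key)  # compact relabeling
        n_groups = nz.size
        counts = counts[nz]
        e = float((counts * (counts - 1)).sum() / 2.0 / pairs_total)
        points.append((gpos[m], e))
        bps.append(pos_bp[m])
        if e == 0.0:
            break
        if stop_below is not None and e < stop_below:
            break
    return np.asarray(points, dtype=float).reshape(-1, 2), np.asarray(bps, dtype=np.int64)


def ehh(panel: HaplotypePanel | np.ndarray, core: int, allele: int, *,
        genetic_pos_cM: np.ndarray | None = None,
        positions_bp: np.ndarray | None = None,
        stop_below: float | None = None) -> EHHCurve:
    """EHH curve around ``core`` for haplotypes carrying ``allele`` there.

    Accepts either a :class:`HaplotypePanel` (coordinates taken from it) or a
    bare binary matrix with explicit coordinate arrays.  Needs at least two
    carrier haplotypes.  ``stop_below`` optionally truncates each flank after
    EHH first drops below the given value (used by the scan for speed); the
    full curve is returned when it is None.
    """
    if isinstance(panel, HaplotypePanel):
        hap = panel.haplotypes
        if genetic_pos_cM is None:
            genetic_pos_cM = panel.genetic_pos_cM
        if positions_bp is None:
            positions_bp = panel.positions_bp
    else:
        hap = np.asarray(panel, dtype=np.uint8)
    if genetic_pos_cM is None:
        raise ValueError("genetic positions are required (interpolate the map first)")
    gpos = np.asarray(genetic_pos_cM, dtype=float)
    pos_bp = (
        np.asarray(positions_bp, dtype=np.int64)
        if positions_bp is not None
        else np.arange(hap.shape[1], dtype=np.int64)
    )
    carriers = np.nonzero(hap[:, core] == allele)[0]
    if carriers.size < 2:
        raise ValueError(
            f"need >= 2 carrier haplotypes of allele {allele} at core {core} "
            f"(found {carriers.size}); pairwise homozygosity is undefined"
        )
    L = hap.shape[1]
    core_pt = np.array([[gpos[core], 1.0]])
    core_bp = np.array([pos_bp[core]])
    lorder = np.arange(core - 1, -1, -1)
    rorder = np.arange(core + 1, L)
    lpts, lbp = _ehh_one_flank(hap, carriers, lorder, gpos, pos_bp, stop_below)
    rpts, rbp = _ehh_one_flank(hap, carriers, rorder, gpos, pos_bp, stop_below)
    return EHHCurve(
        core_site=core,
        allele=allele,
        n_core=int(carriers.size),
        left=np.vstack([core_pt, lpts]) if lpts.size else core_pt,
        right=np.vstack([core_pt, rpts]) if rpts.size else core_pt,
        left_bp=np.concatenate([core_bp, lbp]),
        right_bp=np.concatenate([core_bp, rbp]),
    )


def _integrate_flank(
    points: np.ndarray,
    bp: np.ndarray,
    cutoff: float,
    max_gap_bp: float,
) -> tuple[float, str]:
    """Trapezoidal integral of (EHH - cutoff)+ outward until EHH < cutoff.

    Returns (area in cM, qc flag).  The flank is ``edge_truncated`` if it
    runs out of markers while EHH is still >= cutoff, and ``gap`` if a
    physical gap larger than ``max_gap_bp`` is crossed before truncation.
    """
    area = 0.0
    flag = QC_OK
    g = points[:, 0]
    e = points[:, 1]
    v = np.clip(e - cutoff, 0.0, None)
    truncated = False
    for k in range(1, len(points)):
        if abs(bp[k] - bp[k - 1]) > max_gap_bp:
            flag = QC_GAP
        area += abs(g[k] - g[k - 1]) * (v[k] + v[k - 1]) / 2.0
        if e[k] < cutoff:
            truncated = True
            break
    if not truncated and flag == QC_OK:
        flag = QC_EDGE
    return area, flag


def ihh(
    curve: EHHCurve,
    cutoff: float = 0.05,
    max_gap_bp: float = 200_000,
) -> tuple[float, str]:
    """Integrated haplotype homozygosity of a curve: both flanks summed.

    Gap flags dominate edge flags; a single-marker flank (core at the
    chromosome end) contributes zero area and an edge flag.
    """
    al, fl = _integrate_flank(curve.left, curve.left_bp, cutoff, max_gap_bp)
    ar, fr = _integrate_flank(curve.right, curve.right_bp, cutoff, max_gap_bp)
    flags = {fl, fr}
    if QC_GAP in flags:
        flag = QC_GAP
    elif QC_EDGE in flags:
        flag = QC_EDGE
    else:
        flag = QC_OK
    return al + ar, flag


def ihs_scan(
    panel: HaplotypePanel,
    gmap: GeneticMap | None = None,
    min_maf: float = 0.05,
    cutoff: float = 0.05,
    max_gap_bp: float = 200_000,
    bin_width: float = 0.01,
    drop_truncated: bool = True,
) -> pd.DataFrame:
    """Genome scan: unstandardized and bin-standardized iHS per passing site.

    Sites failing the MAF filter, lacking a confident ancestral allele, or
    with degenerate iHH are flagged (QC column) and excluded from
    standardization.  ``drop_truncated`` additionally withholds
    edge-truncated and gap-flagged cores from standardization (their
    unstandardized scores are still reported); set it False on short
    simulated regions where a strong sweep's EHH never decays inside the
    region.
    """
    if panel.genetic_pos_cM is None:
        if gmap is None:
            raise ValueError("provide a genetic map or a panel with genetic positions")
        gpos = interpolate_genetic_map(panel.positions_bp, gmap)
    else:
        gpos = panel.genetic_pos_cM
    hap = panel.haplotypes
    H, L = hap.shape
    daf = hap.mean(axis=0)
    polarized = panel.sites["polarized"].to_numpy(dtype=bool)
    pos_bp = panel.positions_bp

    rows = []
    for m in range(L):
        rec = {
            "CHROM": panel.sites["chrom"].iloc[m],
            "POS": int(pos_bp[m]),
            "DAF": float(daf[m]),
            "IHH_A": np.nan,
            "IHH_D": np.nan,
            "IHS_UNSTD": np.nan,
            "QC": QC_OK,
        }
        maf = min(daf[m], 1.0 - daf[m])
        if not polarized[m]:
            rec["QC"] = QC_UNPOLARIZED
        elif maf <= min_maf:
            rec["QC"] = QC_LOW_MAF
        elif min((hap[:, m] == 0).sum(), (hap[:, m] == 1).sum()) < 2:
            rec["QC"] = QC_FEW_CARRIERS
        else:
            flags = set()
            vals = {}
            for allele, name in ((0, "IHH_A"), (1, "IHH_D")):
                curve = ehh(
                    hap, m, allele,
                    genetic_pos_cM=gpos, positions_bp=pos_bp, stop_below=cutoff,
                )
                v, fl = ihh(curve, cutoff=cutoff, max_gap_bp=max_gap_bp)
                vals[name] = v
                flags.add(fl)
            rec["IHH_A"], rec["IHH_D"] = vals["IHH_A"], vals["IHH_D"]
            if vals["IHH_A"] <= 0.0 or vals["IHH_D"] <= 0.0:
                rec["QC"] = QC_ZERO_IHH
            else:
                rec["IHS_UNSTD"] = float(np.log(vals["IHH_A"] / vals["IHH_D"]))
                if QC_GAP in flags:
                    rec["QC"] = QC_GAP
                elif QC_EDGE in flags:
                    rec["QC"] = QC_EDGE
        rows.append(rec)
    df = pd.DataFrame(rows)
    return standardize_ihs(df, bin_width=bin_width, drop_truncated=drop_truncated)


def standardize_ihs(
    records: pd.DataFrame,
    bin_width: float = 0.01,
    drop_truncated: bool = True,
    variance: str = "population",
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Standardize iHS within derived-allele-frequency bins of ``bin_width``.

    Bin edges are [k*w, (k+1)*w); within each bin with >= 2 scorable records
    the standardized score is (x - bin mean)/bin sd.  Bins with fewer records
    or zero variance leave their records unscored, with a warning.

    ``reference`` optionally supplies a separate record table (same columns)
    from which the bin means/sds are computed — e.g. a genome-wide or neutral
    background — so that scores in a region dominated by one sweep are
    standardized against an undistorted frequency-matched distribution.
    """
    df = records.copy()

    def _scorable(d: pd.DataFrame) -> pd.Series:
        ok = d["IHS_UNSTD"].notna() & (d["QC"] == QC_OK)
        if not drop_truncated:
            ok = d["IHS_UNSTD"].notna() & d["QC"].isin([QC_OK, QC_EDGE, QC_GAP])
        return ok

    scorable = _scorable(df)
    ref = df if reference is None else reference
    ref_scorable = scorable if reference is None else _scorable(reference)
    df["IHS_STD"] = np.nan
    ddof = 0 if variance == "population" else 1
    skipped_bins: list[float] = []
    if scorable.any() and ref_scorable.any():
        bins = np.floor(df.loc[scorable, "DAF"] / bin_width).astype(int)
        ref_bins = np.floor(ref.loc[ref_scorable, "DAF"] / bin_width).astype(int)
        ref_x_all = ref.loc[ref_scorable, "IHS_UNSTD"].to_numpy(dtype=float)
        for b in np.unique(bins):
            idx = bins.index[bins == b]
            x = df.loc[idx, "IHS_UNSTD"].to_numpy(dtype=float)
            rx = ref_x_all[(ref_bins == b).to_numpy()]
            sd = np.std(rx, ddof=ddof) if rx.size >= 2 else 0.0
            if rx.size < 2 or sd == 0.0:
                skipped_bins.append(b * bin_width)
                continue
            df.loc[idx, "IHS_STD"] = (x - rx.mean()) / sd
    if skipped_bins:
        warnings.warn(
            f"{len(skipped_bins)} DAF bin(s) left unstandardized (<2 scored records "
            f"or zero variance), starting at: "
            + ", ".join(f"{b:.2f}" for b in skipped_bins[:5]),
            stacklevel=2,
        )
    df["ABS_IHS"] = df["IHS_STD"].abs()
    cols = ["CHROM", "POS", "DAF", "IHH_A", "IHH_D", "IHS_UNSTD", "IHS_STD", "ABS_IHS", "QC"]
    return df[cols]
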