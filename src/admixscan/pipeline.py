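"""Top-level pipeline: stages wired together from a YAML/dict config.

The full synthetic run builds a small admixture world — one neutral
Wright–Fisher panel split into an "African" (AFR) and a "non-African" (NAF)
source, plus an admixed population (ADMIX) produced by a single pulse — and
then runs the scans against it: pairwise F_ST/Di with ADMIX focal, the iHS
scan, local-ancestry enrichment at the focal site, the frequency-matched
background test, and the selection-coefficient estimate from the configured
scalar inputs.  Every stage writes a TSV; a JSON manifest records package
version, parameters, seed, and SHA-256 checksums of all files so a run is
reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestry import ancestry_enrichment_p, site_ancestry_proportion
from .background import BackgroundCriteria, matched_empirical_p, select_background
from .fstdi import di_statistic, empirical_percentile, pairwise_fst
from .ihs import ihs_scan
from .io import (
    read_ancestry_tracts,
    read_genetic_map,
    read_phased_vcf,
    read_population_map,
    write_ancestry_tracts,
    write_genetic_map,
    write_phased_vcf,
    write_population_map,
    ancestry_matrix_from_tracts,
)
from .panel import HaplotypePanel, PopulationMap
from .selcoef import SelectionModelInput, estimate_s
from .simulate import SimConfig, SimulatedPanel, simulate_admixed_panel, simulate_sweep_panel

logger = logging.getLogger("admixscan")

STAGE_ORDER = ["simulate", "fst_di", "ihs", "ancestry", "matched_bg", "selcoef"]
STAGE_INPUTS = {
    "fst_di": ["simulate"],
    "ihs": ["simulate"],
    "ancestry": ["simulate"],
    "matched_bg": ["simulate", "ihs"],
    "selcoef": [],
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(source: str | Path | dict) -> dict:
    if isinstance(source, dict):
        return dict(source)
    with open(source) as fh:
        return yaml.safe_load(fh)


def simulate_world(config: dict, seed: int, out: Path) -> dict[str, Path]:
    """Build and write the synthetic admixture world (stage ``simulate``)."""
    sim = dict(config.get("simulate", {}))
    n_source = int(sim.pop("source_haplotypes", 100))
    n_admix = int(sim.pop("admixed_haplotypes", 100))
    if n_source % 2 or n_admix % 2:
        raise ValueError("haplotype counts must be even (two haplotypes per sample)")
    f = float(sim.pop("admixture_fraction", 0.5))
    T = int(sim.pop("admixture_generations", 68))
    cfg = SimConfig(
        **{**sim, "seed": seed, "sample_haplotypes": 2 * n_source,
           "admixture_fraction": f, "admixture_generations": T}
    )
    base = simulate_sweep_panel(cfg)
    half = base.n_haplotypes // 2
    src_a = SimulatedPanel(
        base.haplotypes[:half], base.positions_bp, base.genetic_pos_cM,
        base.focal_index, truth={"role": "source_A", **base.truth},
    )
    src_b = SimulatedPanel(
        base.haplotypes[half:], base.positions_bp, base.genetic_pos_cM,
        base.focal_index, truth={"role": "source_B", **base.truth},
    )
    admix = simulate_admixed_panel(src_a, src_b, f=f, T=T, n=n_admix, seed=seed)

    hap = np.vstack([src_a.haplotypes, src_b.haplotypes, admix.haplotypes])
    merged = SimulatedPanel(
        hap, base.positions_bp, base.genetic_pos_cM, base.focal_index,
        truth={"role": "merged", "seed": seed},
    )
    panel = merged.to_haplotype_panel()
    # haplotype blocks: [0, n_source) AFR, [n_source, 2 n_source) NAF, rest ADMIX
    pop_of = {}
    for i, s in enumerate(panel.sample_ids):
        if i < n_source // 2:
            pop_of[s] = "AFR"
        elif i < n_source:
            pop_of[s] = "NAF"
        else:
            pop_of[s] = "ADMIX"
    pops = PopulationMap(pop_of)

    paths = {
        "vcf": write_phased_vcf(panel, out / "panel.vcf"),
        "map": write_genetic_map(merged.genetic_map(), out / "genetic.map"),
        "pops": write_population_map(pops, out / "populations.tsv"),
    }
    admix_ids = [
        f"{hid}"
        for s in panel.sample_ids
        if pop_of[s] == "ADMIX"
        for hid in (f"{s}_0", f"{s}_1")
    ]
    from .ancestry import AncestryMatrix

    amat = AncestryMatrix(
        admix_ids, str(panel.sites["chrom"].iloc[0]), merged.positions_bp,
        admix.ancestry, merged.genetic_pos_cM,
    )
    paths["tracts"] = write_ancestry_tracts(amat.tracts(), out / "ancestry_tracts.tsv")
    meta = {
        "focal_index": int(base.focal_index),
        "focal_pos": int(base.positions_bp[base.focal_index]),
        "admixture_fraction": f,
        "admixture_generations": T,
        "truth": {"base": base.truth, "admix": admix.truth},
    }
    (out / "simulate_meta.json").write_text(json.dumps(meta, indent=2, default=str))
    paths["meta"] = out / "simulate_meta.json"
    return paths


def _load_world(out: Path) -> tuple[HaplotypePanel, PopulationMap, dict]:
    panel = read_phased_vcf(out / "panel.vcf")
    gmap = read_genetic_map(out / "genetic.map")
    from .ihs import interpolate_genetic_map

    panel.genetic_pos_cM = interpolate_genetic_map(panel.positions_bp, gmap)
    pops = read_population_map(out / "populations.tsv")
    meta = json.loads((out / "simulate_meta.json").read_text())
    return panel, pops, meta


def run_pipeline(config: str | Path | dict, seed: int | None = None, out_dir: str | Path | None = None) -> Path:
    """Execute the configured stages in dependency order; return the out dir."""
    cfg = load_config(config)
    seed = int(seed if seed is not None else cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out_dir", "admixscan_run"))
    stages = cfg.get("stages", STAGE_ORDER)
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    stages = [s for s in STAGE_ORDER if s in stages]
    for s in stages:
        for dep in STAGE_INPUTS.get(s, []):
            if dep not in stages:
                raise ValueError(f"stage {s!r} requires stage {dep!r} in the same run")
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        filename=out / "run.log", level=logging.INFO, force=True,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
    logger.info("run start: seed=%d stages=%s", seed, stages)
    outputs: dict[str, str] = {}

    panel = pops = meta = None
    if "simulate" in stages:
        paths = simulate_world(cfg, seed, out)
        outputs.update({k: str(v) for k, v in paths.items()})
        panel, pops, meta = _load_world(out)

    ihs_df = None
    if "fst_di" in stages:
        focal = cfg.get("fst_di", {}).get("focal", "ADMIX")
        table = pairwise_fst(panel, pops)
        di = di_statistic(table, focal).to_frame()
        fst_path = out / "fst.tsv"
        table.to_frame().to_csv(fst_path, sep="\t", index=False, na_rep=".")
        di_path = out / f"di_{focal}.tsv"
        di.to_csv(di_path, sep="\t", index=False, na_rep=".")
        outputs["fst"] = str(fst_path)
        outputs["di"] = str(di_path)

    if "ihs" in stages:
        opts = cfg.get("ihs", {})
        rows = pops.haplotype_indices(panel, opts.get("population", "ADMIX"))
        sub = HaplotypePanel(
            panel.haplotypes[rows], panel.sites,
            [panel.sample_ids[i] for i in sorted({r // 2 for r in rows})],
            genetic_pos_cM=panel.genetic_pos_cM,
        )
        ihs_df = ihs_scan(
            sub,
            min_maf=float(opts.get("min_maf", 0.05)),
            cutoff=float(opts.get("ehh_cutoff", 0.05)),
            max_gap_bp=float(opts.get("max_gap_bp", 200_000)),
            bin_width=float(opts.get("bin_width", 0.01)),
            drop_truncated=bool(opts.get("drop_truncated", False)),
        )
        scored = ihs_df["ABS_IHS"].dropna()
        ihs_df["EMP_P"] = [
            empirical_percentile(scored, v) if np.isfinite(v) else np.nan
            for v in ihs_df["ABS_IHS"]
        ]
        ihs_path = out / "ihs.tsv"
        ihs_df.to_csv(ihs_path, sep="\t", index=False, na_rep=".")
        outputs["ihs"] = str(ihs_path)

    if "ancestry" in stages:
        tracts = read_ancestry_tracts(out / "ancestry_tracts.tsv")
        amat = ancestry_matrix_from_tracts(
            tracts, panel.positions_bp, panel.genetic_pos_cM
        )
        props = site_ancestry_proportion(amat)
        focal_idx = meta["focal_index"]
        try:
            p = ancestry_enrichment_p(props, focal_idx)
        except ValueError as exc:
            logger.warning("ancestry enrichment not computed: %s", exc)
            p = np.nan
        anc_df = pd.DataFrame(
            {"CHROM": panel.sites["chrom"], "POS": panel.positions_bp, "PROP_NONAFR": props}
        )
        anc_path = out / "ancestry_sites.tsv"
        anc_df.to_csv(anc_path, sep="\t", index=False)
        (out / "ancestry_summary.json").write_text(
            json.dumps(
                {"focal_pos": meta["focal_pos"], "prop_nonafr": float(props[focal_idx]),
                 "empirical_p": None if np.isnan(p) else float(p)},
                indent=2,
            )
        )
        outputs["ancestry_sites"] = str(anc_path)
        outputs["ancestry_summary"] = str(out / "ancestry_summary.json")

    if "matched_bg" in stages:
        opts = cfg.get("matched_bg", {})
        pos_index = pd.Index(panel.positions_bp)
        freqs = {}
        for name, key in (("NAF", "source"), ("AFR", "outgroup"), ("ADMIX", "focal")):
            rows = pops.haplotype_indices(panel, opts.get(key, name))
            freqs[key] = pd.Series(panel.haplotypes[rows].mean(axis=0), index=pos_index)
        target_pos = int(opts.get("target_pos", meta["focal_pos"]))
        crit = BackgroundCriteria(
            source_freq_target=float(freqs["source"].loc[target_pos]),
            source_tolerance=float(opts.get("tolerance", 0.01)),
            outgroup_max_freq=float(opts.get("outgroup_max_freq", 0.0)),
            focal_min_maf=float(opts.get("focal_min_maf", 0.05)),
        )
        summary_path = out / "matched_bg_summary.json"
        try:
            bg_sites = select_background(
                freqs["source"], freqs["outgroup"], freqs["focal"], target_pos, crit
            )
            ihs_by_pos = ihs_df.set_index("POS")["ABS_IHS"]
            bg_scores = ihs_by_pos.reindex(bg_sites).dropna()
            target_score = ihs_by_pos.get(target_pos, np.nan)
            if bg_scores.empty or not np.isfinite(target_score):
                raise ValueError("no scored background/target |iHS| values")
            p = matched_empirical_p(bg_scores.to_numpy(), float(target_score))
            summary = {
                "N_BACKGROUND": int(bg_scores.size),
                "TARGET_ABS_IHS": float(target_score),
                "EMP_P": p,
            }
            pd.DataFrame({"POS": bg_scores.index, "ABS_IHS": bg_scores.to_numpy()}).to_csv(
                out / "matched_bg_sites.tsv", sep="\t", index=False
            )
            outputs["matched_bg_sites"] = str(out / "matched_bg_sites.tsv")
        except (ValueError, KeyError) as exc:
            logger.warning("matched background test not computed: %s", exc)
            summary = {"error": str(exc)}
        summary_path.write_text(json.dumps(summary, indent=2))
        outputs["matched_bg_summary"] = str(summary_path)

    if "selcoef" in stages:
        opts = dict(cfg.get("selcoef", {}))
        lr_factor = float(opts.pop("lr_factor", 100.0))
        inp = SelectionModelInput(
            T=float(opts.get("T", 68)),
            N=int(opts.get("N", 440)),
            k=int(opts.get("k", 147)),
            nu0=opts.get("nu0"),
            nu_source=opts.get("nu_source", 0.36 if "nu0" not in opts else None),
            f_nah=opts.get("f_nah", 0.5 if "nu0" not in opts else None),
        )
        est = estimate_s(inp, lr_factor=lr_factor)
        sel_path = out / "selcoef.tsv"
        pd.DataFrame(
            [
                {
                    "NU0": inp.nu0, "T": inp.T, "N": inp.N, "K": inp.k,
                    "S_HAT": est.s_hat, "S_LO": est.interval[0], "S_HI": est.interval[1],
                    "LR_FACTOR": est.lr_factor, "LOGLIK_MAX": est.loglik_max,
                }
            ]
        ).to_csv(sel_path, sep="\t", index=False)
        np.savetxt(
            out / "selcoef_profile.tsv", est.profile, delimiter="\t",
            header="s\tloglik", comments="",
        )
        outputs["selcoef"] = str(sel_path)
        outputs["selcoef_profile"] = str(out / "selcoef_profile.tsv")

    manifest = {
        "package": "admixscan",
        "version": __version__,
        "seed": seed,
        "stages": stages,
        "config": {k: v for k, v in cfg.items() if k != "out_dir"},
        "checksums": {k: _sha256(Path(v)) for k, v in outputs.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    logger.info("run complete: %d outputs", len(outputs))
    return out
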