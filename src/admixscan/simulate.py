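"""Synthetic-data generators for the selection-scan pipeline.

Three generators cover everything the analysis consumes:

* :func:`simulate_trajectory` — allele-frequency trajectories under constant
  genic selection, either the deterministic logistic-in-odds closed form
  ``nu(t) = x0 e^{st} / (1 + x0 e^{st})`` with ``x0 = nu0/(1-nu0)``, or a
  Wright–Fisher stochastic version that applies the same per-generation odds
  update and then binomially resamples ``2 Ne`` allele copies.
* :func:`simulate_sweep_panel` — forward Wright–Fisher simulation of phased
  haplotypes over a recombining region with multiplicative fitness ``e^s`` per
  derived copy at a focal site; with ``s_focal = 0`` the same machinery yields
  neutral panels.
* :func:`simulate_admixed_panel` — mosaic haplotypes from a single admixture
  pulse ``T`` generations ago between two source panels, with recombination
  breakpoints drawn as a Poisson process at rate ``T`` per Morgan along the
  genetic map and a true per-site ancestry matrix.

All generators expand one global seed into named independent substreams
(:mod:`admixscan._rng`), so identical seed + config gives identical output.
These are stand-ins for real cohort data: no mutation accumulation, no
demography beyond constant ``Ne``, and neutral-site starting frequencies drawn
from a symmetric Beta(0.5, 0.5) as a pragmatic proxy for a neutral SFS.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from ._rng import substream
from .panel import GeneticMap, HaplotypePanel, PopulationMap

__all__ = [
    "TrajectoryResult",
    "SimConfig",
    "SimulatedPanel",
    "simulate_trajectory",
    "simulate_sweep_panel",
    "simulate_admixed_panel",
]


@dataclass
class TrajectoryResult:
    """Allele-frequency trajectory, one value per generation 0..T."""

    frequencies: np.ndarray
    mode: Literal["deterministic", "stochastic"]
    parameters: dict

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)

    @property
    def final_freq(self) -> float:
        return float(self.frequencies[-1])


@dataclass
class SimConfig:
    """Configuration of the forward haplotype simulators.

    Defaults describe a 2-Mb region at 1 cM/Mb — the scale of the scanned
    gene region — with 600 segregating sites, a diploid population of
    ``Ne = 500``, and a sample of 440 chromosomes (the cohort's sample size).
    ``stop_freq = None`` means run for ``max_generations`` regardless of the
    focal frequency (the neutral default).
    """

    region_length_bp: int = 2_000_000
    n_sites: int = 600
    recomb_rate_cM_per_Mb: float = 1.0
    Ne: int = 500
    sample_haplotypes: int = 440
    s_focal: float = 0.0
    init_focal_freq: float = 0.1
    max_generations: int = 300
    stop_freq: float | None = None
    admixture_fraction: float = 0.5
    admixture_generations: int = 68
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_length_bp <= 0 or self.n_sites <= 0:
            raise ValueError("region length and site count must be positive")
        if self.recomb_rate_cM_per_Mb < 0:
            raise ValueError("recombination rate must be non-negative")
        if self.Ne < 1:
            raise ValueError("Ne must be >= 1")
        if not 0.0 <= self.admixture_fraction <= 1.0:
            raise ValueError("admixture fraction must be in [0, 1]")
        if not 0.0 < self.init_focal_freq < 1.0:
            raise ValueError("init_focal_freq must be in (0, 1)")
        if self.seed is None:
            raise ValueError("seed is required")


@dataclass
class SimulatedPanel:
    """A simulated phased haplotype panel with ground truth.

    ``haplotypes`` is H x L binary (0 = ancestral, 1 = derived);
    ``ancestry``, when present, is the same shape with 0 = African-source and
    1 = non-African-source labels.  ``truth`` records every simulation
    parameter (including the seed) plus run diagnostics, and is labelled
    synthetic: these panels are generator stand-ins, not inferred data.
    """

    haplotypes: np.ndarray
    positions_bp: np.ndarray
    genetic_pos_cM: np.ndarray
    focal_index: int | None
    ancestry: np.ndarray | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.genetic_pos_cM = np.asarray(self.genetic_pos_cM, dtype=float)
        if np.any(np.diff(self.positions_bp) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(np.diff(self.genetic_pos_cM) < 0):
            raise ValueError("genetic positions must be non-decreasing")
        if self.ancestry is not None:
            self.ancestry = np.ascontiguousarray(self.ancestry, dtype=np.uint8)
            if self.ancestry.shape != self.haplotypes.shape:
                raise ValueError("ancestry matrix must match haplotype shape")
        self.truth.setdefault("synthetic", True)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def focal_freq(self) -> float | None:
        if self.focal_index is None:
            return None
        return float(self.haplotypes[:, self.focal_index].mean())

    def to_haplotype_panel(self, chrom: str = "1", prefix: str = "sim") -> HaplotypePanel:
        """View as a polarized :class:`HaplotypePanel` (drops ancestry/truth)."""
        h = self.n_haplotypes
        if h % 2:
            raise ValueError("need an even number of haplotypes to form diploids")
        sites = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": self.positions_bp,
                "ref": "A",
                "alt": "G",
                "aa": "A",
                "polarized": True,
            }
        )
        samples = [f"{prefix}{i}" for i in range(h // 2)]
        return HaplotypePanel(
            haplotypes=self.haplotypes,
            sites=sites,
            sample_ids=samples,
            genetic_pos_cM=self.genetic_pos_cM,
        )

    def population_map(self, name: str = "SIM", prefix: str = "sim") -> PopulationMap:
        return PopulationMap({f"{prefix}{i}": name for i in range(self.n_haplotypes // 2)})

    def genetic_map(self) -> GeneticMap:
        """Two-point constant-rate map spanning the simulated region."""
        p0, p1 = int(self.positions_bp[0]), int(self.positions_bp[-1])
        g0, g1 = float(self.genetic_pos_cM[0]), float(self.genetic_pos_cM[-1])
        rate = (g1 - g0) / max(p1 - p0, 1) * 1e6
        return GeneticMap(
            positions_bp=np.array([p0, p1]),
            rates_cM_per_Mb=np.array([rate, rate]),
            cum_cM=np.array([g0, g1]),
        )


def _odds_update(nu: float, s: float) -> float:
    # nu -> nu e^s / (1 - nu + nu e^s); fixed points 0 and 1 are preserved.
    w = np.exp(s)
    return nu * w / (1.0 - nu + nu * w)


def simulate_trajectory(
    nu0: float,
    s: float,
    T: int,
    mode: Literal["deterministic", "stochastic"] = "deterministic",
    Ne: int | None = None,
    seed: int | None = None,
) -> TrajectoryResult:
    """Allele-frequency trajectory over generations 0..T under constant selection.

    Deterministic mode evaluates the closed form
    ``nu(t) = x0 e^{st} / (1 + x0 e^{st})`` with ``x0 = nu0/(1 - nu0)``.
    Stochastic mode applies the same odds update each generation and then
    binomially resamples ``2 Ne`` allele copies (Wright–Fisher drift).
    """
    if not 0.0 < nu0 < 1.0:
        raise ValueError("nu0 must lie strictly in (0, 1): the odds are undefined at 0 or 1")
    if T < 0:
        raise ValueError("T must be >= 0")
    params = {"nu0": nu0, "s": s, "T": T, "Ne": Ne, "seed": seed}
    if mode == "deterministic":
        t = np.arange(T + 1, dtype=float)
        x0 = nu0 / (1.0 - nu0)
        xt = x0 * np.exp(s * t)
        freqs = xt / (1.0 + xt)
        freqs[0] = nu0  # exact, not round-tripped through the odds
        return TrajectoryResult(freqs, "deterministic", params)
    if mode != "stochastic":
        raise ValueError(f"unknown mode {mode!r}")
    if Ne is None or Ne < 1:
        raise ValueError("stochastic mode requires Ne >= 1")
    rng = substream(seed, "trajectory")
    freqs = np.empty(T + 1)
    freqs[0] = nu = nu0
    two_ne = 2 * int(Ne)
    for t in range(1, T + 1):
        nu = _odds_update(nu, s)
        nu = rng.binomial(two_ne, nu) / two_ne
        freqs[t] = nu
    return TrajectoryResult(freqs, "stochastic", params)


def _region_sites(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, int]:
    """Distinct sorted site positions, genetic positions, and the focal index."""
    pos = np.sort(
        rng.choice(np.arange(1, cfg.region_length_bp + 1), size=cfg.n_sites, replace=False)
    ).astype(np.int64)
    gpos = (pos - 1) * cfg.recomb_rate_cM_per_Mb / 1e6  # cM from region start
    focal = int(np.argmin(np.abs(pos - cfg.region_length_bp // 2)))
    return pos, gpos, focal


def _recombine(
    pop: np.ndarray,
    idx1: np.ndarray,
    idx2: np.ndarray,
    gpos_morgans: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One generation of offspring: copy parent 1, splice parent 2 segments.

    Crossover counts are Poisson in the map length (Morgans); crossover points
    are uniform in genetic distance.  Which parent contributes the leftmost
    segment is a fair coin.
    """
    total = gpos_morgans[-1] - gpos_morgans[0]
    n = idx1.size
    out = pop[idx1].copy()
    ncx = rng.poisson(total, size=n)
    start_with_2 = rng.random(n) < 0.5
    rows = np.nonzero((ncx > 0) | start_with_2)[0]
    for r in rows:
        k = ncx[r]
        cuts = np.sort(rng.uniform(gpos_morgans[0], gpos_morgans[-1], size=k))
        # phase[i] = which parent contributes site i (0 -> idx1, 1 -> idx2)
        seg = np.searchsorted(cuts, gpos_morgans, side="right")
        phase = (seg + int(start_with_2[r])) % 2
        take2 = phase == 1
        if take2.any():
            out[r, take2] = pop[idx2[r], take2]
    return out


def simulate_sweep_panel(config: SimConfig) -> SimulatedPanel:
    """Forward Wright–Fisher panel with (optional) genic selection at a focal site.

    The founding generation draws per-site derived frequencies from
    Beta(0.5, 0.5) (redrawn if monomorphic); the focal site starts at exactly
    ``round(init_focal_freq * 2 Ne)`` copies (at least one).  Each generation,
    parents are sampled proportional to fitness ``e^{s}`` per derived copy at
    the focal site and offspring recombine with Poisson crossovers per Morgan.
    The run stops when the focal frequency reaches ``stop_freq`` (if set) or
    after ``max_generations``; if the derived allele is lost the simulation
    restarts from a fresh substream, counting restarts in ``truth``.
    """
    cfg = config
    two_ne = 2 * cfg.Ne
    if cfg.sample_haplotypes > two_ne:
        raise ValueError("cannot sample more haplotypes than 2*Ne")
    site_rng = substream(cfg.seed, "sweep-sites")
    pos, gpos, focal = _region_sites(cfg, site_rng)
    gmorg = gpos / 100.0

    n_restarts = 0
    for attempt in range(1000):
        rng = substream(cfg.seed, "sweep-wf", attempt)
        # Founding generation at linkage equilibrium.
        p_init = rng.beta(0.5, 0.5, size=cfg.n_sites)
        pop = (rng.random((two_ne, cfg.n_sites)) < p_init).astype(np.uint8)
        mono = (pop.sum(axis=0) == 0) | (pop.sum(axis=0) == two_ne)
        while mono.any():
            p_init[mono] = rng.beta(0.5, 0.5, size=int(mono.sum()))
            pop[:, mono] = rng.random((two_ne, int(mono.sum()))) < p_init[mono]
            mono = (pop.sum(axis=0) == 0) | (pop.sum(axis=0) == two_ne)
        k0 = max(1, round(cfg.init_focal_freq * two_ne))
        pop[:, focal] = 0
        pop[rng.choice(two_ne, size=k0, replace=False), focal] = 1

        lost = False
        hit = "max_generations"
        gen = 0
        for gen in range(1, cfg.max_generations + 1):
            if cfg.s_focal != 0.0:
                w = np.where(pop[:, focal] == 1, np.exp(cfg.s_focal), 1.0)
                probs = w / w.sum()
                idx1 = rng.choice(two_ne, size=two_ne, p=probs)
                idx2 = rng.choice(two_ne, size=two_ne, p=probs)
            else:
                idx1 = rng.integers(0, two_ne, size=two_ne)
                idx2 = rng.integers(0, two_ne, size=two_ne)
            pop = _recombine(pop, idx1, idx2, gmorg, rng)
            freq = pop[:, focal].mean()
            if freq == 0.0:
                lost = True
                break
            if cfg.stop_freq is not None and freq >= cfg.stop_freq:
                hit = "stop_freq"
                break
        if not lost:
            break
        n_restarts += 1
    else:  # pragma: no cover - would need pathological parameters
        raise RuntimeError("derived allele lost in 1000 consecutive attempts")

    sample = np.sort(rng.choice(two_ne, size=cfg.sample_haplotypes, replace=False))
    hap = pop[sample]
    truth = {
        "generator": "simulate_sweep_panel",
        "config": dataclasses.asdict(cfg),
        "n_restarts": n_restarts,
        "generations_run": gen,
        "stop_condition": hit,
        "population_focal_freq": float(pop[:, focal].mean()),
    }
    return SimulatedPanel(hap, pos, gpos, focal, ancestry=None, truth=truth)


def simulate_admixed_panel(
    source_A: SimulatedPanel,
    source_B: SimulatedPanel,
    f: float,
    T: int,
    n: int,
    seed: int,
) -> SimulatedPanel:
    """Mosaic panel from a single admixture pulse ``T`` generations ago.

    Each output haplotype is built by dropping recombination breakpoints as a
    Poisson process at rate ``T`` per Morgan along the shared genetic map and
    copying each segment from a uniformly chosen haplotype of source B
    (non-African, label 1) with probability ``f``, else source A (African,
    label 0).  The returned ancestry matrix records the true segment source.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("admixture fraction f must be in [0, 1]")
    if T < 1:
        raise ValueError("T must be >= 1")
    if not np.array_equal(source_A.positions_bp, source_B.positions_bp) or not np.allclose(
        source_A.genetic_pos_cM, source_B.genetic_pos_cM
    ):
        raise ValueError("source panels must share physical and genetic coordinates")
    rng = substream(seed, "admixture")
    gpos = source_A.genetic_pos_cM
    gmorg = gpos / 100.0
    total = gmorg[-1] - gmorg[0]
    L = gpos.size
    hap = np.empty((n, L), dtype=np.uint8)
    anc = np.empty((n, L), dtype=np.uint8)
    segments: list[dict] = []
    sources = (source_A.haplotypes, source_B.haplotypes)
    for h in range(n):
        k = rng.poisson(T * total)
        cuts = np.sort(rng.uniform(gmorg[0], gmorg[-1], size=k))
        seg_of_site = np.searchsorted(cuts, gmorg, side="right")
        labels = (rng.random(k + 1) < f).astype(np.uint8)
        donors = np.empty(k + 1, dtype=np.int64)
        for lab in (0, 1):
            m = labels == lab
            donors[m] = rng.integers(0, sources[lab].shape[0], size=int(m.sum()))
        anc[h] = labels[seg_of_site]
        for seg in range(k + 1):
            cols = seg_of_site == seg
            if cols.any():
                hap[h, cols] = sources[labels[seg]][donors[seg], cols]
        segments.append(
            {"cuts_morgans": cuts, "labels": labels, "donors": donors}
        )
    truth = {
        "generator": "simulate_admixed_panel",
        "f": f,
        "T": T,
        "n": n,
        "seed": seed,
        "segments": segments,
    }
    return SimulatedPanel(
        hap,
        source_A.positions_bp,
        gpos,
        source_A.focal_index,
        ancestry=anc,
        truth=truth,
    )
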