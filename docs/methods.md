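# Methods

This note documents the models implemented in `admixscan`, the assumptions
behind them, the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical choices that affect
results at the margins.

## Selection-coefficient model (`selcoef`)

**Model.** An allele enters an admixed population at initial frequency
ν₀ = ν_source · f_nah, where ν_source is its frequency in the source
population and f_nah the fraction of haplotypes introduced by admixture.
Under constant genic selection s the frequency after T generations follows
the logistic-in-odds closed form

    ν(ν₀, T, s) = x₀ e^{sT} / (1 + x₀ e^{sT}),   x₀ = ν₀ / (1 − ν₀),

equivalently a per-generation odds multiplication by e^s. The observation
model is a single binomial draw: k selected alleles among N sampled
chromosomes with success probability ν(ν₀, T, s). The likelihood of s is
maximized numerically (Nelder–Mead on the negative log-likelihood,
tolerance 1e-15); for 0 < k < N the MLE also has the closed form
ŝ = ln[(k/(N−k)) · (1−ν₀)/ν₀] / T, which the optimizer is required (and
tested) to match to 1e-8. Uncertainty is reported as the LR₁₀₀ interval:
all s whose likelihood is within a factor of 100 of the maximum, found by
doubling-step bracketing plus Brent root refinement of
logL(ŝ) − logL(s) = ln 100 on each monotone side (endpoint residual
≤ 1e-6 log-units).

**Assumptions and their consequences.** Drift is absent from the
likelihood: the trajectory is deterministic and the only stochasticity is
the final binomial sample. For large admixed populations this is a
reasonable first-order model, but the LR interval understates uncertainty
when Ne is small or T is long. `recover_s_simulation` quantifies this: with
Ne = 10,000, T = 68 and N = 440 the estimator is unbiased to within Monte
Carlo error and LR₁₀₀ coverage of the true s is ≈ 0.9; with much smaller
Ne the interval would undercover. Boundary data (k = 0 or k = N) make the
MLE diverge to ∓∞; the estimate is flagged and the interval is open on the
divergent side.

**Conventions.** The log-likelihood includes the log binomial coefficient,
so absolute values are defined; all inference quantities are invariant to
this constant (tested). s is unconstrained (negative values allowed, flat
prior). Percentages are 100·s, rounded only at presentation.

**A note on the two standard scenarios.** With ν_source = 0.36,
f_nah = 0.5, T = 68, N = 440, k = 147, the closed form gives
ŝ = 1.216%; with f_nah = 0.6 (ν₀ = 0.216) it gives ŝ = 0.881%. Published
analyses of this scenario have quoted a point estimate near 1.12% for the
first case alongside a likelihood-ratio interval of roughly 0.99–1.44%;
the equations as stated yield 1.216%, which lies inside that interval but
not on the quoted point. We implement the stated equations and report the
computed value; the tests treat the first scenario as an interval check
and the second as a point check.

## Weir–Cockerham F_ST and Di (`fstdi`)

Per-site θ̂ = a/(a+b+c) is computed from the two-population
variance components of diploid genotype counts, heterozygote term
included — the estimator VCFtools `--weir-fst-pop` reports per site.
Per-site estimates may be negative and are retained (not clamped) in all
summaries, because Di standardizes against the genome-wide mean and
standard deviation of the same quantity. Sites monomorphic across both
samples have a+b+c = 0 and are undefined (NaN); they are excluded from the
per-pair mean and sd used by Di. The per-pair sd uses ddof = 1 (sample sd
of the genome-wide per-site distribution); with genome-scale locus counts
the distinction from ddof = 0 is negligible, and the brute-force test
oracle codes the same convention independently. A pair whose genome-wide
sd is below 1e-12 (numerically constant) cannot be standardized and is
excluded from Di globally, with a warning. Diploid genotypes are
reconstructed from consecutive haplotype pairs, matching the phased VCF
the matrix came from.

Empirical P-values throughout the package are upper-tail r/n — the count
of background values ≥ the observed value over the background size — with
no continuity correction and no multiple-testing adjustment.

## EHH, iHH, and iHS (`ihs`)

EHH at marker x for the carriers of a core allele is
Σ_g C(n_g, 2)/C(n_c, 2) over the groups g of carriers identical at every
site from the core through x. The implementation refines integer group
labels marker by marker outward (exact, and verified against an explicit
pairwise-comparison oracle); it never approximates.

iHH integrates (EHH − c)₊ by the trapezoid rule over genetic distance
(cM), truncating each flank at the first marker where EHH < c. Defaults
follow the conventions of the standard scan tooling where the analysis
protocol is otherwise silent: cutoff c = 0.05; physical gaps > 200 kb
between consecutive markers flag the core (`gap`); cores whose EHH never
decays below c before the chromosome end are flagged `edge_truncated`.
Flagged cores keep their unstandardized score but are excluded from
standardization when `drop_truncated=True` (the default, mirroring how
genome-wide scans discard truncated cores). On deliberately short
simulated regions a strong sweep's EHH cannot decay inside the region at
all, so the simulation tests set `drop_truncated=False`; this is a
property of the test world, not a change to the scan.

iHS_unstd = ln(iHH_ancestral/iHH_derived): negative for sweeps on the
derived allele. Scores are standardized to mean 0, variance 1 within
derived-allele-frequency bins of width 0.01 (population variance, ddof 0;
switchable). Bins with fewer than two scored records, or zero variance,
are left unscored with a warning. `standardize_ihs` optionally takes a
*reference* record set from which the bin moments are computed — the
analogue of normalizing a region's scores against the genome-wide
distribution. The sweep-detection tests use pooled neutral replicates as
the reference because in a 2-Mb simulated region every site hitchhikes
with the sweep, so within-panel bins are themselves sweep-distorted; a
genome-wide scan's bins are overwhelmingly neutral.

Genetic positions come from linear interpolation of a HapMap-format
cumulative-cM map; beyond the map ends, positions extrapolate at the
outermost interval's rate. Ties in genetic position are allowed and
contribute zero-width trapezoids. The MAF filter (> 5%) and the
ancestral-polarity requirement are applied before scoring; records failing
them carry `low_maf`/`unpolarized` flags. Two extra flags extend the set:
`zero_ihh` (either allele's iHH integrates to zero — no score) and
`too_few_carriers` (< 2 carriers of one allele).

## Local ancestry (`ancestry`)

Inputs are per-haplotype, per-site binary labels (0 African,
1 non-African), the shape of RFmix output; the package never infers
ancestry itself. The enrichment test compares the focal site's
non-African proportion against the genome-wide per-site distribution
(upper-tail r/n), optionally restricting the background to sites whose
focal-population MAF is within a tolerance (default ±0.01) of the focal
site's, and requires ≥ 100 background sites.

Tract dating inverts the single-pulse exponential approximation: tracts of
the ancestry present at fraction f have mean genetic length
1/((1−f)·T) Morgans, so T̂ = 1/(mean·(1−f)). Tract boundaries inside the
region are placed at the midpoint between the two sites where the label
changes (unbiased when marker spacing is dense relative to tract lengths);
tracts touching either end of the region are censored out of the mean.
The approximation ignores tract mergers and drift, both mild for
T ~ tens of generations and f near 0.5; the simulator-recovery tests
bound the combined bias at < 10% for T = 68.

Years = generations × generation time, with a 30-year default, reported
unrounded; comparisons against conventionally rounded year values use a
±1-year tolerance.

## Matched background (`background`)

Background SNPs must (1) match the target's source-population frequency
within ±0.01 (source frequencies are quantized by sample size, so exact
matching is a degenerate special case; the tolerance is configurable),
(2) be at frequency ≤ 0 (default: exactly absent) in the outgroup, and
(3) have MAF > 5% in the focal population. The target is always excluded
from its own background. The empirical P of the target's |iHS| is r/n over
the selected set. An empty selection raises an error that reports how many
sites passed each condition separately, so the limiting filter is visible.

## Synthetic data (`simulate`)

The generators state a world; their defaults are fixed once and are not
tuned to test outcomes.

- **Trajectories.** Deterministic mode is the closed form above;
  stochastic mode applies the same per-generation odds update and then
  binomially resamples 2Ne copies (Wright–Fisher drift around the
  deterministic path). Frequencies 0 and 1 are absorbing.
- **Sweep/neutral panels.** Forward Wright–Fisher on 2Ne haplotypes over a
  region (default 2 Mb at 1 cM/Mb, 600 segregating sites — a realistic
  common-variant density of ~1 SNP per 3.3 kb). Founding haplotypes draw
  per-site derived frequencies from Beta(0.5, 0.5) (redrawn if
  monomorphic) at linkage equilibrium — a pragmatic stand-in for a neutral
  site-frequency spectrum; haplotype structure then accrues by drift. Each
  generation, parents are sampled proportional to fitness e^s per derived
  copy at the focal site and offspring recombine with Poisson crossovers
  per Morgan. Conditioned sweeps restart from a fresh substream if the
  derived allele is lost, counting restarts in the truth record. No new
  mutations, no demography beyond constant Ne, two alleles per site.
- **Admixture mosaics.** A single pulse T generations ago: breakpoints are
  a Poisson process at rate T per Morgan along the genetic map, each
  segment copies a uniformly chosen haplotype from the non-African source
  with probability f, else the African source. True per-site ancestry and
  per-segment donors are recorded. This "copying" model has no post-pulse
  drift or selection on ancestry and exactly matches the exponential tract
  approximation the dating utility inverts — so tract-dating tests
  validate the estimator's algebra and the discretization, not the
  adequacy of the exponential model for real genomes.
- **Reproducibility.** One global seed expands into named, independent
  substreams (CRC-keyed `SeedSequence` spawn keys) per generator call;
  identical seed + config gives bit-identical output.

What a green simulation test therefore establishes: internal consistency
of the statistics with their definitions, detectability of strong sweeps
under the stated world, and unbiasedness of the estimators under their own
model assumptions. It does not establish robustness to demographic
misspecification, background selection, genotyping error, phasing error,
or ancestry-inference error, none of which the generators emulate.

## Numerical choices

- Trajectory evaluation uses the log-odds form to avoid overflow at large
  |s|T; generation 0 is set to ν₀ exactly.
- WC84 components use exact float arithmetic on counts; θ̂ is NaN (never
  ±inf) when a+b+c = 0.
- Genome-wide pair sd < 1e-12 is treated as zero (exactly-constant arrays
  carry ~1e-17 rounding noise).
- EHH group refinement relabels via bincount + searchsorted; equality with
  the pairwise oracle is exact, not approximate.
- LR endpoints: Brent with xtol 1e-12 on a bracket found by doubling from
  the MLE; profile grids are for inspection only and never feed inference.
- Empirical P ties count as exceedances (≥), making P monotone and
  conservative.

## Known limitations

- The selection likelihood ignores drift and ancestry-proportion
  uncertainty; intervals are accordingly anti-conservative.
- Desk-scale panels cannot populate 1% frequency bins the way genome-wide
  scans do; sparse bins are left unscored rather than merged, and the
  reference-standardization mechanism exists precisely so small regions
  can borrow bins from a larger background.
- The tract-length estimator censors terminal tracts; for short regions or
  large T this discards most tracts and inflates variance.
- Only two ancestry sources and a single pulse are modeled; multi-wave
  admixture biases T̂ toward the more recent wave.
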