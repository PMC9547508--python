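"""Post-admixture selection-coefficient inference.

The model: an allele enters the admixed population at frequency
``nu0 = nu_source * f_nah`` (source-population frequency times the fraction
of introduced haplotypes), evolves deterministically for T generations under
constant genic selection s,

    nu(nu0, T, s) = x0 e^{sT} / (1 + x0 e^{sT}),    x0 = nu0 / (1 - nu0),

and is then observed as k selected alleles among N sampled chromosomes, with
binomial likelihood P(k | N, nu0, T, s) = Binom(k; N, nu(nu0, T, s)).  The
MLE maximizes this over s (flat prior); with 0 < k < N it has the closed
form s_hat = ln[(k/(N-k)) * (1-nu0)/nu0] / T, which anchors the numerical
optimizer.  Uncertainty is the likelihood-ratio interval: all s whose
likelihood is within a chosen factor (default 100, the "LR100" interval) of
the maximum.

Drift is deliberately absent from the likelihood — the model is a
deterministic trajectory plus one binomial sampling step — so the interval
understates uncertainty when Ne is small; :func:`recover_s_simulation`
quantifies this against the stochastic trajectory simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .simulate import simulate_trajectory
from ._rng import substream

__all__ = [
    "SelectionModelInput",
    "SelectionEstimate",
    "trajectory",
    "binomial_loglik",
    "estimate_s",
    "lr_interval",
    "recover_s_simulation",
]


@dataclass
class SelectionModelInput:
    """Scalar inputs of the selection-coefficient model.

    Either give ``nu0`` directly, or ``nu_source`` and ``f_nah`` (then
    ``nu0 = nu_source * f_nah``).
    """

    T: float
    N: int
    k: int
    nu0: float | None = None
    nu_source: float | None = None
    f_nah: float | None = None

    def __post_init__(self) -> None:
        if self.nu0 is None:
            if self.nu_source is None or self.f_nah is None:
                raise ValueError("give nu0, or both nu_source and f_nah")
            self.nu0 = self.nu_source * self.f_nah
        if not 0.0 < self.nu0 < 1.0:
            raise ValueError("nu0 must lie strictly in (0, 1)")
        if self.T <= 0:
            raise ValueError("T must be positive")
        if not 0 <= self.k <= self.N:
            raise ValueError("need 0 <= k <= N")


@dataclass
class SelectionEstimate:
    """MLE of s with its likelihood-ratio interval and profile."""

    s_hat: float
    lr_factor: float
    interval: tuple[float, float]
    loglik_max: float
    profile: np.ndarray = field(repr=False)  # (n, 2) columns (s, logL)

    @property
    def s_hat_percent(self) -> float:
        return 100.0 * self.s_hat

    @property
    def interval_percent(self) -> tuple[float, float]:
        return (100.0 * self.interval[0], 100.0 * self.interval[1])


def trajectory(nu0: float, T: float, s: float) -> float:
    """Deterministic allele frequency after T generations of selection s."""
    if not 0.0 < nu0 < 1.0:
        raise ValueError("nu0 must lie strictly in (0, 1)")
    # log-odds form is overflow-safe for large |s| T
    logit = math.log(nu0 / (1.0 - nu0)) + s * T
    if logit > 0:
        return 1.0 / (1.0 + math.exp(-logit))
    e = math.exp(logit)
    return e / (1.0 + e)


def binomial_loglik(k: int, N: int, nu: float) -> float:
    """Log binomial pmf ln C(N,k) + k ln nu + (N-k) ln(1-nu), with 0 ln 0 = 0."""
    if not 0.0 <= nu <= 1.0:
        raise ValueError("nu must lie in [0, 1]")
    if not 0 <= k <= N:
        raise ValueError("need 0 <= k <= N")
    return float(stats.binom.logpmf(k, N, nu))


def _loglik_s(s: float, inp: SelectionModelInput) -> float:
    return binomial_loglik(inp.k, inp.N, trajectory(inp.nu0, inp.T, s))


def closed_form_s(inp: SelectionModelInput) -> float:
    """Exact MLE for 0 < k < N: matches nu(nu0, T, s) to k/N."""
    if not 0 < inp.k < inp.N:
        raise ValueError("closed form requires 0 < k < N")
    return math.log((inp.k / (inp.N - inp.k)) * (1.0 - inp.nu0) / inp.nu0) / inp.T


def estimate_s(
    inp: SelectionModelInput,
    lr_factor: float = 100.0,
    profile_points: int = 201,
) -> SelectionEstimate:
    """Maximum-likelihood s with its LR interval and an evaluated profile.

    The MLE is found by Nelder–Mead on the negative log-likelihood
    (tolerance 1e-15); with k = 0 or k = N the MLE diverges and the result
    carries a signed infinity with an open interval endpoint on that side.
    """
    if inp.k == 0 or inp.k == inp.N:
        sign = -1.0 if inp.k == 0 else 1.0
        s_hat = sign * math.inf
        loglik_max = 0.0  # lim_{s -> sign*inf} logL = ln 1
        lo, hi = _lr_endpoints(inp, s_hat, loglik_max, lr_factor)
        grid = np.linspace(-0.2, 0.2, profile_points)
        prof = np.column_stack([grid, [_loglik_s(s, inp) for s in grid]])
        return SelectionEstimate(s_hat, lr_factor, (lo, hi), loglik_max, prof)

    res = optimize.minimize(
        lambda s: -_loglik_s(float(s[0]), inp),
        x0=[0.0],
        method="Nelder-Mead",
        tol=1e-15,
        options={"maxiter": 10_000, "fatol": 1e-15, "xatol": 1e-15},
    )
    s_hat = float(res.x[0])
    loglik_max = float(-res.fun)
    lo, hi = _lr_endpoints(inp, s_hat, loglik_max, lr_factor)
    span = max(hi - lo, 1e-4) if math.isfinite(hi - lo) else 0.1
    grid = np.linspace(lo - 0.25 * span, hi + 0.25 * span, profile_points)
    prof = np.column_stack([grid, [_loglik_s(s, inp) for s in grid]])
    return SelectionEstimate(s_hat, lr_factor, (lo, hi), loglik_max, prof)


def _lr_endpoints(
    inp: SelectionModelInput,
    s_hat: float,
    loglik_max: float,
    lr_factor: float,
) -> tuple[float, float]:
    if lr_factor < 1.0:
        raise ValueError("lr_factor must be >= 1")
    if lr_factor == 1.0 and math.isfinite(s_hat):
        return (s_hat, s_hat)
    drop = math.log(lr_factor)
    target = loglik_max - drop

    def deficit(s: float) -> float:
        return _loglik_s(s, inp) - target

    def bracket(direction: float, start: float) -> float:
        step = 0.01
        a = start
        for _ in range(200):
            b = a + direction * step
            if deficit(b) < 0.0:
                lo, hi = (a, b) if direction > 0 else (b, a)
                return float(optimize.brentq(deficit, lo, hi, xtol=1e-12, rtol=1e-14))
            a = b
            step *= 2.0
        raise RuntimeError("failed to bracket the LR endpoint")

    if not math.isfinite(s_hat):
        # one-sided: likelihood is monotone in s
        if s_hat > 0:  # k = N: lower endpoint only
            return (bracket(-1.0, 1.0), math.inf)
        return (-math.inf, bracket(+1.0, -1.0))
    return (bracket(-1.0, s_hat), bracket(+1.0, s_hat))


def lr_interval(inp: SelectionModelInput, lr_factor: float = 100.0) -> tuple[float, float]:
    """The connected set of s whose likelihood is within 1/lr_factor of the max."""
    return estimate_s(inp, lr_factor=lr_factor).interval


def recover_s_simulation(
    true_s: float,
    nu0: float,
    T: int,
    Ne: int,
    N: int,
    replicates: int,
    seed: int,
    lr_factor: float = 100.0,
) -> dict:
    """Estimator validation against the stochastic trajectory simulator.

    Each replicate simulates a Wright–Fisher trajectory under ``true_s``,
    binomially samples k of N chromosomes at generation T, and re-estimates
    s.  Returns the per-replicate estimates plus mean bias and the fraction
    of LR intervals covering ``true_s``.
    """
    rng = substream(seed, "recover-s")
    estimates = np.empty(replicates)
    covered = 0
    for r in range(replicates):
        traj = simulate_trajectory(
            nu0, true_s, T, mode="stochastic", Ne=Ne, seed=int(rng.integers(2**31))
        )
        k = int(rng.binomial(N, traj.final_freq))
        est = estimate_s(SelectionModelInput(T=T, N=N, k=k, nu0=nu0), lr_factor=lr_factor)
        estimates[r] = est.s_hat
        if est.interval[0] <= true_s <= est.interval[1]:
            covered += 1
    finite = estimates[np.isfinite(estimates)]
    return {
        "estimates": estimates,
        "mean_s_hat": float(finite.mean()),
        "mean_bias": float(finite.mean() - true_s),
        "coverage": covered / replicates,
        "n_divergent": int(replicates - finite.size),
    }
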