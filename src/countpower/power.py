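"""Closed-form statistical power for NB differential expression.

For a two-group comparison with ``n`` samples per group, fold change
``Delta``, two-sided significance level ``alpha``, average sequencing
coverage ``mu`` (reads per gene) and biological coefficient of variation
``sigma``, the power of detecting the change satisfies

    (z_{1-alpha/2} + z_beta)^2 = n * (ln Delta)^2 / (2 * (1/mu + sigma^2))

The ``1/mu`` term is the Poisson (counting) noise, ``sigma^2`` the
biological variance of true expression between replicates; once coverage
is deep the biological term dominates and more depth no longer buys
power.  Solved for power this is

    power = Phi( sqrt( n (ln Delta)^2 / (2 (1/mu + sigma^2)) ) - z_{1-alpha/2} )

i.e. a two-sided test with rejection mass taken in the tail favored by
the true effect.  At Delta = 1 the formula degenerates to alpha/2 —
rejections in the favored tail by chance alone.

When thousands of genes are tested the per-gene significance level must
target a false discovery rate instead: with ``m`` genes, expected true
positive fraction ``pi1`` (so ``r1 = pi1 * m`` expected true positives and
``m0 = (1 - pi1) * m`` true nulls) and desired FDR ``f``,

    alpha* = r1 * f / (m0 * (1 - f))

replaces alpha in the power formula, giving per-gene *detectability*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import AnalysisConfig, CountDataError, CountMatrix, SampleDesign
from .dispersion import DispersionEstimates

__all__ = [
    "PowerSpec",
    "FdrAdjustment",
    "power_single",
    "sample_size",
    "fdr_alpha",
    "power_curve",
    "genewise_power",
]


@dataclass
class PowerSpec:
    """Parameters of the single-gene power formula."""

    n: int
    delta: float
    alpha: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise CountDataError("sample size n must be >= 1")
        if self.delta <= 0:
            raise CountDataError("fold change delta must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise CountDataError("alpha must lie in (0, 1)")
        if self.mu <= 0:
            raise CountDataError("coverage mu must be positive")
        if self.sigma < 0:
            raise CountDataError("BCOV sigma must be non-negative")

    @property
    def power(self) -> float:
        return power_single(self)


def _power_values(n, delta, alpha, mu, sigma):
    n = np.asarray(n, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(mu <= 0):
        raise CountDataError("coverage mu must be positive")
    if delta <= 0:
        raise CountDataError("fold change delta must be positive")
    if not 0.0 < alpha < 1.0:
        raise CountDataError("alpha must lie in (0, 1)")
    z_alpha = norm.ppf(1.0 - alpha / 2.0)
    effect = np.sqrt(n * np.log(delta) ** 2 / (2.0 * (1.0 / mu + sigma ** 2)))
    return np.clip(norm.cdf(effect - z_alpha), 0.0, 1.0)


def power_single(
    spec: PowerSpec | None = None,
    *,
    n: int | None = None,
    delta: float | None = None,
    alpha: float | None = None,
    mu: float | None = None,
    sigma: float | None = None,
) -> float:
    """Power of detecting a ``delta``-fold change for one gene.

    Accepts either a :class:`PowerSpec` or the five keyword parameters.
    """
    if spec is not None:
        n, delta, alpha, mu, sigma = spec.n, spec.delta, spec.alpha, spec.mu, spec.sigma
    if None in (n, delta, alpha, mu, sigma):
        raise CountDataError("power_single needs a PowerSpec or all five parameters")
    return float(_power_values(n, delta, alpha, mu, sigma))


def sample_size(
    delta: float,
    alpha: float,
    mu: float,
    sigma: float,
    target_power: float,
    n_max: int = 1000,
) -> int:
    """Smallest per-group sample size n >= 2 reaching ``target_power``."""
    if not 0.0 < target_power < 1.0:
        raise CountDataError("target_power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        if power_single(n=n, delta=delta, alpha=alpha, mu=mu, sigma=sigma) >= target_power:
            return n
    asymptote = power_single(n=n_max, delta=delta, alpha=alpha, mu=mu, sigma=sigma)
    raise CountDataError(
        f"target power {target_power} not reachable with n <= {n_max} "
        f"(power at n={n_max} is {asymptote:.4f})"
    )


@dataclass
class FdrAdjustment:
    """FDR-level to per-test significance conversion."""

    f: float
    m: int
    pi1: float

    def __post_init__(self) -> None:
        if not 0.0 < self.f < 1.0:
            raise CountDataError("FDR level f must lie in (0, 1)")
        if not 0.0 < self.pi1 < 1.0:
            raise CountDataError("pi1 must lie in (0, 1)")
        if self.m < 1:
            raise CountDataError("m must be >= 1")

    @property
    def r1(self) -> float:
        return self.pi1 * self.m

    @property
    def m0(self) -> float:
        return (1.0 - self.pi1) * self.m

    @property
    def alpha_star(self) -> float:
        a = self.r1 * self.f / (self.m0 * (1.0 - self.f))
        if not 0.0 < a < 1.0:
            raise CountDataError(
                f"degenerate FDR configuration: alpha* = {a:.4g} outside (0, 1)"
            )
        return a


def fdr_alpha(f: float, m: int, pi1: float) -> float:
    """Per-test significance level targeting FDR ``f`` over ``m`` genes."""
    return FdrAdjustment(f=f, m=m, pi1=pi1).alpha_star


def power_curve(
    delta: float, alpha: float, mu: float, sigma: float, n_range
) -> list[tuple[int, float]]:
    """Power at each per-group sample size in ``n_range``."""
    ns = [int(n) for n in n_range]
    if not ns or min(ns) < 2:
        raise CountDataError("n_range must be non-empty integers >= 2")
    return [
        (n, power_single(n=n, delta=delta, alpha=alpha, mu=mu, sigma=sigma))
        for n in ns
    ]


def genewise_power(
    cm: CountMatrix,
    sd: SampleDesign,
    comparison: tuple[str, str],
    disp: DispersionEstimates,
    config: AnalysisConfig,
    log2cpm: np.ndarray | None = None,
    mu_override: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene detectability table on the log2CPM-BCOV plane.

    For every gene: coverage ``mu_g`` (mean raw count across the
    comparison's samples, i.e. CPM_g x library-size-in-millions),
    ``sigma_g`` from the tagwise dispersion, the FDR-adjusted significance
    level ``alpha*`` computed for the whole gene set, and power at the
    smaller group's sample size.  A gene is *detectable* when its power
    reaches ``config.power_detectable_cutoff``.
    """
    a, b = sd.resolve_comparison(comparison)
    samples = sd.comparison_samples((a, b))
    idx = [cm.sample_ids.index(s) for s in samples]
    sigma_g = disp.bcov_tagwise
    if sigma_g.shape[0] != cm.n_genes:
        raise CountDataError(
            f"dispersion has {sigma_g.shape[0]} genes but counts have {cm.n_genes}"
        )
    if mu_override is not None:
        mu_g = np.asarray(mu_override, dtype=float)
    else:
        mu_g = cm.counts[:, idx].mean(axis=1)
    mu_g = np.maximum(mu_g, 1e-8)  # power of an unexpressed gene is ~alpha*/2

    n = min(len(sd.samples_in(a)), len(sd.samples_in(b)))
    alpha_star = fdr_alpha(config.fdr_level, cm.n_genes, config.true_positive_fraction)
    p_g = _power_values(n, config.fold_change, alpha_star, mu_g, sigma_g)

    if log2cpm is None:
        from .normalize import cpm as _cpm, tmm_factors as _tmm

        log2cpm = _cpm(cm, _tmm(cm), log=True)
    mean_log2cpm = np.asarray(log2cpm, dtype=float)[:, idx].mean(axis=1)

    table = pd.DataFrame(
        {
            "mean_coverage": mu_g,
            "log2cpm": mean_log2cpm,
            "bcov": sigma_g,
            "power": p_g,
            "detectable": p_g >= config.power_detectable_cutoff,
        },
        index=pd.Index(cm.gene_ids, name="gene_id"),
    )
    table.attrs["alpha_star"] = alpha_star
    table.attrs["n_per_group"] = n
    table.attrs["comparison"] = (a, b)
    return table
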