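"""Negative-binomial dispersion estimation (common and tagwise) and BCOV.

The NB model used throughout is mean/dispersion parameterized:
``Var(Y) = mu + phi * mu^2``.  The biological coefficient of variation
(BCOV) is ``sigma = sqrt(phi)`` — the standard deviation of a gene's true
relative expression between biological replicates.

Estimation follows the quantile-adjusted conditional maximum-likelihood
(qCML) scheme for two-group designs:

1.  *Equalize library sizes*: observed counts are mapped to pseudo-counts
    that would have been observed had every library had the geometric-mean
    size, by matching quantiles of the per-sample NB distribution at the
    current dispersion (averaged normal and gamma approximations).
2.  *Conditional likelihood*: given equal library sizes, the within-group
    sum of NB counts is sufficient for the group mean, and the likelihood
    of the counts conditional on their group sums depends on the
    dispersion alone.  The common dispersion maximizes this conditional
    log-likelihood pooled over genes; equalization and maximization are
    alternated until the estimate is self-consistent.
3.  *Tagwise shrinkage*: per-gene dispersions maximize the gene's own
    conditional log-likelihood plus a ``prior_df``-weighted share of the
    pooled one (weighted-likelihood empirical Bayes), so individual genes
    borrow strength from the ensemble.  ``prior_df -> inf`` collapses all
    tagwise estimates onto the common value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, gammainc, gammaincinv
from scipy.interpolate import CubicSpline

from .io import CountDataError, CountMatrix, SampleDesign

__all__ = [
    "DispersionEstimates",
    "common_dispersion",
    "tagwise_dispersion",
    "estimate_dispersion",
    "bcov",
]

PHI_MIN = 1e-6
PHI_MAX = 10.0
DEFAULT_PRIOR_DF = 10.0


@dataclass
class DispersionEstimates:
    """Common and per-gene NB dispersions with their BCOVs."""

    common: float
    tagwise: np.ndarray
    prior_df: float

    @property
    def bcov_common(self) -> float:
        return float(np.sqrt(self.common))

    @property
    def bcov_tagwise(self) -> np.ndarray:
        return np.sqrt(self.tagwise)


def bcov(phi):
    """Biological coefficient of variation: elementwise sqrt(dispersion)."""
    arr = np.asarray(phi, dtype=float)
    if np.any(arr < 0):
        raise CountDataError("dispersion must be non-negative")
    out = np.sqrt(arr)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# quantile-matching pseudo-counts
# ---------------------------------------------------------------------------

def _q2q_nbinom(y: np.ndarray, mu_in: np.ndarray, mu_out: np.ndarray, phi: float) -> np.ndarray:
    """Map counts between NB distributions by matching quantiles.

    Averages a normal and a gamma approximation of the NB quantile map,
    which is accurate over the whole count range and smooth in ``y``
    (fractional counts supported).
    """
    y = np.asarray(y, dtype=float)
    mu_in = np.maximum(np.asarray(mu_in, dtype=float), 1e-10)
    mu_out = np.maximum(np.asarray(mu_out, dtype=float), 1e-10)
    v_in = mu_in * (1.0 + phi * mu_in)
    v_out = mu_out * (1.0 + phi * mu_out)

    z = (y - mu_in) / np.sqrt(v_in)
    out_norm = mu_out + z * np.sqrt(v_out)

    shape_in = mu_in ** 2 / v_in
    scale_in = v_in / mu_in
    shape_out = mu_out ** 2 / v_out
    scale_out = v_out / mu_out
    p = gammainc(shape_in, y / scale_in)
    p = np.clip(p, 0.0, 1.0 - 1e-14)
    out_gam = gammaincinv(shape_out, p) * scale_out

    pseudo = 0.5 * (out_norm + out_gam)
    return np.maximum(pseudo, 0.0)


def _group_indices(
    cm: CountMatrix, sd: SampleDesign, comparison: tuple[str, str]
) -> list[np.ndarray]:
    a, b = sd.resolve_comparison(comparison)
    idx = []
    for g in (a, b):
        samples = sd.samples_in(g)
        idx.append(np.array([cm.sample_ids.index(s) for s in samples]))
    return idx


def _equalize(
    counts: np.ndarray, lib: np.ndarray, groups: list[np.ndarray], phi: float
) -> tuple[np.ndarray, float]:
    """Pseudo-counts on a common (geometric-mean) library size."""
    common_lib = float(np.exp(np.mean(np.log(lib))))
    pseudo = np.array(counts, dtype=float, copy=True)
    for idx in groups:
        group_tot = counts[:, idx].sum(axis=1)
        lib_tot = lib[idx].sum()
        p_g = group_tot / lib_tot  # per-gene relative abundance in this group
        for j in idx:
            pseudo[:, j] = _q2q_nbinom(counts[:, j], p_g * lib[j], p_g * common_lib, phi)
    return pseudo, common_lib


# ---------------------------------------------------------------------------
# conditional log-likelihood
# ---------------------------------------------------------------------------

def _cond_loglik_rows(
    pseudo: np.ndarray, groups: list[np.ndarray], phi: float
) -> np.ndarray:
    """Per-gene conditional NB log-likelihood given group sums.

    Groups with a single sample carry no dispersion information and are
    skipped.  Terms not involving phi are dropped.
    """
    r = 1.0 / max(phi, PHI_MIN / 10)
    ll = np.zeros(pseudo.shape[0])
    for idx in groups:
        n = idx.size
        if n < 2:
            continue
        y = pseudo[:, idx]
        z = y.sum(axis=1)
        ll += (
            gammaln(y + r).sum(axis=1)
            - gammaln(z + n * r)
            + gammaln(n * r)
            - n * gammaln(r)
        )
    return ll


def _golden_max(fun, lo: float, hi: float, tol: float = 1e-6) -> float:
    """Golden-section maximizer of ``fun`` over log-dispersion [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = np.log(lo), np.log(hi)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fun(np.exp(c)), fun(np.exp(d))
    while (b - a) > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(np.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(np.exp(d))
    return float(np.exp(0.5 * (a + b)))


def _moment_dispersion(
    counts: np.ndarray, lib: np.ndarray, groups: list[np.ndarray]
) -> float:
    """Method-of-moments starting value on depth-equalized counts."""
    common_lib = float(np.exp(np.mean(np.log(lib))))
    x = counts * (common_lib / lib)[None, :]
    est = []
    for idx in groups:
        if idx.size < 2:
            continue
        m = x[:, idx].mean(axis=1)
        v = x[:, idx].var(axis=1, ddof=1)
        ok = m > 0
        if np.any(ok):
            est.append((v[ok] - m[ok]) / m[ok] ** 2)
    if not est:
        return 0.1
    med = float(np.median(np.concatenate(est)))
    return float(np.clip(med, PHI_MIN, PHI_MAX))


def _check_replication(groups: list[np.ndarray]) -> None:
    if all(idx.size < 2 for idx in groups):
        raise CountDataError(
            "no replication in any comparison group: the dispersion cannot be "
            "estimated from these data; supply a dispersion value explicitly"
        )


def _effective_libs(cm: CountMatrix) -> np.ndarray:
    """TMM-corrected library sizes (plain sizes if TMM is unavailable)."""
    from .normalize import effective_library_sizes, tmm_factors

    try:
        return effective_library_sizes(cm, tmm_factors(cm))
    except CountDataError:
        return cm.library_sizes()


def common_dispersion(
    cm: CountMatrix,
    sd: SampleDesign,
    comparison: tuple[str, str],
    tol: float = 1e-6,
    max_iter: int = 10,
) -> float:
    """qCML common NB dispersion for a two-group comparison.

    Starts from a method-of-moments value, then alternates library-size
    equalization and conditional-likelihood maximization (log-grid scan
    refined by golden section) until the estimate is self-consistent.
    """
    groups = _group_indices(cm, sd, comparison)
    _check_replication(groups)
    lib = _effective_libs(cm)
    counts = cm.counts

    phi = _moment_dispersion(counts, lib, groups)
    for _ in range(max_iter):
        pseudo, _ = _equalize(counts, lib, groups, phi)

        def total(p: float) -> float:
            return float(_cond_loglik_rows(pseudo, groups, p).sum())

        grid = np.logspace(np.log10(PHI_MIN), np.log10(PHI_MAX), 60)
        vals = [total(p) for p in grid]
        j = int(np.argmax(vals))
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, grid.size - 1)]
        new_phi = _golden_max(total, lo, hi, tol=tol)
        if abs(np.log(new_phi) - np.log(phi)) < 1e-4:
            phi = new_phi
            break
        phi = new_phi
    return float(np.clip(phi, PHI_MIN, PHI_MAX))


def tagwise_dispersion(
    cm: CountMatrix,
    sd: SampleDesign,
    comparison: tuple[str, str],
    phi_common: float,
    prior_df: float = DEFAULT_PRIOR_DF,
) -> np.ndarray:
    """Per-gene dispersions by weighted-likelihood empirical Bayes.

    Each gene maximizes ``ll_g(phi) + (prior_df / residual_df) * mean_g
    ll_g(phi)``; the shared term pulls gene estimates toward the common
    dispersion with strength set by ``prior_df``.
    """
    groups = _group_indices(cm, sd, comparison)
    _check_replication(groups)
    lib = _effective_libs(cm)
    pseudo, _ = _equalize(cm.counts, lib, groups, phi_common)

    res_df = sum(max(idx.size - 1, 0) for idx in groups)
    weight = float(prior_df) / max(res_df, 1)

    # per-gene conditional log-likelihood on a dense dispersion grid
    grid = np.logspace(np.log10(PHI_MIN), np.log10(PHI_MAX), 141)
    ll_grid = np.stack([_cond_loglik_rows(pseudo, groups, p) for p in grid], axis=1)
    shared_grid = ll_grid.mean(axis=0)
    shared = CubicSpline(np.log(grid), shared_grid)

    obj_grid = ll_grid + weight * shared_grid[None, :]
    j_best = np.argmax(obj_grid, axis=1)

    n_genes = pseudo.shape[0]
    phi_g = np.empty(n_genes)
    for g in range(n_genes):
        j = j_best[g]
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, grid.size - 1)]
        row = pseudo[g : g + 1, :]

        def obj(p: float) -> float:
            return float(
                _cond_loglik_rows(row, groups, p)[0] + weight * shared(np.log(p))
            )

        phi_g[g] = _golden_max(obj, lo, hi)
    return np.clip(phi_g, PHI_MIN, PHI_MAX)


def estimate_dispersion(
    cm: CountMatrix,
    sd: SampleDesign,
    comparison: tuple[str, str],
    prior_df: float = DEFAULT_PRIOR_DF,
) -> DispersionEstimates:
    """Common + tagwise dispersion in one pass."""
    phi_c = common_dispersion(cm, sd, comparison)
    phi_g = tagwise_dispersion(cm, sd, comparison, phi_c, prior_df=prior_df)
    return DispersionEstimates(common=phi_c, tagwise=phi_g, prior_df=float(prior_df))
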