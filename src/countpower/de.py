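"""Differential expression and power-informed triage.

Two tests are provided, matching standard NB count-model practice:

* :func:`exact_test` — for a plain two-group comparison.  Library sizes
  are first equalized by quantile-matched pseudo-counts; conditional on
  the total pseudo-count of a gene, the split between the two groups has
  a distribution (product of two NB sums) that is free of the common
  mean, and the two-sided p-value sums the probabilities of all splits no
  more likely than the observed one (minimum-likelihood method).
* :func:`glm_ql_test` — for designs with covariates (replicate, batch).
  Each gene gets an NB log-linear model with the gene's tagwise
  dispersion fixed and offset log effective library size; residual
  quasi-dispersions are squeezed toward a common value by empirical
  Bayes, and the group coefficient is tested with a quasi-likelihood
  F-test.

p-values are Benjamini-Hochberg adjusted within one comparison.  The
*triage* step crosses DE calls with per-gene detectability to separate
confident negatives (NDE&DT) from likely false negatives (NDE&NDT), and
:func:`build_signature` exports the combined DE + confident-negative
gene list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, polygamma
from scipy.stats import f as f_dist, nbinom
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .io import AnalysisConfig, CountDataError, CountMatrix, SampleDesign
from .dispersion import DispersionEstimates, _q2q_nbinom
from .normalize import cpm as _cpm, effective_library_sizes, tmm_factors

__all__ = [
    "exact_test",
    "glm_ql_test",
    "bh_adjust",
    "triage",
    "Signature",
    "build_signature",
    "ma_data",
]

TRIAGE_LABELS = ("DE", "NDE_DT", "NDE_NDT")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise CountDataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _resolve_dispersion(disp, n_genes: int) -> np.ndarray:
    if isinstance(disp, DispersionEstimates):
        phi = disp.tagwise
    else:
        phi = np.asarray(disp, dtype=float)
        if phi.ndim == 0:
            phi = np.full(n_genes, float(phi))
    if phi.shape[0] != n_genes:
        raise CountDataError(
            f"dispersion length {phi.shape[0]} does not match {n_genes} genes"
        )
    return np.maximum(phi, 1e-6)


def _nb_logpmf(a, mean, r):
    """NB log-pmf in gamma form (valid for non-integer a)."""
    a = np.asarray(a, dtype=float)
    logp = np.log(r) - np.log(r + mean)
    log1mp = np.log(mean) - np.log(r + mean) if mean > 0 else -np.inf
    return gammaln(a + r) - gammaln(r) - gammaln(a + 1.0) + r * logp + a * log1mp


def _exact_pvalue(s_a: float, s_b: float, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional NB p-value for a split (s_a, s_b) of equalized
    group sums, by the minimum-likelihood rule."""
    total = s_a + s_b
    if total <= 0:
        return 1.0
    t = int(round(total))
    if t == 0:
        return 1.0
    lam = total / (n_a + n_b)
    mu_a, mu_b = n_a * lam, n_b * lam
    r_a, r_b = n_a / phi, n_b / phi

    # window holding all non-negligible conditional mass
    p_a = r_a / (r_a + mu_a)
    p_b = r_b / (r_b + mu_b)
    lo_a = nbinom.ppf(1e-14, r_a, p_a)
    hi_a = nbinom.isf(1e-14, r_a, p_a)
    lo_b = nbinom.ppf(1e-14, r_b, p_b)
    hi_b = nbinom.isf(1e-14, r_b, p_b)
    lo = int(max(0, min(lo_a, t - hi_b) - 5))
    hi = int(min(t, max(hi_a, t - lo_b) + 5))
    grid = np.arange(lo, hi + 1, dtype=float)

    logf = _nb_logpmf(grid, mu_a, r_a) + _nb_logpmf(t - grid, mu_b, r_b)
    a_obs = s_a * t / total  # observed split rescaled onto the integer total
    logf_obs = float(_nb_logpmf(a_obs, mu_a, r_a) + _nb_logpmf(t - a_obs, mu_b, r_b))

    m = logf.max()
    f = np.exp(logf - m)
    keep = logf <= logf_obs + 1e-7
    p = f[keep].sum() / f.sum()
    return float(min(p, 1.0))


def _comparison_layout(cm: CountMatrix, sd: SampleDesign, comparison):
    a, b = sd.resolve_comparison(comparison)
    idx_a = np.array([cm.sample_ids.index(s) for s in sd.samples_in(a)])
    idx_b = np.array([cm.sample_ids.index(s) for s in sd.samples_in(b)])
    return a, b, idx_a, idx_b


def _mean_log2cpm(cm: CountMatrix, idx: np.ndarray) -> np.ndarray:
    log2cpm = _cpm(cm, tmm_factors(cm), log=True)
    return log2cpm[:, idx].mean(axis=1)


def exact_test(
    cm: CountMatrix,
    sd: SampleDesign,
    comparison: tuple[str, str],
    disp,
) -> pd.DataFrame:
    """Gene-wise exact NB test between two groups (no covariates).

    ``disp`` may be a :class:`DispersionEstimates`, a per-gene array, or a
    scalar.  Returns a frame with ``log2_fc`` (B over A), ``mean_log2cpm``,
    ``p_value`` and BH-adjusted ``fdr``.
    """
    a, b, idx_a, idx_b = _comparison_layout(cm, sd, comparison)
    phi = _resolve_dispersion(disp, cm.n_genes)
    # effective (TMM-corrected) library sizes so composition shifts from a
    # minority of DE genes do not masquerade as depth differences
    lib = effective_library_sizes(cm, tmm_factors(cm))
    comp_idx = np.concatenate([idx_a, idx_b])
    common_lib = float(np.exp(np.mean(np.log(lib[comp_idx]))))

    # quantile-equalize library sizes within each group at the gene's phi
    pseudo = np.empty((cm.n_genes, comp_idx.size))
    pos = 0
    for idx in (idx_a, idx_b):
        group_tot = cm.counts[:, idx].sum(axis=1)
        p_g = group_tot / lib[idx].sum()
        for j in idx:
            pseudo[:, pos] = _q2q_nbinom(
                cm.counts[:, j], p_g * lib[j], p_g * common_lib, phi
            )
            pos += 1
    n_a, n_b = idx_a.size, idx_b.size
    s_a = pseudo[:, :n_a].sum(axis=1)
    s_b = pseudo[:, n_a:].sum(axis=1)

    pvals = np.array(
        [_exact_pvalue(s_a[g], s_b[g], n_a, n_b, phi[g]) for g in range(cm.n_genes)]
    )
    log2_fc = np.log2((s_b / n_b + 0.5) / (s_a / n_a + 0.5))

    res = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "mean_log2cpm": _mean_log2cpm(cm, comp_idx),
            "p_value": pvals,
            "fdr": bh_adjust(pvals),
        },
        index=pd.Index(cm.gene_ids, name="gene_id"),
    )
    res.attrs["method"] = "exact"
    res.attrs["comparison"] = (a, b)
    return res


# ---------------------------------------------------------------------------
# quasi-likelihood GLM
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve polygamma(1, x) = y for x (Newton, monotone decreasing)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes squeezing of scaled-chi-square variances toward a
    common value; returns (posterior variances, prior df d0, prior s0^2)."""
    from scipy.special import digamma

    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 1e-10)
    if ok.sum() < 2:
        return np.maximum(s2, 1e-10), np.inf, float(np.median(np.maximum(s2, 1e-10)))
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(np.mean(e)))
    s2_safe = np.maximum(s2, 1e-10)
    if np.isinf(d0):
        post = np.full_like(s2_safe, s02)
    else:
        post = (d0 * s02 + df * s2_safe) / (d0 + df)
    return post, d0, s02


def build_design_matrix(
    sd: SampleDesign,
    comparison: tuple[str, str],
    covariates: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Intercept + group-B indicator + dummy-coded covariates for the
    comparison's samples.  Raises on rank deficiency, naming aliased
    columns."""
    a, b = sd.resolve_comparison(comparison)
    samples = sd.comparison_samples((a, b))
    X = pd.DataFrame({"intercept": 1.0}, index=samples)
    X[f"group[{b}]"] = [1.0 if sd.group[s] == b else 0.0 for s in samples]
    for cov in covariates or []:
        if cov not in sd.covariates:
            raise CountDataError(f"unknown covariate {cov!r}")
        values = pd.Series([sd.covariates[cov][s] for s in samples], index=samples)
        dummies = pd.get_dummies(values, prefix=cov, drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = []
        cols: list[str] = []
        for c in X.columns:
            trial = cols + [c]
            if np.linalg.matrix_rank(X[trial].to_numpy()) < len(trial):
                aliased.append(c)
            else:
                cols.append(c)
        raise CountDataError(f"design matrix is rank-deficient; aliased columns: {aliased}")
    return X, samples


def glm_ql_test(
    cm: CountMatrix,
    sd: SampleDesign,
    comparison: tuple[str, str],
    covariates: list[str] | None,
    disp,
) -> pd.DataFrame:
    """NB GLM with quasi-likelihood F-test on the group coefficient.

    Per gene the NB log-linear model is fit with the tagwise dispersion
    fixed and offset = log effective library size; the quasi-dispersion is
    the residual deviance over its df, squeezed toward a common value, and
    the group effect is tested by an F statistic on the deviance drop.
    """
    X, samples = build_design_matrix(sd, comparison, covariates)
    idx = np.array([cm.sample_ids.index(s) for s in samples])
    df_res = len(samples) - X.shape[1]
    if df_res < 1:
        raise CountDataError(
            f"residual df = {df_res}: the design leaves no replication to "
            "estimate quasi-dispersions"
        )
    phi = _resolve_dispersion(disp, cm.n_genes)
    eff_lib = effective_library_sizes(cm, tmm_factors(cm))[idx]
    offset = np.log(eff_lib)
    Xn = X.to_numpy()
    group_col = list(X.columns).index(f"group[{sd.resolve_comparison(comparison)[1]}]")
    X_red = np.delete(Xn, group_col, axis=1)

    n_genes = cm.n_genes
    dev_full = np.full(n_genes, np.nan)
    dev_red = np.full(n_genes, np.nan)
    coef = np.zeros(n_genes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for g in range(n_genes):
            y = cm.counts[g, idx]
            fam = sm.families.NegativeBinomial(alpha=float(phi[g]))
            try:
                full = sm.GLM(y, Xn, family=fam, offset=offset).fit(maxiter=100)
                red = sm.GLM(y, X_red, family=fam, offset=offset).fit(maxiter=100)
                dev_full[g] = full.deviance
                dev_red[g] = red.deviance
                coef[g] = full.params[group_col]
            except Exception:
                dev_full[g] = dev_red[g] = 0.0
                coef[g] = 0.0

    s2 = np.maximum(dev_full, 0.0) / df_res
    s2_post, d0, _ = _squeeze_var(s2, df_res)
    f_stat = np.maximum(dev_red - dev_full, 0.0) / s2_post
    df2 = df_res + (d0 if np.isfinite(d0) else 1e6)
    pvals = np.clip(f_dist.sf(f_stat, 1, df2), 0.0, 1.0)

    res = pd.DataFrame(
        {
            "log2_fc": coef / np.log(2.0),
            "mean_log2cpm": _mean_log2cpm(cm, idx),
            "p_value": pvals,
            "fdr": bh_adjust(pvals),
        },
        index=pd.Index(cm.gene_ids, name="gene_id"),
    )
    res.attrs["method"] = "glm_ql"
    res.attrs["comparison"] = sd.resolve_comparison(comparison)
    res.attrs["covariates"] = list(covariates or [])
    res.attrs["ql_prior_df"] = float(d0)
    return res


# ---------------------------------------------------------------------------
# triage and signatures
# ---------------------------------------------------------------------------

def triage(
    de: pd.DataFrame, det: pd.DataFrame, config: AnalysisConfig
) -> tuple[pd.Series, dict[str, int]]:
    """Label each gene DE / NDE_DT / NDE_NDT and count the categories.

    DE: FDR below ``de_fdr_cutoff``.  NDE_DT: not DE but power reaches
    ``power_detectable_cutoff`` (confident negative).  NDE_NDT: neither
    (potential false negative).  The three labels partition the genes.
    """
    if not de.index.equals(det.index):
        raise CountDataError("DE results and detectability table cover different genes")
    is_de = de["fdr"] < config.de_fdr_cutoff
    is_dt = det["power"] >= config.power_detectable_cutoff
    labels = pd.Series(
        np.where(is_de, "DE", np.where(is_dt, "NDE_DT", "NDE_NDT")),
        index=de.index,
        name="triage",
    )
    counts = {lab: int((labels == lab).sum()) for lab in TRIAGE_LABELS}
    return labels, counts


@dataclass
class Signature:
    """Exportable DE signature: likely true positives plus confident
    negatives, with provenance."""

    table: pd.DataFrame
    comparison: tuple[str, str]
    covariates: list[str] = field(default_factory=list)
    fdr_cutoff: float = 0.01
    power_cutoff: float = 0.7

    def __len__(self) -> int:
        return len(self.table)


def build_signature(
    de: pd.DataFrame, det: pd.DataFrame, config: AnalysisConfig
) -> Signature:
    """Genes with FDR < ``signature_fdr_cutoff`` (DE side) plus genes with
    FDR >= cutoff and power >= ``signature_power_cutoff`` (confident
    negatives)."""
    labels, _ = triage(de, det, config)
    is_sig = de["fdr"] < config.signature_fdr_cutoff
    confident_neg = ~is_sig & (det["power"] >= config.signature_power_cutoff)
    keep = is_sig | confident_neg
    table = pd.DataFrame(
        {
            "log2_fc": de["log2_fc"],
            "p_value": de["p_value"],
            "fdr": de["fdr"],
            "power": det["power"],
            "triage": labels,
        }
    )[keep].sort_values("fdr", kind="stable")
    if table.empty:
        warnings.warn("signature is empty under the configured cutoffs")
    return Signature(
        table=table,
        comparison=tuple(de.attrs.get("comparison", ("A", "B"))),
        covariates=list(de.attrs.get("covariates", [])),
        fdr_cutoff=config.signature_fdr_cutoff,
        power_cutoff=config.signature_power_cutoff,
    )


def ma_data(de: pd.DataFrame, de_fdr_cutoff: float = 0.05) -> pd.DataFrame:
    """Per-gene (A, M) table for MA plots with a significance flag."""
    return pd.DataFrame(
        {
            "mean_log2cpm": de["mean_log2cpm"],
            "log2_fc": de["log2_fc"],
            "significant": de["fdr"] < de_fdr_cutoff,
        }
    )
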