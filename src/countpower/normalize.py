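"""Between-sample normalization and expression filtering.

Implements trimmed-mean-of-M-values (TMM) scaling factors, counts per
million (CPM) and log2CPM, the minimum-group-size expression filter, and
median-absolute-deviation ranking of variable genes.

TMM computes, for each sample against a reference sample, gene-wise
log2 ratios (M) and average log2 abundances (A) of library-size-scaled
counts, discards the most extreme 30% of M values on each side and 5% of
A values on each side, and averages the surviving M values weighted by
inverse asymptotic binomial variances.  The resulting per-sample scaling
factors are renormalized to geometric mean 1, so they express relative
composition corrections rather than sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CountDataError, CountMatrix, SampleDesign

__all__ = [
    "NormalizationResult",
    "tmm_factors",
    "cpm",
    "effective_library_sizes",
    "filter_expressed",
    "top_variable_genes",
    "center_rows",
    "normalize",
]

# canonical TMM trim fractions: 30% two-sided on M, 5% two-sided on A
M_TRIM = 0.30
A_TRIM = 0.05


@dataclass
class NormalizationResult:
    tmm_factors: np.ndarray
    effective_lib_sizes: np.ndarray
    cpm: np.ndarray
    log2cpm: np.ndarray


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float
) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2**)."""
    # genes with zero in either sample carry no usable log-ratio
    keep = (obs > 0) & (ref > 0)
    if not np.any(keep):
        return 1.0
    y_o, y_r = obs[keep], ref[keep]
    p_o, p_r = y_o / n_obs, y_r / n_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    w = (n_obs - y_o) / (n_obs * y_o) + (n_ref - y_r) / (n_ref * y_r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * M_TRIM) + 1
    hi_m = n - np.floor(n * M_TRIM)
    lo_a = np.floor(n * A_TRIM) + 1
    hi_a = n - np.floor(n * A_TRIM)
    # rank with average ties, matching the conventional trim rule
    from scipy.stats import rankdata

    rm = rankdata(m)
    ra = rankdata(a)
    sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not np.any(sel) or np.sum(w[sel]) == 0:
        return 1.0
    f = np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])
    return float(2.0 ** f)


def tmm_factors(cm: CountMatrix) -> np.ndarray:
    """Per-sample TMM scaling factors, geometric mean 1.

    The reference sample is the one whose 75th-percentile CPM is closest
    to the mean of all samples' 75th percentiles (deterministic).
    """
    if cm.n_samples < 2:
        raise CountDataError("TMM needs at least 2 samples")
    lib = cm.library_sizes()
    zero = [cm.sample_ids[i] for i in np.flatnonzero(lib == 0)]
    if zero:
        raise CountDataError(f"zero library size for sample(s): {zero}")
    q75 = np.array(
        [np.quantile(cm.counts[:, j] / lib[j], 0.75) for j in range(cm.n_samples)]
    )
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    f = np.array(
        [
            1.0
            if j == ref
            else _tmm_pair(cm.counts[:, j], cm.counts[:, ref], lib[j], lib[ref])
            for j in range(cm.n_samples)
        ]
    )
    # renormalize so factors are comparable across choices of reference
    f /= np.exp(np.mean(np.log(f)))
    return f


def effective_library_sizes(cm: CountMatrix, factors: np.ndarray) -> np.ndarray:
    return cm.library_sizes() * np.asarray(factors, dtype=float)


def cpm(
    cm: CountMatrix,
    factors: np.ndarray | None = None,
    log: bool = False,
    pseudocount: float = 0.5,
) -> np.ndarray:
    """Counts per million on effective library sizes.

    Plain CPM is ``count / (lib_size * factor) * 1e6`` with no offset, so
    CPM > 0 is exactly count > 0.  The log variant stabilizes zeros as
    ``log2((count + pseudocount) / (effective_lib + 1) * 1e6)``.
    """
    if factors is None:
        factors = np.ones(cm.n_samples)
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise CountDataError("normalization factors must be positive")
    eff = effective_library_sizes(cm, factors)
    if log:
        return np.log2((cm.counts + pseudocount) / (eff + 1.0) * 1e6)
    return cm.counts / eff * 1e6


def filter_expressed(
    cm: CountMatrix, sd: SampleDesign, comparison: tuple[str, str]
) -> np.ndarray:
    """Boolean mask of genes expressed (CPM > 0) in at least *m* of the
    comparison's samples, where *m* is the smaller group size."""
    a, b = sd.resolve_comparison(comparison)
    samples_a, samples_b = sd.samples_in(a), sd.samples_in(b)
    if not samples_a or not samples_b:
        raise CountDataError("both comparison groups must be non-empty")
    m = min(len(samples_a), len(samples_b))
    idx = [cm.sample_ids.index(s) for s in samples_a + samples_b]
    n_positive = np.sum(cm.counts[:, idx] > 0, axis=1)
    return n_positive >= m


def _row_mad(x: np.ndarray) -> np.ndarray:
    med = np.median(x, axis=1, keepdims=True)
    return np.median(np.abs(x - med), axis=1)


def top_variable_genes(log2cpm: np.ndarray, gene_ids: list[str], k: int) -> list[str]:
    """Top-k genes by row MAD of log2CPM, descending, stable in ties."""
    n = len(gene_ids)
    if k > n:
        raise CountDataError(f"k={k} exceeds the number of genes ({n})")
    mad = _row_mad(np.asarray(log2cpm, dtype=float))
    order = np.argsort(-mad, kind="stable")
    return [gene_ids[i] for i in order[:k]]


def center_rows(matrix: np.ndarray) -> np.ndarray:
    """Subtract each row's mean (gene-centering)."""
    m = np.asarray(matrix, dtype=float)
    return m - m.mean(axis=1, keepdims=True)


def normalize(cm: CountMatrix) -> NormalizationResult:
    """TMM factors plus CPM and log2CPM matrices in one call."""
    f = tmm_factors(cm)
    return NormalizationResult(
        tmm_factors=f,
        effective_lib_sizes=effective_library_sizes(cm, f),
        cpm=cpm(cm, f, log=False),
        log2cpm=cpm(cm, f, log=True),
    )
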