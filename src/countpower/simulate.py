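"""Negative-binomial count simulation with known truth.

The generator mirrors the assumptions of the closed-form power model:
counts are NB with ``Var = mu + phi * mu^2`` where ``sqrt(phi)`` is the
BCOV, gene means are library size times a relative abundance, and DE
genes carry a multiplicative fold change in the second group.  It serves
both as the fixture generator for tests and as the Monte-Carlo oracle for
power, type-I error, and dispersion recovery.

Defaults describe a typical bulk RNA-seq design: 10,000 genes, 4
replicates per group, ~30 million reads per library (the depth regime
where gene quantification saturates), BCOV 0.21 (a well-controlled cell
line experiment), 10% DE genes at two-fold change, split evenly between
up and down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountDataError, CountMatrix, SampleDesign, DEFAULT_SEED
from .power import _power_values

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_counts",
    "empirical_power",
    "predicted_power",
    "PowerEstimate",
    "make_use_case_fixture",
]


@dataclass
class SimulationConfig:
    n_genes: int = 10_000
    groups: tuple[str, str] = ("A", "B")
    n_per_group: int = 4
    lib_sizes: np.ndarray | None = None  # explicit per-sample depths
    mean_depth: float = 30e6
    depth_spread: float = 0.15  # lognormal CV of library sizes
    baseline_log_sd: float = 1.8  # spread of log relative abundances
    bcov: float | np.ndarray = 0.21
    de_fraction: float = 0.1
    fold_change: float = 2.0
    direction_balance: float = 0.5  # fraction of DE genes that go up
    de_coverage: float | None = None  # pin DE-gene coverage (see simulate_counts)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_per_group < 1:
            raise CountDataError("n_genes and n_per_group must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise CountDataError("de_fraction must lie in [0, 1]")
        if self.fold_change <= 0:
            raise CountDataError("fold_change must be positive")
        if not 0.0 <= self.direction_balance <= 1.0:
            raise CountDataError("direction_balance must lie in [0, 1]")
        if np.any(np.asarray(self.bcov, dtype=float) < 0):
            raise CountDataError("bcov must be non-negative")


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    design: SampleDesign
    truth: pd.DataFrame  # status {null, up, down}, true_log2_fc, true_dispersion
    config: SimulationConfig | None = None


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw with Var = mean + phi * mean^2 (phi=0 -> Poisson)."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=float)
    pois = phi <= 0
    if np.any(pois):
        out[pois] = rng.poisson(mean[pois])
    if np.any(~pois):
        shape = 1.0 / phi[~pois]
        lam = mean[~pois] * rng.gamma(shape, 1.0) / shape
        out[~pois] = rng.poisson(lam)
    return out


def simulate_counts(config: SimulationConfig) -> SimulatedDataset:
    """Draw a two-group NB dataset with known per-gene truth.

    Gene means are ``lib_size(s) * q_g * fc_g(s)`` with ``q_g`` log-normal
    relative abundances normalized to sum 1 and ``fc_g`` the planted fold
    change (applied in group B, up or down per ``direction_balance``; the
    up/down split is the deterministic rounded count).

    When ``de_coverage`` is set (calibration mode for validating the
    closed-form power model), per-gene baselines are fixed instead of
    drawn so that every DE gene's two group coverages have *harmonic mean*
    equal to ``de_coverage`` and null genes sit at ``de_coverage``
    exactly.  The harmonic mean is the coverage the power formula's
    counting-noise term ``2/mu`` refers to: ``1/mu_A + 1/mu_B = 2/mu``.
    If ``lib_sizes`` is not given it is then set to the implied column
    total so coverages are exact.
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    n = config.n_per_group
    a, b = config.groups

    phi = np.broadcast_to(np.asarray(config.bcov, dtype=float) ** 2, (G,)).copy()

    status = np.full(G, "null", dtype=object)
    n_de = int(round(config.de_fraction * G))
    de_idx = rng.choice(G, size=n_de, replace=False)
    n_up = int(round(config.direction_balance * n_de))
    status[de_idx[:n_up]] = "up"
    status[de_idx[n_up:]] = "down"
    fc = np.ones(G)
    fc[status == "up"] = config.fold_change
    fc[status == "down"] = 1.0 / config.fold_change
    status[fc == 1.0] = "null"  # a planted 1-fold "change" is no change

    if config.de_coverage is not None:
        t, d = config.de_coverage, config.fold_change
        baseline = np.full(G, t)
        baseline[status == "up"] = t * (1.0 + d) / (2.0 * d)
        baseline[status == "down"] = t * (1.0 + d) / 2.0
        implied_lib = baseline.sum()
        if config.lib_sizes is not None:
            lib = np.asarray(config.lib_sizes, dtype=float)
        else:
            lib = np.full(2 * n, implied_lib)
        q = baseline / implied_lib
    else:
        if config.lib_sizes is not None:
            lib = np.asarray(config.lib_sizes, dtype=float)
        else:
            lib = config.mean_depth * rng.lognormal(
                -0.5 * np.log1p(config.depth_spread ** 2),
                np.sqrt(np.log1p(config.depth_spread ** 2)),
                size=2 * n,
            )
        q = rng.lognormal(0.0, config.baseline_log_sd, size=G)
        q /= q.sum()
    if lib.size != 2 * n:
        raise CountDataError(f"lib_sizes must have {2 * n} entries")

    mean = np.empty((G, 2 * n))
    mean[:, :n] = q[:, None] * lib[None, :n]
    mean[:, n:] = (q * fc)[:, None] * lib[None, n:]
    counts = _nb_sample(rng, mean, phi[:, None])

    gene_ids = [f"gene{i:05d}" for i in range(G)]
    sample_ids = [f"{a}{i + 1}" for i in range(n)] + [f"{b}{i + 1}" for i in range(n)]
    group = {s: (a if i < n else b) for i, s in enumerate(sample_ids)}
    cm = CountMatrix(gene_ids, sample_ids, counts)
    sd = SampleDesign(sample_ids, group)
    truth = pd.DataFrame(
        {
            "status": status,
            "true_log2_fc": np.log2(fc),
            "true_dispersion": phi,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return SimulatedDataset(counts=cm, design=sd, truth=truth, config=config)


@dataclass
class PowerEstimate:
    power: float
    power_se: float
    type1: float
    type1_se: float
    n_de: int
    n_null: int


def empirical_power(
    config: SimulationConfig,
    test: str = "exact",
    alpha: float = 0.01,
    n_reps: int = 1,
    dispersion: str = "true",
) -> PowerEstimate:
    """Monte-Carlo rejection rates of the chosen test, stratified by truth.

    ``dispersion="true"`` plugs the generating dispersions into the test
    (isolating the test's behaviour from estimation error);
    ``"estimated"`` runs the qCML pipeline first.
    """
    from .de import exact_test, glm_ql_test
    from .dispersion import estimate_dispersion

    if not 0.0 < config.de_fraction < 1.0:
        raise CountDataError("empirical_power needs de_fraction in (0, 1)")
    rej_de = n_de = rej_null = n_null = 0
    for rep in range(n_reps):
        cfg = SimulationConfig(**{**config.__dict__, "seed": config.seed + rep})
        ds = simulate_counts(cfg)
        if dispersion == "true":
            disp = ds.truth["true_dispersion"].to_numpy()
        else:
            disp = estimate_dispersion(ds.counts, ds.design, cfg.groups)
        if test == "exact":
            res = exact_test(ds.counts, ds.design, cfg.groups, disp)
        elif test == "glm_ql":
            res = glm_ql_test(ds.counts, ds.design, cfg.groups, None, disp)
        else:
            raise CountDataError(f"unknown test {test!r}")
        is_de = (ds.truth["status"] != "null").to_numpy()
        rej = (res["p_value"] < alpha).to_numpy()
        rej_de += int(np.sum(rej & is_de))
        n_de += int(np.sum(is_de))
        rej_null += int(np.sum(rej & ~is_de))
        n_null += int(np.sum(~is_de))

    def rate_se(k: int, n: int) -> tuple[float, float]:
        if n == 0:
            return float("nan"), float("nan")
        p = k / n
        return p, float(np.sqrt(max(p * (1 - p), 1e-12) / n))

    power, power_se = rate_se(rej_de, n_de)
    type1, type1_se = rate_se(rej_null, n_null)
    return PowerEstimate(power, power_se, type1, type1_se, n_de, n_null)


def predicted_power(ds: SimulatedDataset, alpha: float) -> float:
    """Mean analytic power over the truly-DE genes of a simulated dataset.

    The formula's coverage parameter is the log-scale average depth of a
    gene across the two groups, i.e. the geometric mean of its group mean
    counts; sigma is the generating BCOV.
    """
    cfg = ds.config
    if cfg is None:
        raise CountDataError("dataset carries no simulation config")
    n = cfg.n_per_group
    is_de = (ds.truth["status"] != "null").to_numpy()
    if not np.any(is_de):
        raise CountDataError("no DE genes in the dataset")
    counts = ds.counts.counts
    mean_a = counts[:, :n].mean(axis=1)
    mean_b = counts[:, n:].mean(axis=1)
    mu_g = np.sqrt(np.maximum(mean_a, 1e-12) * np.maximum(mean_b, 1e-12))
    sigma = np.sqrt(ds.truth["true_dispersion"].to_numpy())
    pw = _power_values(n, cfg.fold_change, alpha, mu_g[is_de], sigma[is_de])
    return float(np.mean(pw))


# ---------------------------------------------------------------------------
# crossed-factor fixture
# ---------------------------------------------------------------------------

def make_use_case_fixture(
    seed: int = DEFAULT_SEED, n_genes: int = 4000, mean_depth: float = 2e6
) -> SimulatedDataset:
    """A 32-sample dataset with four crossed two-level factors.

    Emulates a two-cell-line hypoxia/mTOR-inhibitor design sequenced for
    total and polysome-bound mRNA, two replicates per combination.  The
    planted effect hierarchy is cell line >> mRNA fraction > oxygen >
    treatment, plus a small replicate batch shift, so exploratory analyses
    separate cell lines first.  ``truth`` records the oxygen (hypoxia)
    effect, the factor a DE comparison would target.
    """
    rng = np.random.default_rng(seed)
    G = n_genes
    q = rng.lognormal(0.0, 1.8, size=G)
    q /= q.sum()
    phi = (0.21 * rng.lognormal(0.0, 0.25, size=G)) ** 2

    def planted(frac: float, log2_sd: float) -> np.ndarray:
        eff = np.zeros(G)
        idx = rng.choice(G, size=int(frac * G), replace=False)
        eff[idx] = rng.normal(0.0, log2_sd, size=idx.size)
        return eff

    eff = {
        "cell_line": planted(0.30, 2.0),
        "fraction": planted(0.15, 1.2),
        "oxygen": planted(0.10, 1.0),
        "treatment": planted(0.08, 0.8),
    }
    batch = rng.normal(0.0, 0.05, size=G)  # mild replicate shift on all genes

    cells = ("MCF10A", "MDA231")
    oxygens = ("normoxia", "hypoxia")
    treatments = ("untreated", "PP242")
    fractions = ("total", "polysome")

    sample_ids: list[str] = []
    group: dict[str, str] = {}
    cov: dict[str, dict[str, str]] = {
        k: {} for k in ("cell_line", "oxygen", "treatment", "fraction", "replicate")
    }
    cols = []
    for cell in cells:
        for oxy in oxygens:
            for trt in treatments:
                for frac in fractions:
                    for rep in ("r1", "r2"):
                        sid = f"{cell}_{oxy}_{trt}_{frac}_{rep}"
                        sample_ids.append(sid)
                        cond = oxy if trt == "untreated" else f"{oxy}_PP242"
                        group[sid] = f"{cell}_{cond}_{frac}"
                        cov["cell_line"][sid] = cell
                        cov["oxygen"][sid] = oxy
                        cov["treatment"][sid] = trt
                        cov["fraction"][sid] = frac
                        cov["replicate"][sid] = rep
                        log2_mult = (
                            (cell == cells[1]) * eff["cell_line"]
                            + (frac == fractions[1]) * eff["fraction"]
                            + (oxy == oxygens[1]) * eff["oxygen"]
                            + (trt == treatments[1]) * eff["treatment"]
                            + (rep == "r2") * batch
                        )
                        cols.append(log2_mult)
    lib = mean_depth * rng.lognormal(-0.005, 0.1, size=len(sample_ids))
    mean = q[:, None] * (2.0 ** np.stack(cols, axis=1)) * lib[None, :]
    counts = _nb_sample(rng, mean, phi[:, None])

    gene_ids = [f"gene{i:05d}" for i in range(G)]
    cm = CountMatrix(gene_ids, sample_ids, counts)
    sd = SampleDesign(sample_ids, group, cov)
    status = np.where(
        eff["oxygen"] > 0, "up", np.where(eff["oxygen"] < 0, "down", "null")
    )
    truth = pd.DataFrame(
        {
            "status": status,
            "true_log2_fc": eff["oxygen"],
            "true_dispersion": phi,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return SimulatedDataset(counts=cm, design=sd, truth=truth, config=None)
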