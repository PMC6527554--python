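import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import nbinom, spearmanr

from countpower import (
    AnalysisConfig,
    CountDataError,
    CountMatrix,
    SampleDesign,
    SimulationConfig,
    bh_adjust,
    build_signature,
    exact_test,
    glm_ql_test,
    ma_data,
    simulate_counts,
    triage,
)
from countpower.de import _exact_pvalue, build_design_matrix


def _two_group(counts, n=None):
    counts = np.asarray(counts, dtype=float)
    n = n or counts.shape[1] // 2
    samples = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(counts.shape[1] - n)]
    sd = SampleDesign(samples, {s: ("A" if i < n else "B") for i, s in enumerate(samples)})
    cm = CountMatrix([f"g{i}" for i in range(counts.shape[0])], samples, counts)
    return cm, sd


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

def enumerate_exact_pvalue(s_a, s_b, n_a, n_b, phi):
    """Exhaustive oracle: the split of the total between two NB group sums,
    conditional on the total; two-sided by the minimum-likelihood rule."""
    t = s_a + s_b
    lam = t / (n_a + n_b)

    def pmf(k, n_samp):
        mean = n_samp * lam
        r = n_samp / phi
        return nbinom.pmf(k, r, r / (r + mean))

    probs = np.array([pmf(a, n_a) * pmf(t - a, n_b) for a in range(t + 1)])
    probs /= probs.sum()
    p_obs = probs[s_a]
    return float(probs[probs <= p_obs * (1 + 1e-10)].sum())


@pytest.mark.parametrize(
    "s_a,s_b,phi",
    [(3, 15, 0.1), (10, 10, 0.1), (0, 20, 0.1), (7, 2, 0.3), (25, 11, 0.05)],
)
def test_exact_pvalue_equals_enumeration(s_a, s_b, phi):
    """Conditional p-value equals brute-force enumeration over all splits
    of the total (2 vs 2 samples, small integer counts)."""
    got = _exact_pvalue(float(s_a), float(s_b), 2, 2, phi)
    want = enumerate_exact_pvalue(s_a, s_b, 2, 2, phi)
    assert got == pytest.approx(want, rel=1e-9, abs=1e-12)


def test_exact_pvalue_unbalanced_groups_enumeration():
    got = _exact_pvalue(9.0, 30.0, 2, 3, 0.2)
    want = enumerate_exact_pvalue(9, 30, 2, 3, 0.2)
    assert got == pytest.approx(want, rel=1e-9)


def test_exact_test_identical_group_totals_gives_p_one():
    """Perfectly null gene: equal pseudo-count totals in equal-sized
    groups sit at the mode of the conditional distribution."""
    assert _exact_pvalue(20.0, 20.0, 2, 2, 0.1) == 1.0
    counts = np.array([[10.0, 10.0, 10.0, 10.0], [8.0, 8.0, 8.0, 8.0]])
    cm, sd = _two_group(counts)
    res = exact_test(cm, sd, ("A", "B"), 0.1)
    assert res["p_value"].iloc[0] == pytest.approx(1.0)


def test_exact_test_pipeline_matches_oracle_on_balanced_fixture():
    """With constant filler genes the TMM factors are 1 and pseudo-counts
    equal raw counts, so the pipeline p-value is the enumeration value."""
    fillers = np.tile(np.array([40.0, 60.0, 35.0, 90.0, 120.0])[:, None], (1, 4))
    target = np.array([[2.0, 1.0, 8.0, 7.0]])
    cm, sd = _two_group(np.vstack([fillers, target]))
    res = exact_test(cm, sd, ("A", "B"), 0.1)
    want = enumerate_exact_pvalue(3, 15, 2, 2, 0.1)
    assert res["p_value"].iloc[-1] == pytest.approx(want, rel=1e-6)


def test_exact_test_group_swap_negates_logfc():
    rng = np.random.default_rng(2)
    counts = rng.poisson(60, size=(40, 6)).astype(float)
    cm, sd = _two_group(counts)
    ab = exact_test(cm, sd, ("A", "B"), 0.1)
    ba = exact_test(cm, sd, ("B", "A"), 0.1)
    np.testing.assert_allclose(ab["log2_fc"], -ba["log2_fc"], atol=1e-9)
    np.testing.assert_allclose(ab["p_value"], ba["p_value"], atol=1e-9)


def test_exact_test_rejects_more_than_two_groups():
    counts = np.ones((3, 6))
    samples = [f"s{i}" for i in range(6)]
    sd = SampleDesign(samples, dict(zip(samples, ["A", "A", "B", "B", "C", "C"])))
    cm = CountMatrix(["g0", "g1", "g2"], samples, counts)
    with pytest.raises(CountDataError):
        exact_test(cm, sd, ("A", "C", "B"), 0.1)  # malformed comparison


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def test_bh_hand_computed_step_up():
    got = bh_adjust([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(got, [0.04, 0.04, 0.04, 0.04])


def test_bh_trivial_cases():
    assert bh_adjust([0.37])[0] == pytest.approx(0.37)
    np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)


def test_bh_out_of_range_error():
    with pytest.raises(CountDataError):
        bh_adjust([0.5, 1.5])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
def test_bh_dominates_p_and_preserves_ranking(pvals):
    p = np.array(pvals)
    fdr = bh_adjust(p)
    assert np.all(fdr >= p - 1e-12)
    assert np.all(fdr <= 1.0 + 1e-12)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(fdr[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# GLM quasi-likelihood test
# ---------------------------------------------------------------------------

def test_glm_concordant_with_exact_test_without_covariates():
    cfg = SimulationConfig(
        n_genes=400, n_per_group=4, mean_depth=400 * 50.0, baseline_log_sd=0.8,
        bcov=0.2, de_fraction=0.2, seed=9,
    )
    ds = simulate_counts(cfg)
    disp = ds.truth["true_dispersion"].to_numpy()
    r_exact = exact_test(ds.counts, ds.design, ("A", "B"), disp)
    r_glm = glm_ql_test(ds.counts, ds.design, ("A", "B"), None, disp)
    rho = spearmanr(r_exact["p_value"], r_glm["p_value"]).statistic
    assert rho >= 0.95


def test_glm_flat_gene_gives_null_result():
    """Equal counts in every sample (equal library sizes): zero group
    coefficient and p ~ 1."""
    rng = np.random.default_rng(0)
    # noisy fillers with the same per-sample pattern in both groups, so
    # normalization is exactly symmetric between A and B
    pattern = rng.poisson(100, size=(30, 4)).astype(float)
    fillers = np.hstack([pattern, pattern])
    counts = np.vstack([np.full(8, 30.0), fillers])
    cm, sd = _two_group(counts)
    res = glm_ql_test(cm, sd, ("A", "B"), None, 0.05)
    assert abs(res["log2_fc"].iloc[0]) < 1e-6
    assert res["p_value"].iloc[0] > 0.99


def test_glm_rank_deficient_design_names_aliased_column():
    samples = ["a1", "a2", "b1", "b2"]
    sd = SampleDesign(
        samples,
        {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        {"batch": {"a1": "x", "a2": "x", "b1": "y", "b2": "y"}},  # aliased with group
    )
    with pytest.raises(CountDataError, match="batch"):
        build_design_matrix(sd, ("A", "B"), ["batch"])


def test_glm_adjusts_for_planted_batch_effect():
    """A replicate batch shifting both groups equally: the
    covariate-adjusted QL test keeps type-I error within the binomial
    band at the 0.05 level."""
    rng = np.random.default_rng(21)
    G, b, phi = 1500, 200.0, 0.04
    batch = np.zeros(G)
    idx = rng.choice(G, G // 3, replace=False)
    batch[idx] = rng.normal(0, 0.7, idx.size)
    samples = [f"{g}_{r}{i}" for g in "AB" for r in ("r1", "r2") for i in (1, 2)]
    group = {s: s[0] for s in samples}
    rep = {s: s.split("_")[1][:2] for s in samples}
    mean = np.stack(
        [b * (2.0 ** batch if rep[s] == "r2" else np.ones(G)) for s in samples], axis=1
    )
    counts = rng.poisson(mean * rng.gamma(1 / phi, phi, (G, 8)))
    cm = CountMatrix([f"g{i}" for i in range(G)], samples, counts)
    sd = SampleDesign(samples, group, {"replicate": rep})
    res = glm_ql_test(cm, sd, ("A", "B"), ["replicate"], phi * np.ones(G))
    rate = float((res["p_value"] < 0.05).mean())
    band = 1.96 * np.sqrt(0.05 * 0.95 / G)
    assert abs(rate - 0.05) < band + 1e-12


# ---------------------------------------------------------------------------
# triage / signature / MA
# ---------------------------------------------------------------------------

def _tables(fdr, power):
    idx = pd.Index([f"g{i}" for i in range(len(fdr))], name="gene_id")
    de = pd.DataFrame(
        {"log2_fc": 1.0, "mean_log2cpm": 5.0, "p_value": fdr, "fdr": fdr}, index=idx
    )
    det = pd.DataFrame({"power": power}, index=idx)
    return de, det


@pytest.mark.parametrize(
    "fdr,power,label",
    [(0.01, 0.5, "DE"), (0.2, 0.9, "NDE_DT"), (0.2, 0.3, "NDE_NDT")],
)
def test_triage_label_definitions(fdr, power, label):
    de, det = _tables([fdr], [power])
    labels, counts = triage(de, det, AnalysisConfig())
    assert labels.iloc[0] == label
    assert counts[label] == 1


def test_triage_partitions_all_genes():
    rng = np.random.default_rng(0)
    de, det = _tables(rng.uniform(0, 1, 200), rng.uniform(0, 1, 200))
    labels, counts = triage(de, det, AnalysisConfig())
    assert sum(counts.values()) == 200
    assert set(labels.unique()) <= {"DE", "NDE_DT", "NDE_NDT"}


def test_triage_gene_mismatch_error():
    de, det = _tables([0.1], [0.5])
    det2 = det.rename(index={"g0": "other"})
    with pytest.raises(CountDataError):
        triage(de, det2, AnalysisConfig())


def test_signature_membership_matches_rule_enumeration():
    """6-gene toy spanning all cutoff combinations (FDR 0.01, power 0.7)."""
    fdr = [0.005, 0.005, 0.5, 0.5, 0.02, 0.9]
    power = [0.2, 0.9, 0.75, 0.3, 0.71, 0.69]
    de, det = _tables(fdr, power)
    cfg = AnalysisConfig()
    sig = build_signature(de, det, cfg)
    expect = {
        f"g{i}"
        for i in range(6)
        if fdr[i] < 0.01 or (fdr[i] >= 0.01 and power[i] >= 0.7)
    }
    assert set(sig.table.index) == expect
    assert {"log2_fc", "p_value", "fdr", "power", "triage"} <= set(sig.table.columns)


def test_signature_rule_examples():
    de, det = _tables([0.005, 0.5], [0.2, 0.75])
    sig = build_signature(de, det, AnalysisConfig())
    assert "g0" in sig.table.index  # DE side despite low power
    assert "g1" in sig.table.index  # confident negative


def test_empty_signature_warns():
    de, det = _tables([0.5], [0.1])
    with pytest.warns(UserWarning, match="empty"):
        sig = build_signature(de, det, AnalysisConfig())
    assert len(sig) == 0


def test_ma_data_consistency():
    rng = np.random.default_rng(1)
    fdr = rng.uniform(0, 1, 50)
    de, det = _tables(fdr, rng.uniform(0, 1, 50))
    ma = ma_data(de, 0.05)
    assert len(ma) == 50
    labels, _ = triage(de, det, AnalysisConfig())
    np.testing.assert_array_equal(ma["significant"].to_numpy(), labels == "DE")


def test_ma_arithmetic_on_toy():
    """A = mean log2 CPM, M = log2 fold change, straight from the DE table.

    Column sums are balanced so pseudo-counts equal the raw counts and
    the hand arithmetic is exact.
    """
    rng = np.random.default_rng(0)
    fillers = np.tile(rng.integers(20, 200, size=20).astype(float)[:, None], (1, 4))
    target = np.array([[10.0, 10.0, 40.0, 40.0]])
    balancer = np.array([[130.0, 130.0, 100.0, 100.0]])
    counts = np.vstack([fillers, target, balancer])
    cm, sd = _two_group(counts)
    res = exact_test(cm, sd, ("A", "B"), 0.05)
    ma = ma_data(res)
    assert len(ma) == 22
    # target gene: pseudocount-stabilized group-mean ratio
    assert ma["log2_fc"].iloc[20] == pytest.approx(np.log2(40.5 / 10.5), abs=1e-6)
    # a flat filler gene has zero fold change
    assert ma["log2_fc"].iloc[0] == pytest.approx(0.0, abs=1e-9)
    # A values are mean log2 CPM across the comparison's samples
    lib = counts.sum(axis=0)
    log2cpm = np.log2((counts + 0.5) / (lib + 1.0) * 1e6)
    assert ma["mean_log2cpm"].iloc[20] == pytest.approx(log2cpm[20].mean(), abs=1e-6)
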