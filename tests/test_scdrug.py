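"""Monotone factorial model: normalisation, constrained fit, phase inference,
explanatory power and drug-gene ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.isotonic import IsotonicRegression

import masterreg as mr
from masterreg import scdrug, synth
from masterreg.scdrug import MonotoneFactorialModel


def make_meta(n, status="sensitive", conc=None, time=None, pair="p1"):
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "pair_id": pair,
            "status": status,
            "conc_level": conc if conc is not None else np.zeros(n, dtype=int),
            "time_level": time if time is not None else np.zeros(n, dtype=int),
        }
    )


# ----------------------------------------------------------- rank_normalize

def test_rank_normalize_examples():
    counts = pd.DataFrame(
        [[2.0, 4.0, 6.0], [4.0, 4.0, 4.0], [6.0, 4.0, 2.0]],
        index=["g1", "g2", "g3"], columns=["a", "b", "c"],
    )
    # equal per-cell sums, so sum-normalisation preserves per-gene order
    X = scdrug.rank_normalize(counts)
    np.testing.assert_allclose(X.loc["g1"], [0.0, 0.5, 1.0])
    np.testing.assert_allclose(X.loc["g2"], [0.5, 0.5, 0.5])  # average-rank ties
    np.testing.assert_allclose(X.loc["g3"], [1.0, 0.5, 0.0])


def test_rank_normalize_matches_sort_oracle_and_scale_invariance():
    rng = np.random.default_rng(1)
    counts = pd.DataFrame(
        rng.poisson(20, size=(5, 20)).astype(float) + 1,
        index=[f"g{i}" for i in range(5)],
        columns=[f"c{i}" for i in range(20)],
    )
    X = scdrug.rank_normalize(counts)
    sums = counts.sum(axis=0)
    for g in counts.index:
        v = (counts.loc[g] / sums).to_numpy()
        ref = (pd.Series(v).rank(method="average") - 1) / (len(v) - 1)
        np.testing.assert_allclose(X.loc[g], ref)
    # per-cell positive rescaling changes nothing (ranks of sum-normalised data)
    scaled = counts * rng.uniform(0.5, 2.0, size=20)
    pd.testing.assert_frame_equal(X, scdrug.rank_normalize(scaled))


def test_rank_normalize_rejects_zero_cell():
    counts = pd.DataFrame([[1.0, 0.0], [2.0, 0.0]])
    with pytest.raises(ValueError):
        scdrug.rank_normalize(counts)


# ------------------------------------------------------------ monotone fit

def pava_best_direction(values, weights):
    """Oracle: isotonic fit in both directions, keep smaller SSE."""
    xs = np.arange(len(values))
    best = None
    for sign in (1, -1):
        ir = IsotonicRegression(increasing=sign > 0)
        fit = ir.fit(xs, values, sample_weight=weights).predict(xs)
        sse = np.sum(weights * (values - fit) ** 2)
        if best is None or sse < best[1] - 1e-12:
            best = (fit, sse, sign)
    return best


def test_single_factor_fit_examples():
    # already monotone group means -> beta = group means
    X = pd.DataFrame([[0.1, 0.1, 0.4, 0.4, 0.9, 0.9]], index=["g"],
                     columns=[f"c{i}" for i in range(6)])
    meta = make_meta(6, conc=[0, 0, 1, 1, 2, 2])
    res = MonotoneFactorialModel(X, meta).fit()
    np.testing.assert_allclose(res.beta[0, 0, :, 0, 0], [0.1, 0.4, 0.9], atol=1e-8)
    assert res.rss[0] == pytest.approx(0.0, abs=1e-12)

    # means {1.0, 0.2, 0.6} equal sizes -> nonincreasing, pooled {1.0, 0.4, 0.4}
    meta2 = make_meta(3, conc=[0, 1, 2])
    X2 = pd.DataFrame([[1.0, 0.2, 0.6]], index=["g"], columns=meta2["cell_id"])
    res2 = MonotoneFactorialModel(X2, meta2).fit()
    np.testing.assert_allclose(res2.beta[0, 0, :, 0, 0], [1.0, 0.4, 0.4], atol=1e-8)
    assert res2.directions[0, 0] == -1


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(2, 6), st.integers(0, 10_000))
def test_single_factor_fit_matches_pava_oracle(levels, seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(levels, 21))
    conc = np.sort(rng.integers(0, levels, size=n))
    conc[: levels] = np.arange(levels)  # every level observed
    x = rng.uniform(0, 1, size=n)
    X = pd.DataFrame([x], index=["g"], columns=[f"c{i}" for i in range(n)])
    res = MonotoneFactorialModel(X, make_meta(n, conc=conc)).fit()
    # oracle on the weighted group means
    means = pd.Series(x).groupby(conc).mean().to_numpy()
    weights = pd.Series(x).groupby(conc).size().to_numpy().astype(float)
    fit, sse_between, _ = pava_best_direction(means, weights)
    within = np.sum((x - means[conc]) ** 2) - 0  # recomputed below precisely
    within = sum((x[conc == l] - x[conc == l].mean()).sum() * 0 +
                 np.sum((x[conc == l] - x[conc == l].mean()) ** 2)
                 for l in range(levels))
    np.testing.assert_allclose(
        res.beta[0, 0, :, 0, 0], fit, atol=1e-6
    )
    assert res.rss[0] == pytest.approx(within + sse_between, abs=1e-6)


def test_zero_noise_factorial_recovers_planted_directions():
    """Noise-free data monotone in dose and time is fitted exactly."""
    rows = []
    meta_rows = []
    k = 0
    for d in range(3):
        for t in range(3):
            for _ in range(2):
                rows.append(0.1 + 0.3 * d / 2 + 0.5 * t / 2)
                meta_rows.append((f"c{k}", "p1", "sensitive", d, t))
                k += 1
    meta = pd.DataFrame(
        meta_rows, columns=["cell_id", "pair_id", "status", "conc_level", "time_level"]
    )
    X = pd.DataFrame([rows], index=["g"], columns=meta["cell_id"])
    res = MonotoneFactorialModel(X, meta).fit()
    assert res.rss[0] == pytest.approx(0.0, abs=1e-10)
    assert tuple(res.directions[0]) == (1, 1)
    grid = res.beta[0, 0, :, :, 0]
    np.testing.assert_allclose(
        grid, 0.1 + 0.3 * np.arange(3)[:, None] / 2 + 0.5 * np.arange(3)[None, :] / 2,
        atol=1e-8,
    )


def test_rss_nesting_across_dropped_variables():
    """The full model never fits worse than any variable-collapsed model."""
    rng = np.random.default_rng(8)
    n = 120
    meta = make_meta(
        n,
        status=rng.choice(["sensitive", "resistant"], n),
        conc=rng.integers(0, 3, n),
        time=rng.integers(0, 3, n),
    )
    X = pd.DataFrame(
        rng.uniform(0, 1, size=(4, n)), index=list("abcd"), columns=meta["cell_id"]
    )
    full = MonotoneFactorialModel(X, meta).fit()
    for v in ("drug", "time", "cellline"):
        reduced = full.model.drop_variable(v).fit()
        assert np.all(full.rss <= reduced.rss + 1e-8)
        ep = full.explanatory_power(v)
        assert np.all(ep.to_numpy() >= 0)


def test_explanatory_power_extremes():
    n = 60
    conc = np.array([0, 0, 1, 1, 2, 2] * 10)
    meta = make_meta(n, conc=conc)
    determined = conc / 2.0  # exactly the drug level, no noise
    balanced = np.tile([0.2, 0.8], n // 2)  # identical distribution per level
    X = pd.DataFrame(
        [determined, balanced], index=["det", "ind"], columns=meta["cell_id"]
    )
    res = MonotoneFactorialModel(X, meta).fit()
    ep = res.explanatory_power("drug")
    assert ep["det"] == pytest.approx(1.0, abs=1e-8)
    assert ep["ind"] == pytest.approx(0.0, abs=1e-8)


def test_constant_gene_flagged_nan_ep():
    n = 20
    meta = make_meta(n, conc=np.arange(n) % 2)
    X = pd.DataFrame([[0.5] * n], index=["flat"], columns=meta["cell_id"])
    res = MonotoneFactorialModel(X, meta).fit()
    assert np.isnan(res.explanatory_power("drug")["flat"])


# ----------------------------------------------------------- phase inference

def one_hot_phase_data(n_per_phase=30, seed=0):
    phases = ["G1", "S", "G2M"]
    markers = {ph: [f"m_{ph}"] for ph in phases}
    rng = np.random.default_rng(seed)
    rows, true = [], []
    for ph in phases:
        for _ in range(n_per_phase):
            rows.append([1.0 if p == ph else 0.0 for p in phases])
            true.append(ph)
    order = rng.permutation(len(rows))
    X = pd.DataFrame(
        np.array(rows)[order].T,
        index=[f"m_{p}" for p in phases],
        columns=[f"c{i}" for i in range(len(rows))],
    )
    meta = make_meta(len(rows))
    return X, meta, markers, np.array(true)[order]


def test_phase_inference_separable_markers(phase_match):
    X, meta, markers, true = one_hot_phase_data()
    res = scdrug.infer_phases(X, meta, markers, iters=50, restarts=3, seed=1)
    assert phase_match(true, res.phases.to_numpy()) == 1.0
    # objective is non-increasing within every restart
    assert all(
        b <= a + 1e-9 for a, b in zip(res.objective_trace, res.objective_trace[1:])
    )


def test_phase_inference_deterministic_under_seed():
    X, meta, markers, _ = one_hot_phase_data(seed=3)
    r1 = scdrug.infer_phases(X, meta, markers, iters=20, restarts=1, seed=7)
    r2 = scdrug.infer_phases(X, meta, markers, iters=20, restarts=1, seed=7)
    pd.testing.assert_series_equal(r1.phases, r2.phases)
    assert r1.objective == r2.objective


def test_phase_inference_requires_two_disjoint_phases():
    X, meta, markers, _ = one_hot_phase_data()
    with pytest.raises(ValueError):
        scdrug.infer_phases(X, meta, {"G1": ["m_G1"]})
    overlapping = {"G1": ["m_G1"], "S": ["m_G1"]}
    with pytest.raises(ValueError):
        scdrug.infer_phases(X, meta, overlapping)


def test_phase_recovery_on_generated_counts(phase_match):
    """Cells simulated with four-fold marker elevation recover their planted
    phases (label permutation allowed)."""
    gene_ids = [f"G{i:05d}" for i in range(60)]
    markers = {
        ph: [gene_ids[3 * k + j] for j in range(3)]
        for k, ph in enumerate(synth.DEFAULT_PHASES)
    }
    truth = mr.GroundTruth()
    counts, meta = synth.gen_sc_counts(
        40, 60, markers, truth, pairs=("pairA",), n_conc=2, n_time=2, seed=5
    )
    X = scdrug.rank_normalize(counts)
    res = scdrug.infer_phases(X, meta, markers, iters=50, restarts=3, seed=6)
    agree = phase_match(meta["true_phase"].to_numpy(), res.phases.to_numpy())
    assert agree >= 0.9


# ------------------------------------------------------------ gene ranking

def test_rank_drug_genes_orders_by_sensitive_minus_resistant():
    ep_s = pd.Series({"a": 0.5, "b": 0.1, "c": 0.3})
    ep_r = pd.Series({"a": 0.1, "b": 0.1, "d": 0.2})
    ranked = scdrug.rank_drug_genes(ep_s, ep_r)
    # c and d are absent from one side each and drop out
    assert list(ranked["gene_id"]) == ["a", "b"]
    assert ranked.loc[0, "score"] == pytest.approx(0.4)
    assert ranked.loc[1, "score"] == pytest.approx(0.0)
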