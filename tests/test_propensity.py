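"""Expression metrics, transition matrices and permutation statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from exprevo import propensity as pr
from exprevo.propensity import (StatsConfig, TransitionMatrix,
                                brunner_munzel, build_shift_records,
                                omega_analysis, permutation_enrichment,
                                polarity, polarity_value, shift_rates, tau,
                                tec, transition_matrix, robustness_subsets)
from exprevo.synth import ORGANS

vec6 = st.lists(st.floats(0.0, 1e6, allow_nan=False), min_size=6, max_size=6)


# ---------------------------------------------------------------------------
# tau and TEC
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("x,expected", [
    ((5, 5, 5, 5, 5, 5), 0.0),
    ((8, 0, 0, 0, 0, 0), 1.0),
    ((4, 2, 0, 0, 0, 0), 0.9),
])
def test_tau_reference_values(x, expected):
    assert tau(x) == pytest.approx(expected)


def test_tau_rejects_degenerate_input():
    with pytest.raises(ValueError):
        tau([0, 0, 0, 0, 0, 0])
    with pytest.raises(ValueError):
        tau([-1, 1, 1, 1, 1, 1])


@settings(max_examples=200, deadline=None, derandomize=True)
@given(vec6)
def test_tau_bounds_and_scale_invariance(x):
    if max(x) <= 0:
        return
    t = tau(x)
    assert 0.0 <= t <= 1.0
    assert tau([3.7 * v for v in x]) == pytest.approx(t, abs=1e-9)


@pytest.mark.parametrize("a,b,expected", [
    ((1, 0, 0, 0, 0, 0), (0, 1, 0, 0, 0, 0), 1.0),
    ((2, 3, 1, 0, 0, 0), (2, 3, 1, 0, 0, 0), 0.0),
    ((.5, .5, 0, 0, 0, 0), (.5, 0, .5, 0, 0, 0), 0.5),
])
def test_tec_reference_values(a, b, expected):
    assert tec(a, b) == pytest.approx(expected)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(vec6, vec6)
def test_tec_bounds_and_symmetry(a, b):
    if sum(a) <= 0 or sum(b) <= 0:
        return
    v = tec(a, b)
    assert 0.0 <= v <= 1.0 + 1e-12
    assert tec(b, a) == pytest.approx(v, abs=1e-12)


def test_tec_rejects_zero_sum():
    with pytest.raises(ValueError):
        tec([0] * 6, [1] * 6)


# ---------------------------------------------------------------------------
# shift records
# ---------------------------------------------------------------------------

def _toy_family(delta_organ="testis", magnitude=6.0):
    """One family whose single shift drives brain -> `delta_organ`."""
    from exprevo import parse_newick
    from exprevo.oushifts import OrganOUParams, RegimeModel
    tree = parse_newick("((a:50,b:50)n1:50,c:100)n0;")
    tree.set_ages_from_lengths()
    theta0 = np.array([5.0, 1, 1, 1, 1, 1])     # PEO brain
    delta = np.zeros(6)
    delta[list(ORGANS).index(delta_organ)] = magnitude
    optima = {"n0": theta0, "n1": theta0 + delta, "c": theta0,
              "a": theta0 + delta, "b": theta0 + delta}
    params = {o: OrganOUParams(0.05, 0.3, float(theta0[i]))
              for i, o in enumerate(ORGANS)}
    model = RegimeModel(shift_branches=["n1"], organ_params=params,
                        deltas=pd.DataFrame([delta], index=["n1"],
                                            columns=list(ORGANS)),
                        optima=optima, loglik=0.0, aicc=0.0, n_params=24,
                        n_tips=3)
    return {"model": model, "tree": tree,
            "categories": {"n1": "D", "c": "S", "a": "D", "b": "D"}}


def test_shift_record_captures_planted_peo_switch():
    fam = _toy_family()
    omegas = pd.DataFrame({"omega": {("f1", "n1"): 0.4, ("f1", "c"): 0.1}})
    omegas.index = pd.MultiIndex.from_tuples(omegas.index)
    rec = build_shift_records({"f1": fam}, omegas)
    assert len(rec) == 1
    row = rec.iloc[0]
    assert row["peo_anc"] == "brain" and row["peo_der"] == "testis"
    assert row["peo_switch"]
    assert row["category"] == "D"
    assert row["omega_shift"] == 0.4 and row["omega_sister"] == 0.1
    assert 0 <= row["tec"] <= 1


def test_proportional_shift_is_flagged_non_switching():
    fam = _toy_family()
    # overwrite: derived optimum = ancestral + 1 in log2 space everywhere
    theta0 = fam["model"].optima["n0"]
    fam["model"].optima["n1"] = theta0 + 1.0
    fam["model"].optima["a"] = theta0 + 1.0
    fam["model"].optima["b"] = theta0 + 1.0
    rec = build_shift_records({"f1": fam})
    assert len(rec) == 1
    assert not rec.iloc[0]["peo_switch"]


def test_root_branch_shift_skipped_and_counted():
    fam = _toy_family()
    fam["shifts"] = ["n0", "n1"]
    rec = build_shift_records({"f1": fam})
    assert len(rec) == 1
    assert rec.attrs["skipped_root"] == 1


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------

def test_shift_rates_arithmetic():
    rec = pd.DataFrame({"category": ["S"] * 10,
                        "peo_switch": [True] * 10})
    census = pd.DataFrame({"category": ["S"] * 100,
                           "duration": [10.0] * 100})
    out = shift_rates(rec, census)
    assert out.loc["S", "frequency"] == pytest.approx(0.1)
    assert out.loc["S", "rate_per_my"] == pytest.approx(0.01)


def test_shift_rates_zero_shift_category():
    rec = pd.DataFrame({"category": ["S"], "peo_switch": [True]})
    census = pd.DataFrame({"category": ["S", "D"], "duration": [10.0, 5.0]})
    out = shift_rates(rec, census)
    assert out.loc["D", "frequency"] == 0 and out.loc["D", "rate_per_my"] == 0


def test_shift_rate_chi2_null_pvalues_are_uniform():
    """Equal per-branch shift probability across categories: the chi2
    p-value is U(0,1) over simulations."""
    rng = np.random.default_rng(0)
    pvals = []
    for _ in range(200):
        census = pd.DataFrame({
            "category": ["S"] * 300 + ["D"] * 150 + ["R"] * 60,
            "duration": 10.0})
        hits = rng.random(len(census)) < 0.15
        rec = pd.DataFrame({"category": census.loc[hits, "category"],
                            "peo_switch": True})
        out = shift_rates(rec, census)
        pvals.append(out.attrs["chi2_p"])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# Brunner-Munzel
# ---------------------------------------------------------------------------

def _bm_rank_oracle(x, y):
    """Direct implementation of the rank formulas."""
    n1, n2 = len(x), len(y)
    allv = np.concatenate([x, y])
    R = stats.rankdata(allv)
    r1, r2 = R[:n1], R[n1:]
    ri1, ri2 = stats.rankdata(x), stats.rankdata(y)
    s1 = np.sum((r1 - ri1 - r1.mean() + (n1 + 1) / 2) ** 2) / (n1 - 1)
    s2 = np.sum((r2 - ri2 - r2.mean() + (n2 + 1) / 2) ** 2) / (n2 - 1)
    return n1 * n2 * (r2.mean() - r1.mean()) / \
        ((n1 + n2) * np.sqrt(n1 * s1 + n2 * s2))


def test_brunner_munzel_matches_rank_formula_oracle():
    rng = np.random.default_rng(4)
    for _ in range(5):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.3, 2, 10)
        got = brunner_munzel(x, y)
        assert got["statistic"] == pytest.approx(_bm_rank_oracle(x, y),
                                                 abs=1e-10)


def test_brunner_munzel_relative_effect_extremes():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 50)
    res = brunner_munzel(x, x + 100.0)
    assert res["relative_effect"] == pytest.approx(1.0)
    assert res["p"] < 1e-3
    same = brunner_munzel(x, x.copy())
    assert same["relative_effect"] == pytest.approx(0.5)


def test_brunner_munzel_small_sample_permutation_fallback():
    res = brunner_munzel([1.0, 2, 3], [4.0, 5, 6], min_n=10, seed=0)
    assert res["fallback"] and 0 < res["p"] <= 1


def test_stationary_variance_compare_gamma_layout():
    from exprevo.oushifts import OrganOUParams, RegimeModel
    models = []
    for g_rep, g_oth in ((10.0, 1.0), (12.0, 1.5), (9.0, 1.2),
                         (11.0, 0.9), (10.5, 1.1), (9.5, 0.8),
                         (10.2, 1.3), (11.5, 1.0), (9.8, 1.4), (10.8, 0.7)):
        params = {}
        for o in ORGANS:
            g = g_rep if o in ("ovary", "testis") else g_oth
            params[o] = OrganOUParams(alpha=0.05, sigma2=2 * 0.05 * g,
                                      theta0=0.0)
        models.append(RegimeModel([], params, pd.DataFrame(columns=list(ORGANS)),
                                  {}, 0.0, 0.0, 18, 8))
    out = pr.stationary_variance_compare(models)
    assert out["median_reproductive"] > out["median_other"]
    assert out["test"]["p"] < 0.01


# ---------------------------------------------------------------------------
# transition matrices and permutation null
# ---------------------------------------------------------------------------

def _records_from_pairs(pairs):
    rows = [{"peo_anc": a, "peo_der": d, "peo_switch": a != d,
             "category": "S"} for a, d in pairs]
    return pd.DataFrame(rows)


def test_transition_matrix_counts_and_zero_diagonal():
    rec = _records_from_pairs([("brain", "testis")] * 3
                              + [("testis", "brain")]
                              + [("brain", "brain")])
    tm = transition_matrix(rec)
    assert tm.counts.loc["brain", "testis"] == 3
    assert tm.counts.loc["testis", "brain"] == 1
    assert tm.total == 4                       # non-switching excluded


def test_identical_matrices_have_spearman_rho_one():
    rec = _records_from_pairs([("brain", "testis")] * 3
                              + [("heart", "liver")] * 2)
    m = transition_matrix(rec)
    out = pr.compare_matrices({"A": m, "B": m})
    assert out["spearman"][("A", "B")]["rho"] == pytest.approx(1.0)


def test_permutation_preserves_margins():
    rng = np.random.default_rng(6)
    pairs = [(ORGANS[a], ORGANS[d]) for a, d in
             zip(rng.integers(0, 6, 200), rng.integers(0, 6, 200))
             if a != d]
    tm = transition_matrix(_records_from_pairs(pairs))
    null = pr._null_transition_counts(tm, 200, seed=0)
    obs = tm.counts.to_numpy()
    for p in range(200):
        mat = null[p].reshape(6, 6)
        assert np.array_equal(mat.sum(axis=1), obs.sum(axis=1))
        assert np.array_equal(mat.sum(axis=0), obs.sum(axis=0))


def test_extreme_cell_reaches_minimal_pvalue():
    rec = _records_from_pairs([("brain", "testis")] * 40
                              + [("heart", "liver")] * 40)
    tm = transition_matrix(rec)
    p = permutation_enrichment(tm, StatsConfig(n_perm=999, seed=0))
    assert p.loc["brain", "testis"] <= 2.0 / (999 + 1) + 1e-12


def test_degenerate_margins_rejected():
    rec = _records_from_pairs([("brain", "testis")] * 5)
    tm = transition_matrix(rec)
    with pytest.raises(ValueError):
        permutation_enrichment(tm, StatsConfig(n_perm=100))


def test_zero_permutations_rejected():
    with pytest.raises(ValueError):
        StatsConfig(n_perm=0)


# ---------------------------------------------------------------------------
# polarity
# ---------------------------------------------------------------------------

def test_polarity_reference_values():
    m = np.zeros((6, 6))
    m[0, 1], m[1, 0] = 3, 1
    assert polarity_value(m) == pytest.approx(0.5)
    m2 = np.zeros((6, 6))
    m2[0, 1] = m2[1, 0] = 7
    assert polarity_value(m2) == 0.0
    m3 = np.zeros((6, 6))
    m3[2, 4] = 9
    assert polarity_value(m3) == 1.0


def test_polarity_invariant_under_organ_relabeling():
    rng = np.random.default_rng(7)
    m = rng.integers(0, 20, (6, 6)).astype(float)
    np.fill_diagonal(m, 0)
    v = polarity_value(m)
    perm = rng.permutation(6)
    assert polarity_value(m[np.ix_(perm, perm)]) == pytest.approx(v)


def test_polarity_bootstrap_and_ks_comparison():
    rng = np.random.default_rng(8)
    pairs_a = [("brain", "testis")] * 50 + [("testis", "brain")] * 10
    pairs_b = [("brain", "testis")] * 30 + [("testis", "brain")] * 30
    ra, rb = _records_from_pairs(pairs_a), _records_from_pairs(pairs_b)
    ta, tb = transition_matrix(ra), transition_matrix(rb)
    cfg = StatsConfig(n_boot=300, seed=1)
    pa, pb = polarity(ta, ra, cfg), polarity(tb, rb, cfg)
    assert pa["polarity"] > pb["polarity"]
    cmpres = pr.polarity_compare(pa["bootstrap"], pb["bootstrap"])
    assert cmpres["p"] < 0.01


# ---------------------------------------------------------------------------
# omega analysis
# ---------------------------------------------------------------------------

def _omega_records(n, rng, slope=0.0):
    tec_vals = rng.uniform(0, 1, n)
    log_ratio = slope * tec_vals + rng.normal(0, 0.2, n)
    omega_sister = rng.uniform(0.05, 0.5, n)
    omega_shift = omega_sister * 2.0 ** log_ratio
    return pd.DataFrame({
        "category": rng.choice(["S", "D", "R"], n),
        "omega_shift": omega_shift, "omega_sister": omega_sister,
        "sister_shifted": False,
        "d_tau": rng.normal(0, 0.3, n), "d_mu_max": rng.normal(0, 1, n),
        "tec": tec_vals,
        "peo_switch": True, "peo_anc": "brain", "peo_der": "testis"})


def test_omega_identical_pairs_all_undifferentiated():
    rng = np.random.default_rng(9)
    rec = _omega_records(60, rng)
    rec["omega_shift"] = rec["omega_sister"]
    out = omega_analysis(rec)
    assert out["classification"] == {"undifferentiated": 60}
    for cat in out["regressions"].values():
        for r in cat.values():
            if not r["insufficient"]:
                assert abs(r["slope"]) < 1e-9


def test_omega_planted_tec_slope_recovered():
    rng = np.random.default_rng(10)
    rec = _omega_records(500, rng, slope=1.2)
    out = omega_analysis(rec)
    for cat, reg in out["regressions"].items():
        assert reg["tec"]["slope"] > 0
        assert reg["tec"]["p"] < 0.05


def test_omega_insufficient_regression_guard():
    rng = np.random.default_rng(11)
    rec = _omega_records(2, rng)
    out = omega_analysis(rec)
    found = [r for reg in out["regressions"].values() for r in reg.values()]
    assert any(r["insufficient"] for r in found)


def test_omega_excludes_shifted_sisters_and_bad_values():
    rng = np.random.default_rng(12)
    rec = _omega_records(20, rng)
    rec.loc[rec.index[:5], "sister_shifted"] = True
    rec.loc[rec.index[5:8], "omega_shift"] = -1.0
    out = omega_analysis(rec)
    assert out["excluded_pairs"] == 8


# ---------------------------------------------------------------------------
# robustness subsets
# ---------------------------------------------------------------------------

def test_zero_thresholds_reproduce_full_analysis():
    rng = np.random.default_rng(13)
    pairs = [(ORGANS[a], ORGANS[d]) for a, d in
             zip(rng.integers(0, 6, 150), rng.integers(0, 6, 150)) if a != d]
    rec = _records_from_pairs(pairs)
    rec["tau_der"] = rng.uniform(0.3, 1.0, len(rec))
    rec["bootstrap_support"] = 1.0
    cfg = StatsConfig(n_perm=500, seed=3)
    full = transition_matrix(rec)
    out = robustness_subsets(rec, {"min_tau": 0.0, "min_support": 0.0}, cfg)
    assert not out["skipped"]
    assert out["matrix"].counts.equals(full.counts)
    assert out["concordance"] == pytest.approx(1.0)


def test_impossible_filter_reports_empty_subset():
    rec = _records_from_pairs([("brain", "testis")] * 5)
    rec["tau_der"] = 0.1
    rec["bootstrap_support"] = 0.5
    out = robustness_subsets(rec, {"min_tau": 0.9}, StatsConfig(n_perm=100))
    assert out["skipped"] and out["n_records"] == 0
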