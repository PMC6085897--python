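import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats as sps

from alpaca_cwas.stats import (
    CorrectionResult,
    StatsError,
    classify_symmetry,
    correct,
    effective_tests,
    effective_tests_from_correlation,
    fit_all_edges,
    fit_edge_model,
    sidak_alpha,
    significant_edges,
    tally_by_group,
)


def covariates(n, rng=None, seed=0):
    rng = rng or np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "age": rng.uniform(6, 10, n),
            "sex": rng.integers(0, 2, n),
            "cbcl_sqrt_total": np.sqrt(rng.poisson(9, n).astype(float)),
        }
    )


# -- edgewise model ---------------------------------------------------------


def test_exact_linear_age_effect_recovered():
    covs = covariates(50)
    z = 0.2 + 0.05 * covs["age"].to_numpy()
    row = fit_edge_model(z, covs)
    assert row["beta_age"] == pytest.approx(0.05, abs=1e-10)
    assert row["p_age"] < 1e-12


def test_interaction_term_recovered():
    covs = covariates(80)
    z = 0.1 + 0.03 * covs["age"] * covs["sex"]
    row = fit_edge_model(z.to_numpy(), covs, interaction=True)
    assert row["beta_interaction"] == pytest.approx(0.03, abs=1e-8)
    assert row["p_interaction"] < 1e-10


def test_constant_edge_degenerates_to_p_one():
    covs = covariates(30)
    with pytest.warns(RuntimeWarning, match="constant edge"):
        row = fit_edge_model(np.full(30, 0.4), covs)
    assert row["p_age"] == 1.0 and row["beta_age"] == 0.0


def test_collinear_covariates_named():
    covs = covariates(30)
    covs["cbcl_sqrt_total"] = 2.0 * covs["age"]
    with pytest.raises(StatsError, match="collinear"):
        fit_edge_model(np.random.default_rng(0).standard_normal(30), covs)


def test_too_few_subjects_rejected():
    covs = covariates(4)
    with pytest.raises(StatsError, match="subjects"):
        fit_edge_model(np.zeros(4), covs)


def test_null_p_values_uniform():
    """Under the global null the age p-value is Uniform(0,1) (K-S check)."""
    rng = np.random.default_rng(7)
    covs = covariates(40, rng=rng)
    pvals = [
        fit_edge_model(rng.standard_normal(40), covs)["p_age"] for _ in range(1000)
    ]
    d, _ = sps.kstest(pvals, "uniform")
    assert d < 0.05


# -- effective number of tests ----------------------------------------------


def test_meff_identity_correlation_is_m(rng):
    X = rng.standard_normal((500, 8))
    m_eff = effective_tests(X)
    assert m_eff == pytest.approx(8, abs=0.7)  # sampling wiggle only
    assert effective_tests_from_correlation(np.eye(8)) == 8.0


def test_meff_rank_one_is_one(rng):
    base = rng.standard_normal(100)
    X = np.column_stack([base * s for s in (1.0, 2.0, -3.0, 0.5)])
    assert effective_tests(X) == pytest.approx(1.0)


def test_meff_two_edges_half_correlation():
    corr = np.array([[1.0, 0.5], [0.5, 1.0]])  # eigenvalues 1.5, 0.5
    assert effective_tests_from_correlation(corr) == pytest.approx(2.0)
    assert effective_tests_from_correlation(corr, "kaiser") == 1.0


def test_meff_invariant_to_edge_rescaling(rng):
    X = rng.standard_normal((80, 6))
    scales = np.array([0.1, 5, 1, 2, 0.5, 100.0])
    assert effective_tests(X * scales) == pytest.approx(effective_tests(X))


def test_meff_input_validation(rng):
    with pytest.raises(StatsError):
        effective_tests(rng.standard_normal((2, 5)))
    X = rng.standard_normal((30, 3))
    X[:, 1] = 2.0
    with pytest.raises(StatsError, match="zero-variance"):
        effective_tests(X)


# -- Sidak ------------------------------------------------------------------


def test_sidak_identity_and_values():
    assert sidak_alpha(1.0) == pytest.approx(0.05)
    assert sidak_alpha(2.0) == pytest.approx(0.025321, abs=1e-6)
    with pytest.raises(StatsError):
        sidak_alpha(0.5)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(hst.floats(1.0, 5000.0))
def test_sidak_never_more_conservative_than_bonferroni(m_eff):
    assert sidak_alpha(m_eff) >= 0.05 / m_eff


def test_sidak_monotone_decreasing():
    grid = np.linspace(1, 200, 100)
    vals = [sidak_alpha(m) for m in grid]
    assert all(a > b for a, b in zip(vals, vals[1:]))


# -- significant edges, symmetry, tallies -----------------------------------


def _correction(alpha_corr=0.01):
    return CorrectionResult(
        method="meants", M=10, M_eff=5.0, alpha=0.05, alpha_corr=alpha_corr
    )


def _table(rows):
    df = pd.DataFrame(
        rows, columns=["region_a", "region_b", "beta_age", "p_age"]
    )
    for col in ("beta_sex", "beta_cbcl"):
        df[col] = 0.0
    for col in ("p_sex", "p_cbcl"):
        df[col] = 1.0
    df["n_subjects"] = 100
    return df


def test_significant_edges_thresholding_and_sign():
    table = _table(
        [
            ("A_L", "B_L", 0.2, 0.001),
            ("A_R", "B_R", -0.1, 0.005),
            ("A_L", "B_R", 0.3, 0.5),
        ]
    )
    sig = significant_edges(table, _correction(0.01), "age")
    assert len(sig) == 2
    assert list(sig["sign"]) == [1, -1]


def test_all_p_one_yields_empty_set():
    table = _table([("A_L", "B_L", 0.2, 1.0)])
    assert significant_edges(table, _correction(), "age").empty


def _sig_frame(edges):
    return pd.DataFrame(
        {
            "region_a": [a for a, _ in edges],
            "region_b": [b for _, b in edges],
            "beta": 0.1,
            "p": 0.001,
            "sign": 1,
        }
    )


def test_symmetry_definitions(small_atlas):
    sig = _sig_frame([("Cac_L", "Cun_L"), ("Cac_R", "Cun_R")])
    rep = classify_symmetry(sig, small_atlas)
    assert len(rep) == 1
    assert bool(rep["intra_symmetric"].iloc[0])
    assert not bool(rep["inter_symmetric"].iloc[0])

    sig = _sig_frame([("Cac_L", "Cun_R")])
    assert classify_symmetry(sig, small_atlas).empty

    sig = _sig_frame([("Cac_L", "Cun_R"), ("Cac_R", "Cun_L")])
    rep = classify_symmetry(sig, small_atlas)
    assert bool(rep["inter_symmetric"].iloc[0])
    assert not bool(rep["intra_symmetric"].iloc[0])


@pytest.mark.parametrize("seed", range(20))
def test_symmetry_matches_set_membership_oracle(seed, small_atlas):
    rng = np.random.default_rng(seed)
    keys = small_atlas.keys
    all_edges = [
        (keys[i], keys[j]) for i in range(len(keys)) for j in range(i + 1, len(keys))
    ]
    chosen = [all_edges[i] for i in rng.choice(len(all_edges), 12, replace=False)]
    rep = classify_symmetry(_sig_frame(chosen), small_atlas)
    edge_set = {frozenset(e) for e in chosen}
    bases = {r.abbreviation for r in small_atlas.regions}
    expected = []
    for x in sorted(bases):
        for y in sorted(bases):
            if x > y:
                continue
            intra = (
                frozenset((f"{x}_L", f"{y}_L")) in edge_set
                and frozenset((f"{x}_R", f"{y}_R")) in edge_set
            )
            inter = (
                frozenset((f"{x}_L", f"{y}_R")) in edge_set
                and frozenset((f"{x}_R", f"{y}_L")) in edge_set
            )
            if intra or inter:
                expected.append((x, y, intra, inter))
    got = [
        (
            min(r["region_x"], r["region_y"]),
            max(r["region_x"], r["region_y"]),
            bool(r["intra_symmetric"]),
            bool(r["inter_symmetric"]),
        )
        for _, r in rep.iterrows()
    ]
    assert sorted(got) == sorted(expected)


def test_tally_single_edge_cell(small_atlas):
    sig = _sig_frame([("Acc_L", "Acc_R")])  # Sub/Sub, Between
    sig["sign"] = -1
    tally = tally_by_group(sig, small_atlas)
    assert len(tally) == 1
    row = tally.iloc[0]
    assert (row["group_pair"], row["sign"], row["location"]) == (
        "Sub/Sub",
        "negative",
        "Between",
    )
    assert row["count"] == 1


def test_tally_partitions_significant_set(small_atlas, rng):
    keys = small_atlas.keys
    all_edges = [
        (keys[i], keys[j]) for i in range(len(keys)) for j in range(i + 1, len(keys))
    ]
    chosen = [all_edges[i] for i in rng.choice(len(all_edges), 20, replace=False)]
    sig = _sig_frame(chosen)
    sig.loc[::2, "sign"] = -1
    tally = tally_by_group(sig, small_atlas)
    assert tally["count"].sum() == len(sig)


def test_left_right_between_locations(small_atlas):
    sig = _sig_frame([("Cac_L", "Cun_L"), ("Cac_R", "Cun_R"), ("IPa_L", "Acc_R")])
    tally = tally_by_group(sig, small_atlas)
    assert set(tally["location"]) == {"Left", "Right", "Between"}


# -- correction container ---------------------------------------------------


def test_correct_bundles_m_and_threshold(rng):
    X = rng.standard_normal((60, 5))
    res = correct(X, "alpaca")
    assert res.M == 5
    assert 1 <= res.M_eff <= 5
    assert res.alpha_corr == pytest.approx(sidak_alpha(res.M_eff))
    with pytest.raises(StatsError):
        CorrectionResult("meants", M=5, M_eff=9.0, alpha=0.05, alpha_corr=0.01)
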