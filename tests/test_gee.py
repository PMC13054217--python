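"""GEE estimator: oracle equivalence, invariances, error handling."""

import numpy as np
import pandas as pd
import pytest

import woundcdss as w
from woundcdss.gee import BinaryGEE

from conftest import random_binary_table
from oracles import logistic_mle


def _fit(df, cov_struct="exchangeable", covariates=("x",), outcome="y", cluster="cluster"):
    return BinaryGEE.from_dataframe(
        df, outcome=outcome, covariates=list(covariates), cluster=cluster,
        cov_struct=cov_struct,
    ).fit()


def test_independence_equals_logistic_mle(rng):
    """With an independence working correlation the GEE point estimates are the MLE."""
    for _ in range(5):
        df = random_binary_table(rng)
        fit = _fit(df, cov_struct="independence")
        X = np.column_stack([np.ones(len(df)), df["x"]])
        beta = logistic_mle(df["y"], X)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-8)


def test_singleton_clusters_give_alpha_zero(rng):
    df = random_binary_table(rng, n_clusters=80, cluster_size=1)
    fit = _fit(df, cov_struct="exchangeable")
    assert fit.alpha == 0.0
    X = np.column_stack([np.ones(len(df)), df["x"]])
    np.testing.assert_allclose(fit.params.to_numpy(), logistic_mle(df["y"], X), atol=1e-8)


def test_matches_statsmodels_exchangeable(sim_table):
    """Full agreement with an independent GEE implementation on a realistic table."""
    sm = pytest.importorskip("statsmodels.api")
    analysis = w.analyze_crossover(sim_table, outcome="ointment")
    d = sim_table.copy()
    d["treatment"] = d["treatment"].map({"control": 0, "intervention": 1})
    d["sequence"] = d["sequence"].map({"A": 0, "B": 1})
    d["period"] = d["period"].map({1: 0, 2: 1})
    X = sm.add_constant(d[["treatment", "period", "sequence"]])
    ref = sm.GEE(
        d["outcome_ointment"], X, groups=d["participant_id"],
        family=sm.families.Binomial(), cov_struct=sm.cov_struct.Exchangeable(),
    ).fit()
    np.testing.assert_allclose(analysis.fit.params.to_numpy(), ref.params.to_numpy(), atol=1e-6)
    np.testing.assert_allclose(analysis.fit.bse.to_numpy(), ref.bse.to_numpy(), atol=1e-6)


def test_within_cluster_permutation_invariance(rng):
    df = random_binary_table(rng, n_clusters=20, cluster_size=8)
    fit = _fit(df)
    shuffled = (
        df.sample(frac=1.0, random_state=3)
        .sort_values("cluster", kind="stable")
        .reset_index(drop=True)
    )
    fit2 = _fit(shuffled)
    np.testing.assert_allclose(fit.params.to_numpy(), fit2.params.to_numpy(), atol=1e-10)
    assert fit.alpha == pytest.approx(fit2.alpha, abs=1e-12)
    np.testing.assert_allclose(
        fit.cov_robust.to_numpy(), fit2.cov_robust.to_numpy(), atol=1e-10
    )


def test_alpha_near_zero_on_independent_data():
    params = w.SimulationParams(
        n_participants=300, p_correct_control=0.4, p_correct_intervention=0.4,
        random_intercept_sd=0.0, seed=9,
    )
    fit = w.analyze_crossover(w.simulate_trial(params), outcome="dressing").fit
    assert abs(fit.alpha) < 0.05


def test_alpha_positive_with_random_intercepts():
    params = w.SimulationParams(
        n_participants=500, p_correct_control=0.4, p_correct_intervention=0.4,
        random_intercept_sd=1.0, seed=10,
    )
    fit = w.analyze_crossover(w.simulate_trial(params), outcome="dressing").fit
    assert fit.alpha > 0.1


def test_alpha_within_valid_range(sim_table):
    fit = w.analyze_crossover(sim_table, outcome="total").fit
    max_n = sim_table.groupby("participant_id").size().max()
    assert -1.0 / (max_n - 1) < fit.alpha < 1.0


def test_separation_error_names_covariate():
    rows = []
    for c in range(10):
        for j in range(4):
            t = j % 2
            rows.append({"cluster": c, "treatment": t, "y": t})
    with pytest.raises(w.SeparationError, match="treatment"):
        BinaryGEE.from_dataframe(
            pd.DataFrame(rows), outcome="y", covariates=["treatment"], cluster="cluster"
        ).fit()


def test_structural_errors(rng):
    df = random_binary_table(rng, n_clusters=1, cluster_size=10)
    with pytest.raises(ValueError, match="clusters"):
        BinaryGEE.from_dataframe(df, outcome="y", covariates=["x"], cluster="cluster")
    df2 = random_binary_table(rng)
    df2["x2"] = 2.0 * df2["x"]
    with pytest.raises(ValueError, match="rank"):
        BinaryGEE.from_dataframe(df2, outcome="y", covariates=["x", "x2"], cluster="cluster")
    df3 = random_binary_table(rng)
    df3["y"] = df3["y"].astype(float)
    df3.loc[0, "y"] = 0.5
    with pytest.raises(ValueError, match="binary"):
        BinaryGEE.from_dataframe(df3, outcome="y", covariates=["x"], cluster="cluster")


def test_wald_and_odds_ratio_consistency(sim_table):
    fit = w.analyze_crossover(sim_table, outcome="ointment").fit
    z, p = fit.wald_test("treatment")
    b = fit.params["treatment"]
    se = fit.bse["treatment"]
    assert z == pytest.approx(b / se)
    orr, lo, hi = fit.odds_ratio("treatment")
    assert orr == pytest.approx(np.exp(b))
    # CI symmetric on the log scale around the estimate
    assert np.log(orr) - np.log(lo) == pytest.approx(np.log(hi) - np.log(orr), rel=1e-9)
    with pytest.raises(KeyError):
        fit.wald_test("nonexistent")


def test_robust_cov_is_symmetric_psd(sim_table):
    fit = w.analyze_crossover(sim_table, outcome="total").fit
    C = fit.cov_robust.to_numpy()
    np.testing.assert_allclose(C, C.T, atol=1e-12)
    assert np.all(np.linalg.eigvalsh(C) > -1e-12)
    assert fit.n_obs == len(sim_table)
    assert fit.converged


def test_mancl_derouen_inflates_se(sim_table):
    base = w.analyze_crossover(sim_table, outcome="ointment").fit
    corrected = w.analyze_crossover(sim_table, outcome="ointment", bias_corrected=True).fit
    assert (corrected.bse.to_numpy() >= base.bse.to_numpy() - 1e-12).all()
    np.testing.assert_allclose(corrected.params.to_numpy(), base.params.to_numpy(), atol=1e-12)


def test_summary_renders(sim_table):
    analysis = w.analyze_crossover(sim_table, outcome="total")
    text = analysis.summary()
    assert "aOR" in text and "treatment" in text
    d = analysis.to_dict()
    assert d["outcome"] == "total"
    assert 0 <= d["p_value"] <= 1
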