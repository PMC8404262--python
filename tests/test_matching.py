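"""Propensity-score model, greedy caliper matching and balance diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import expit

from jaderpv.matching import (
    FittingError,
    adjusted_ror,
    balance_table,
    band_midpoint,
    build_covariates,
    fit_ps_model,
    greedy_caliper_match,
    match_therapy_arms,
    smd,
)
from jaderpv.reference import BALANCE_PROPORTIONS
from jaderpv.simulate import generate, preset


def test_band_midpoint():
    assert band_midpoint("0-9") == 5.0
    assert band_midpoint("60-69") == 65.0
    assert band_midpoint("150-159") == 155.0
    assert band_midpoint(">=100") == 105.0
    assert math.isnan(band_midpoint("unknown"))
    assert math.isnan(band_midpoint(None))


# ----------------------------------------------------------------------
# standardized mean difference


def test_smd_binary_published_proportions():
    for cov, phase, expected in (
        ("sepsis", "before", 0.2190),
        ("male", "before", 0.0985),
        ("sepsis", "after", 0.0048),
        ("male", "after", 0.0100),
    ):
        p1, p2, published = BALANCE_PROPORTIONS[cov][phase]
        assert published == expected
        assert round(smd(p1, p2, kind="binary"), 4) == pytest.approx(expected, abs=5e-5)


def test_smd_numeric_hand_example():
    x1 = [65, 65, 75, 75]
    x2 = [55, 65, 65, 75]
    s2 = ((np.var(x1, ddof=1) + np.var(x2, ddof=1)) / 2) ** 0.5
    assert smd(x1, x2, kind="binned-numeric") == pytest.approx(5 / s2)
    assert smd(x1, x1, kind="binned-numeric") == 0.0


def test_smd_degenerate_and_invalid():
    assert smd([1, 1], [1, 1], kind="binned-numeric") == 0.0
    assert math.isinf(smd([1, 1], [2, 2], kind="binned-numeric"))
    with pytest.raises(ValueError):
        smd([1], [], kind="binned-numeric")
    with pytest.raises(ValueError):
        smd([1], [1], kind="percentile")


# ----------------------------------------------------------------------
# logistic PS model


def test_logistic_coefficient_closed_form():
    # single binary covariate: the slope is the log odds ratio of the 2x2 table
    rows = []
    for x, treated, count in ((1, 1, 30), (1, 0, 20), (0, 1, 10), (0, 0, 40)):
        rows += [{"treated": bool(treated), "x": float(x)}] * count
    frame = pd.DataFrame(rows, index=[f"c{i}" for i in range(100)])
    model = fit_ps_model(frame, model_covariates=("x",))
    assert model.params["x"] == pytest.approx(math.log((30 / 20) / (10 / 40)), abs=1e-6)
    assert model.params["const"] == pytest.approx(math.log(10 / 40), abs=1e-6)
    assert model.n_treated == 40 and model.n_control == 60
    assert 0.5 < model.auc < 1.0


def test_logistic_fit_matches_generic_optimizer():
    rng = np.random.default_rng(5)
    n = 800
    x1, x2 = rng.normal(size=n), rng.normal(size=n)
    y = rng.random(n) < expit(-0.3 + 0.8 * x1 - 0.5 * x2)
    frame = pd.DataFrame(
        {"treated": y, "a": x1, "b": x2}, index=[f"c{i}" for i in range(n)]
    )
    model = fit_ps_model(frame, model_covariates=("a", "b"))

    X = np.column_stack([np.ones(n), x1, x2])

    def nll(beta):
        eta = X @ beta
        return -np.sum(y * eta - np.logaddexp(0.0, eta))

    res = optimize.minimize(nll, np.zeros(3), method="BFGS", options={"gtol": 1e-12})
    assert model.params.to_numpy() == pytest.approx(res.x, abs=1e-6)


def test_ps_model_needs_two_arms():
    frame = pd.DataFrame({"treated": [True] * 5, "x": range(5)}, index=list("abcde"))
    with pytest.raises(FittingError):
        fit_ps_model(frame, model_covariates=("x",))


# ----------------------------------------------------------------------
# greedy caliper matching


def series(values, prefix):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


def test_caliper_hand_example():
    # logits 0 and 1 (treated), 0.05 and 3 (controls)
    logits = np.array([0.0, 1.0, 0.05, 3.0])
    ps = pd.Series(expit(logits), index=["t0", "t1", "c0", "c1"])
    treated = pd.Series([True, True, False, False], index=ps.index)
    result = greedy_caliper_match(ps, treated, caliper_multiplier=0.2, seed=0)
    assert result.caliper == pytest.approx(0.2 * np.std(logits, ddof=1))
    # only t0–c0 (distance 0.05) fits within the caliper; t1's nearest control
    # is 0.95 away and both controls are > caliper from t1
    assert result.n_matched == 1
    pair = result.pairs.iloc[0]
    assert (pair["treated_id"], pair["control_id"]) == ("t0", "c0")
    assert pair["logit_distance"] == pytest.approx(0.05)
    assert result.n_unmatched_treated == 1


def test_matching_without_replacement_and_within_caliper():
    rng = np.random.default_rng(42)
    ps = series(rng.uniform(0.05, 0.95, 400), "c")
    treated = pd.Series(rng.random(400) < 0.3, index=ps.index)
    result = greedy_caliper_match(ps, treated, seed=1)
    assert result.pairs["control_id"].is_unique
    assert result.pairs["treated_id"].is_unique
    assert (result.pairs["logit_distance"] <= result.caliper + 1e-12).all()
    assert set(result.treated_ids) <= set(ps.index[treated])
    assert set(result.control_ids) <= set(ps.index[~treated])


def test_matching_invariant_to_input_row_order():
    rng = np.random.default_rng(9)
    ps = series(rng.uniform(0.1, 0.9, 300), "c")
    treated = pd.Series(rng.random(300) < 0.4, index=ps.index)
    base = greedy_caliper_match(ps, treated, seed=7)
    perm = rng.permutation(300)
    shuffled = greedy_caliper_match(ps.iloc[perm], treated.iloc[perm], seed=7)
    pd.testing.assert_frame_equal(base.pairs, shuffled.pairs)


def test_identical_scores_match_exhaustively_at_zero_distance():
    ps = pd.Series([0.4] * 10, index=[f"c{i}" for i in range(10)])
    treated = pd.Series([True] * 6 + [False] * 4, index=ps.index)
    result = greedy_caliper_match(ps, treated, seed=0)
    assert result.n_matched == 4  # controls exhausted
    assert (result.pairs["logit_distance"] == 0).all()


def test_matching_rejects_degenerate_inputs():
    ps = pd.Series([0.5, 1.0], index=["a", "b"])
    treated = pd.Series([True, False], index=ps.index)
    with pytest.raises(ValueError, match="strictly"):
        greedy_caliper_match(ps, treated)
    ps = pd.Series([0.5, 0.6], index=["a", "b"])
    with pytest.raises(ValueError, match="non-empty"):
        greedy_caliper_match(ps, pd.Series([True, True], index=ps.index))


# ----------------------------------------------------------------------
# end-to-end on a database with planted confounding


@pytest.fixture(scope="module")
def ps_run():
    db, truth = generate(preset("ps-demo", seed=17))
    model, match, balance = match_therapy_arms(db, seed=17)
    return db, truth, model, match, balance


def test_covariate_frame_restricted_to_therapy_arms(ps_run):
    db, truth, *_ = ps_run
    covariates, n_excluded = build_covariates(db)
    counts = truth.anti_infective_count
    assert len(covariates) + n_excluded == int((counts >= 1).sum())
    assert covariates["treated"].sum() > 0
    assert set(covariates.columns) >= {"treated", "age", "height", "weight", "sepsis", "male", "aki"}


def test_planted_allocation_recovered_by_ps_model(ps_run):
    _, _, model, _, _ = ps_run
    # the generator shifts combination-therapy allocation by sepsis and age
    assert model.params["sepsis"] > 0.5
    assert model.params["age"] > 0
    assert model.auc > 0.55
    assert model.converged


def test_matching_restores_balance_single_run(ps_run):
    _, _, _, match, balance = ps_run
    assert match.n_matched > 100
    assert balance["smd_before"].max() > 0.1  # imbalance was planted
    assert (balance["smd_after"] < 0.1).all()
    assert (balance["smd_after"].mean()) < balance["smd_before"].mean()
    assert list(balance.index) == ["age", "weight", "height", "sepsis", "male"]


def test_balance_table_matches_direct_smd(ps_run):
    db, _, _, match, balance = ps_run
    covariates, _ = build_covariates(db)
    direct = smd(
        covariates.loc[match.treated_ids, "sepsis"],
        covariates.loc[match.control_ids, "sepsis"],
        kind="binary",
    )
    assert balance.loc["sepsis", "smd_after"] == pytest.approx(direct)
    pd.testing.assert_frame_equal(balance, balance_table(covariates, match))


def test_adjusted_ror_detects_planted_combination_effect(ps_run):
    db, _, _, match, _ = ps_run
    mono, combo = adjusted_ror(db, match)
    # the preset plants +0.4 log-odds on combination therapy and none on
    # individual drugs, so after balancing the combination arm stays elevated
    assert combo.defined and mono.defined
    assert combo.ror > mono.ror


def test_adjusted_ror_null_when_nothing_planted():
    hits = 0
    reps = 20
    for rep in range(reps):
        cfg = preset("ps-demo", n_reports=4000, seed=100 + rep)
        cfg.combination_aki_log_odds = 0.0
        cfg.sepsis_aki_log_odds = 0.0
        db, _ = generate(cfg)
        _, match, _ = match_therapy_arms(db, seed=rep)
        mono, combo = adjusted_ror(db, match)
        if mono.ci_low <= 1 <= mono.ci_high and combo.ci_low <= 1 <= combo.ci_high:
            hits += 1
    # both matched-arm CIs should cover the null in the vast majority of runs
    assert hits >= reps * 0.8


def test_adjusted_ror_requires_matches():
    db, _ = generate(preset("ps-demo", n_reports=2000, seed=2))
    from jaderpv.matching import MatchResult

    empty = MatchResult(
        pairs=pd.DataFrame(columns=["treated_id", "control_id", "logit_distance"]),
        caliper=0.1,
        n_treated=5,
        n_control=5,
        n_unmatched_treated=5,
    )
    with pytest.raises(ValueError, match="empty"):
        adjusted_ror(db, empty)
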