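"""Time-to-onset extraction, summaries and Weibull hazard profiling."""

import math

import numpy as np
import pytest

from jaderpv.onset import (
    HazardClass,
    OnsetObservation,
    WeibullFitError,
    classify_beta_ci,
    extract_onsets,
    hazard_class,
    median_iqr,
    onset_histogram,
    onset_profile_table,
    weibull_mle,
)
from jaderpv.simulate import generate, preset

from conftest import AKI_PT, CREATININE_PT, demo_row, drug_row, make_db, reac_row


# ----------------------------------------------------------------------
# extraction and date arithmetic


def test_onset_day_difference():
    db = make_db(
        [demo_row("A")],
        drug_rows=[drug_row("A", "vancomycin", start="2020-01-01")],
        reac_rows=[reac_row("A", AKI_PT, onset="2020-01-06")],
    )
    obs = extract_onsets(db, "J01XA")
    assert len(obs) == 1
    assert obs[0].t == 5.0
    assert obs[0].route == "iv"


def test_earliest_start_and_earliest_onset_are_used():
    db = make_db(
        [demo_row("A")],
        drug_rows=[
            drug_row("A", "vancomycin", start="2020-01-10"),
            drug_row("A", "vancomycin", start="2020-01-02"),
        ],
        reac_rows=[
            reac_row("A", AKI_PT, onset="2020-01-20"),
            reac_row("A", CREATININE_PT, onset="2020-01-08"),
        ],
    )
    obs = extract_onsets(db, "J01XA")
    assert [o.t for o in obs] == [6.0]  # Jan 8 − Jan 2


def test_window_and_negative_differences_excluded():
    db = make_db(
        [demo_row("A"), demo_row("B"), demo_row("C"), demo_row("D")],
        drug_rows=[
            drug_row("A", "vancomycin", start="2020-01-10"),  # onset before start
            drug_row("B", "vancomycin", start="2020-01-01"),  # t = 91, out of window
            drug_row("C", "vancomycin", start="2020-01-01"),  # t = 90, kept
            drug_row("D", "vancomycin"),  # missing start date
        ],
        reac_rows=[
            reac_row("A", AKI_PT, onset="2020-01-05"),
            reac_row("B", AKI_PT, onset="2020-04-01"),
            reac_row("C", AKI_PT, onset="2020-03-31"),
            reac_row("D", AKI_PT, onset="2020-01-05"),
        ],
    )
    obs = extract_onsets(db, "J01XA", window_days=90)
    assert [(o.case_id, o.t) for o in obs] == [("C", 90.0)]


def test_route_filter_and_pooled_extraction():
    db = make_db(
        [demo_row("A"), demo_row("B")],
        drug_rows=[
            drug_row("A", "vancomycin", route="iv", start="2020-01-01"),
            drug_row("A", "levofloxacin", route="po", start="2020-01-03"),
            drug_row("B", "acetaminophen", route="po", start="2020-01-01"),
        ],
        reac_rows=[
            reac_row("A", AKI_PT, onset="2020-01-07"),
            reac_row("B", AKI_PT, onset="2020-01-04"),
        ],
    )
    assert [o.t for o in extract_onsets(db, route="iv")] == [6.0]
    assert [o.t for o in extract_onsets(db, route="po")] == [4.0]
    # pooled extraction covers anti-infectives only: B's analgesic is excluded
    assert len(extract_onsets(db)) == 2


def test_median_iqr_examples():
    assert median_iqr([5]) == (5.0, 5.0, 5.0)
    assert median_iqr(range(1, 10)) == (5.0, 3.0, 7.0)
    med, q1, q3 = median_iqr([1, 2, 3, 4])
    assert (med, q1, q3) == (2.5, 1.75, 3.25)
    with pytest.raises(ValueError):
        median_iqr([])


# ----------------------------------------------------------------------
# Weibull maximum likelihood


def weibull_grid_mle(t, bounds=((0.1, 60.0), (0.1, 6.0)), tol=1e-4):
    """Independent slow oracle: iterated grid refinement of the likelihood."""

    def nll(a, b):
        z = t / a
        return -np.sum(np.log(b / a) + (b - 1) * np.log(z) - z**b)

    (a_lo, a_hi), (b_lo, b_hi) = bounds
    for _ in range(30):
        a_grid = np.linspace(a_lo, a_hi, 41)
        b_grid = np.linspace(b_lo, b_hi, 41)
        vals = np.array([[nll(a, b) for b in b_grid] for a in a_grid])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        a_step, b_step = a_grid[1] - a_grid[0], b_grid[1] - b_grid[0]
        a_lo, a_hi = a_grid[i] - a_step, a_grid[i] + a_step
        b_lo, b_hi = max(b_grid[j] - b_step, 1e-3), b_grid[j] + b_step
        if a_step < tol / 10 and b_step < tol / 10:
            break
    return a_grid[i], b_grid[j]


def test_mle_agrees_with_grid_search_oracle():
    rng = np.random.default_rng(21)
    for n, alpha, beta in ((40, 8.0, 1.2), (50, 15.0, 0.8)):
        t = alpha * rng.weibull(beta, size=n)
        fit = weibull_mle(t, zero_policy="exclude", min_n=10)
        a_ref, b_ref = weibull_grid_mle(t[t > 0])
        assert fit.alpha == pytest.approx(a_ref, abs=1e-4)
        assert fit.beta == pytest.approx(b_ref, abs=1e-4)


def test_mle_recovers_parameters_from_large_sample():
    rng = np.random.default_rng(3)
    t = 8.28 * rng.weibull(1.03, size=10_000)
    fit = weibull_mle(t, zero_policy="exclude")
    assert fit.alpha == pytest.approx(8.28, rel=0.02)
    assert fit.beta == pytest.approx(1.03, rel=0.02)
    assert fit.alpha_ci[0] < fit.alpha < fit.alpha_ci[1]
    assert fit.beta_ci[0] < fit.beta < fit.beta_ci[1]


def test_mle_scale_equivariance():
    rng = np.random.default_rng(8)
    t = 5.0 * rng.weibull(1.1, size=300) + 0.01
    f1 = weibull_mle(t, zero_policy="exclude")
    f2 = weibull_mle(t * 3.0, zero_policy="exclude")
    assert f2.alpha == pytest.approx(3.0 * f1.alpha, rel=1e-6)
    assert f2.beta == pytest.approx(f1.beta, rel=1e-6)


def test_fit_maximizes_the_likelihood_locally():
    rng = np.random.default_rng(13)
    t = 9.0 * rng.weibull(0.9, size=200)
    fit = weibull_mle(t, zero_policy="exclude")
    tt = t[t > 0]

    def loglik(a, b):
        z = tt / a
        return float(np.sum(np.log(b / a) + (b - 1) * np.log(z) - z**b))

    best = loglik(fit.alpha, fit.beta)
    assert best == pytest.approx(fit.loglik, rel=1e-9)
    for fa, fb in ((1.05, 1.0), (0.95, 1.0), (1.0, 1.05), (1.0, 0.95)):
        assert loglik(fit.alpha * fa, fit.beta * fb) < best


def test_mle_cross_checked_against_survival_library():
    import lifelines

    rng = np.random.default_rng(1)
    t = 8.0 * rng.weibull(1.2, 500)
    fit = weibull_mle(t, zero_policy="exclude")
    wf = lifelines.WeibullFitter().fit(t[t > 0], event_observed=np.ones((t > 0).sum()))
    assert fit.alpha == pytest.approx(wf.lambda_, rel=1e-4)
    assert fit.beta == pytest.approx(wf.rho_, rel=1e-4)


def test_zero_policies():
    t = np.array([0.0, 1.0, 2.0, 3.0] * 5)
    shifted = weibull_mle(t, zero_policy="shift0.5")
    added = weibull_mle(t, zero_policy="add1")
    excluded = weibull_mle(t, zero_policy="exclude")
    assert excluded.n == 15  # the five zeros are dropped
    assert shifted.n == added.n == 20
    assert added.alpha > shifted.alpha
    # summaries always use the raw days regardless of policy
    assert shifted.median == added.median == 1.5
    with pytest.raises(ValueError, match="zero policy"):
        weibull_mle(t, zero_policy="winsorize")


def test_fit_guards():
    with pytest.raises(WeibullFitError, match="at least"):
        weibull_mle([1, 2, 3], min_n=10)
    with pytest.raises(WeibullFitError, match="identical"):
        weibull_mle([4.0] * 20)
    with pytest.raises(ValueError, match="non-negative"):
        weibull_mle([1.0, -2.0] * 10)


def test_hazard_classification_rule():
    assert classify_beta_ci(1.01, 1.18) is HazardClass.wearout_failure
    assert classify_beta_ci(0.82, 0.92) is HazardClass.initial_failure
    assert classify_beta_ci(0.99, 1.06) is HazardClass.random_failure
    assert classify_beta_ci(0.999, 1.40) is HazardClass.random_failure


def test_hazard_class_from_fit():
    rng = np.random.default_rng(30)
    fit = weibull_mle(8 * rng.weibull(1.0, 500), zero_policy="exclude")
    assert hazard_class(fit) is HazardClass.random_failure
    fit.beta_ci = (math.nan, math.nan)
    assert hazard_class(fit) is HazardClass.indeterminate


def test_shape_ci_covers_the_constant_hazard_truth():
    rng = np.random.default_rng(44)
    covered = 0
    reps = 100
    for _ in range(reps):
        t = rng.exponential(scale=7.0, size=200)  # Weibull with beta = 1
        fit = weibull_mle(t, zero_policy="exclude")
        covered += fit.beta_ci[0] <= 1.0 <= fit.beta_ci[1]
    assert covered >= 0.88 * reps


# ----------------------------------------------------------------------
# histograms and profile tables


def test_histogram_conserves_the_sample():
    obs = [OnsetObservation("A", "J01XA", "iv", t) for t in (0, 0, 1, 5, 90, 90)]
    hist = onset_histogram(obs, window_days=90)
    assert hist.sum() == 6
    assert hist[0] == 2 and hist[1] == 1 and hist[90] == 2
    assert len(hist) == 91


def test_profile_recovers_three_hazard_regimes():
    db, _ = generate(preset("tto-demo", seed=5))
    frame = onset_profile_table(db, routes=("po", "iv")).set_index(["atc_class", "route"])
    by_class = {
        code: frame.xs(code, level="atc_class").iloc[0]
        for code in ("J02AC", "J01DH", "J01GB")
        if code in frame.index.get_level_values(0)
    }
    # planted shapes: 0.7 (decreasing), 1.0 (constant), 1.4 (increasing)
    assert by_class["J02AC"]["hazard"] == "initial_failure"
    assert by_class["J01DH"]["hazard"] == "random_failure"
    assert by_class["J01GB"]["hazard"] == "wearout_failure"


def test_profile_small_cells_report_median_only():
    rows, drugs, reacs = [], [], []
    for i in range(5):  # below the default min_n of 10
        rows.append(demo_row(f"A{i}"))
        drugs.append(drug_row(f"A{i}", "vancomycin", start="2020-01-01"))
        reacs.append(reac_row(f"A{i}", AKI_PT, onset=f"2020-01-0{i + 2}"))
    db = make_db(rows, drug_rows=drugs, reac_rows=reacs)
    frame = onset_profile_table(db, atc_classes=["J01XA"], routes=("iv",))
    assert len(frame) == 2  # the class row plus the pooled Total row
    row = frame.iloc[0]
    assert row["n"] == 5
    assert row["median"] == 3.0
    assert math.isnan(row["alpha"]) and row["hazard"] == ""
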