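"""Discrete-time hazard estimation: closed-form checks for the pooled
logistic model, cumulative-incidence arithmetic, agreement with a
continuous-time proportional-hazards fit in the rare-event regime, and the
person-level bootstrap."""

import numpy as np
import pandas as pd
import pytest

from ttemu import (
    BootstrapSpec,
    SplineSpec,
    bootstrap_cis,
    cox_crude_hr,
    crude_estimates,
    cumulative_incidence,
    fit_pooled_logistic,
    hazard_ratio,
    risk_difference,
)
from ttemu.hazard_estimation import (
    BootstrapError,
    ContractError,
    ExtrapolationError,
    rcs_basis,
)
from tests.conftest import make_exact_periods


# --------------------------------------------------------------------------- #
# spline basis
# --------------------------------------------------------------------------- #

def test_rcs_linear_beyond_boundary_knots():
    knots = np.array([1.0, 3.0, 6.0, 9.0])
    x = np.array([10.0, 11.0, 12.0, 13.0])
    basis, _ = rcs_basis(x, knots=knots)
    for j in range(basis.shape[1]):
        diffs = np.diff(basis[:, j])
        assert np.allclose(diffs, diffs[0], atol=1e-9)


def test_rcs_falls_back_to_linear_with_few_knots():
    basis, knots = rcs_basis(np.array([1.0, 1.0, 2.0]), knots=np.array([1.0, 2.0]))
    assert basis.shape[1] == 1


def test_spline_spec_validation():
    from ttemu import ConfigurationError

    with pytest.raises(ConfigurationError):
        SplineSpec(n_knots=2, knot_quantiles=(0.1, 0.9)).validate()


# --------------------------------------------------------------------------- #
# pooled logistic closed forms
# --------------------------------------------------------------------------- #

def test_constant_hazard_fit_equals_weighted_event_fraction():
    from ttemu.hazard_estimation import fitted_hazards

    per = make_exact_periods(h1=0.04, h0=0.04, n1=500, n0=500, K=1)
    model = fit_pooled_logistic(per, weights=per["weight"].to_numpy())
    assert fitted_hazards(model, 0, 1)[0] == pytest.approx(0.04, abs=1e-7)
    assert fitted_hazards(model, 1, 1)[0] == pytest.approx(0.04, abs=1e-7)


def test_two_arm_exact_odds_ratio():
    h1, h0 = 0.02, 0.025
    per = make_exact_periods(h1, h0, n1=10_000, n0=10_000, K=3)
    model = fit_pooled_logistic(per, weights=per["weight"].to_numpy())
    target = (h1 / (1 - h1)) / (h0 / (1 - h0))
    assert hazard_ratio(model) == pytest.approx(target, abs=1e-6)


def test_integer_weights_equal_physically_duplicated_rows():
    rng = np.random.default_rng(21)
    n = 1500
    per = pd.DataFrame(
        {
            "entry_id": np.arange(n),
            "arm": rng.integers(0, 2, n),
            "k": rng.integers(1, 6, n).astype(float),
            "event": (rng.random(n) < 0.05).astype(float),
        }
    )
    w = rng.integers(1, 4, n)
    dup = per.loc[per.index.repeat(w)].reset_index(drop=True)
    m_w = fit_pooled_logistic(per, weights=w.astype(float))
    m_dup = fit_pooled_logistic(dup, knots=m_w.knots)
    assert np.allclose(m_w.params.to_numpy(), m_dup.params.to_numpy(), atol=1e-8)


def test_refit_reproduces_deviance():
    per = make_exact_periods(0.03, 0.04, 2000, 2000, K=4)
    a = fit_pooled_logistic(per, weights=per["weight"].to_numpy())
    b = fit_pooled_logistic(per, weights=per["weight"].to_numpy())
    assert a.deviance == pytest.approx(b.deviance, rel=1e-10)


# --------------------------------------------------------------------------- #
# cumulative incidence
# --------------------------------------------------------------------------- #

def _constant_hazard_model(lam=0.1, K=10):
    per = make_exact_periods(lam, lam, 1000, 1000, K=K)
    return fit_pooled_logistic(per, weights=per["weight"].to_numpy())


def test_cumulative_incidence_closed_form():
    model = _constant_hazard_model(lam=0.1, K=10)
    curve = cumulative_incidence(model, arm=1, horizon_k=10)
    assert curve[-1] == pytest.approx(1 - 0.9 ** 10, abs=1e-6)
    assert np.all(np.diff(curve) > 0) and np.all((curve >= 0) & (curve <= 1))


def test_equal_hazards_give_zero_risk_difference():
    model = _constant_hazard_model()
    assert risk_difference(model, 10) == pytest.approx(0.0, abs=1e-9)


def test_extrapolation_beyond_fitted_range_rejected():
    model = _constant_hazard_model(K=5)
    with pytest.raises(ExtrapolationError):
        cumulative_incidence(model, 1, 6)


def test_fitted_curves_monotone_on_simulated_cohort(small_prep):
    r = small_prep.estimate(include_curves=True)
    for c in (r["curve1"], r["curve0"]):
        assert np.all(np.diff(c) >= 0)
        assert c[0] >= 0 and c[-1] <= 1


def test_interaction_model_has_no_single_hr():
    rng = np.random.default_rng(22)
    n = 4000
    per = pd.DataFrame(
        {
            "entry_id": np.arange(n),
            "arm": rng.integers(0, 2, n),
            "k": rng.integers(1, 8, n).astype(float),
            "event": (rng.random(n) < 0.08).astype(float),
        }
    )
    model = fit_pooled_logistic(per, interaction=True)
    with pytest.raises(ContractError):
        hazard_ratio(model)
    assert hazard_ratio(model, at_interval=3) > 0


# --------------------------------------------------------------------------- #
# crude vs continuous-time proportional hazards
# --------------------------------------------------------------------------- #

def _survival_periods(n, lam0, hr, horizon=10, seed=31, delta_years=1.0):
    """Continuous exponential survival discretized into person-periods."""
    rng = np.random.default_rng(seed)
    arm = (np.arange(n) % 2).astype(float)
    lam = lam0 * np.where(arm == 1, hr, 1.0)
    t = rng.exponential(1.0 / lam)
    obs = np.minimum(t, horizon)
    event = (t < horizon).astype(int)
    K = int(round(horizon / delta_years))
    k_end = np.minimum(np.ceil(obs / delta_years).astype(int), K)
    k_end = np.maximum(k_end, 1)
    rep = np.repeat(np.arange(n), k_end)
    starts = np.concatenate([[0], np.cumsum(k_end)[:-1]])
    k = np.arange(len(rep)) - starts[rep] + 1
    last = k == k_end[rep]
    return pd.DataFrame(
        {
            "entry_id": rep,
            "person_id": rep,
            "arm": arm[rep].astype(int),
            "k": k.astype(float),
            "event": (last & (event[rep] == 1)).astype(int),
            "censored": (last & (event[rep] == 0)).astype(int),
        }
    ), t, event, arm


def test_crude_pooled_logistic_close_to_cox_in_rare_event_regime():
    per, t, event, arm = _survival_periods(6000, lam0=0.02, hr=0.8)
    crude = crude_estimates(per)
    cox = cox_crude_hr(per)
    assert crude["crude_hr"] == pytest.approx(cox, rel=0.02)


def test_discrete_hazard_ratio_approaches_continuous_as_intervals_shrink():
    # same continuous survival data, annual (hazard ~0.02) vs monthly
    # (~0.002) discretization: the finer grid must sit closer to the
    # continuous-time Cox estimate
    from lifelines import CoxPHFitter

    per_y, t, event, arm = _survival_periods(8000, lam0=0.02, hr=0.8, seed=33)
    per_m, _, _, _ = _survival_periods(
        8000, lam0=0.02, hr=0.8, seed=33, delta_years=1 / 12
    )
    df = pd.DataFrame({"t": np.minimum(t, 10.0), "e": event, "arm": arm})
    cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
    cox = float(np.exp(cph.params_["arm"]))
    or_y = crude_estimates(per_y)["crude_hr"]
    or_m = crude_estimates(per_m)["crude_hr"]
    assert abs(or_m - cox) < abs(or_y - cox) + 1e-6
    assert or_m == pytest.approx(cox, rel=0.005)


# --------------------------------------------------------------------------- #
# bootstrap
# --------------------------------------------------------------------------- #

def test_bootstrap_degenerate_identical_persons_zero_width():
    def pipeline(mult):
        return 0.9, -0.01

    res = bootstrap_cis(pipeline, np.arange(50), BootstrapSpec(n_reps=20, seed=1))
    assert res.hr_ci[0] == res.hr_ci[1] == 0.9
    assert res.rd_ci == (-0.01, -0.01)


def test_bootstrap_deterministic_given_seed(small_prep):
    spec = BootstrapSpec(n_reps=8, seed=4)
    pipe = small_prep.bootstrap_pipeline()
    a = bootstrap_cis(pipe, small_prep.person_ids, spec)
    b = bootstrap_cis(pipe, small_prep.person_ids, spec)
    assert a.hr_ci == b.hr_ci and a.rd_ci == b.rd_ci


def test_bootstrap_failure_threshold():
    from ttemu._glm import EstimationError

    def bad_pipeline(mult):
        raise EstimationError("synthetic failure")

    with pytest.raises(BootstrapError):
        bootstrap_cis(bad_pipeline, np.arange(10), BootstrapSpec(n_reps=10, seed=2))


def test_bootstrap_spec_validation():
    from ttemu import ConfigurationError

    with pytest.raises(ConfigurationError):
        BootstrapSpec(n_reps=1).validate()


def test_bootstrap_interval_coverage_under_the_null():
    """Repeated small experiments with true HR 1: the percentile interval
    should cover 1 at roughly its nominal rate (binomial tolerance)."""
    from ttemu import RunConfig, SimConfig, generate_population
    from ttemu.pipeline import prepare_cohort

    rc = RunConfig.reference()
    covered = 0
    for exp in range(10):
        cfg = SimConfig(n_persons=2000, seed=500 + exp, log_hr_treatment=0.0)
        prep = prepare_cohort(generate_population(cfg), rc)
        boot = bootstrap_cis(
            prep.bootstrap_pipeline(), prep.person_ids,
            BootstrapSpec(n_reps=60, seed=500 + exp),
        )
        covered += boot.hr_ci[0] <= 1.0 <= boot.hr_ci[1]
    assert covered >= 7
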