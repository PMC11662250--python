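"""Propensity fitting, stabilized weights, standardized mean differences and
censoring weights."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ttemu import (
    balance_report,
    fit_propensity,
    ipcw_weights,
    smd,
    smd_from_samples,
    stabilized_weights,
)
from ttemu._glm import EstimationError


def _cov(df_dict):
    return pd.DataFrame(df_dict)


# --------------------------------------------------------------------------- #
# propensity
# --------------------------------------------------------------------------- #

def test_known_odds_ratio_recovered_exactly():
    # saturated single-binary design with arm odds 1:2 at x=0 and 1:1 at x=1
    # (odds ratio exactly 2) -> MLE coefficient is exactly ln 2
    x = np.repeat([0, 0, 1, 1], [2000, 4000, 1500, 1500])
    arm = np.concatenate([np.ones(2000), np.zeros(4000), np.ones(1500), np.zeros(1500)])
    model = fit_propensity(_cov({"x": x.astype(float)}), arm)
    assert model.coefficients["x"] == pytest.approx(np.log(2), abs=1e-6)


def test_independent_covariate_gets_near_zero_coefficient():
    rng = np.random.default_rng(8)
    n = 8000
    cov = _cov({"z": rng.normal(size=n)})
    arm = (rng.random(n) < 0.3).astype(float)
    model = fit_propensity(cov, arm)
    # SE of the slope is ~ 1/sqrt(n p (1-p)); allow 3 SE
    se = 1.0 / np.sqrt(n * 0.3 * 0.7)
    assert abs(model.coefficients["z"]) < 3 * se


def test_intercept_only_model_fits_arm_fraction():
    arm = np.array([1, 0, 0, 0, 1, 0, 0, 0, 0, 0], dtype=float)
    model = fit_propensity(pd.DataFrame(index=range(10)), arm)
    assert np.allclose(model.fitted, 0.2, atol=1e-8)


def test_single_arm_input_raises():
    with pytest.raises(EstimationError, match="arms"):
        fit_propensity(_cov({"x": [1.0, 2.0, 3.0]}), np.ones(3))


def test_constant_column_dropped_with_warning():
    rng = np.random.default_rng(9)
    cov = _cov({"x": rng.normal(size=200), "c": np.full(200, 3.0)})
    arm = (rng.random(200) < 0.5).astype(float)
    with pytest.warns(UserWarning, match="constant"):
        model = fit_propensity(cov, arm)
    assert "c" not in model.coefficients.index


# --------------------------------------------------------------------------- #
# stabilized weights
# --------------------------------------------------------------------------- #

def _entries(arm, fy=None):
    n = len(arm)
    return pd.DataFrame(
        {
            "entry_id": np.arange(n),
            "arm": np.asarray(arm),
            "trial_fy": np.full(n, 2010) if fy is None else np.asarray(fy),
        }
    )


class _FakeModel:
    def __init__(self, fitted):
        self.fitted = np.asarray(fitted, dtype=float)


def test_uninformative_covariates_give_unit_weights():
    arm = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
    ws = stabilized_weights(_FakeModel(np.full(10, 0.2)), _entries(arm))
    assert np.allclose(ws.sw, 1.0)


def test_weight_formula_direct_example():
    # entry with a=1, fiscal-year arm fraction 0.3, e(L)=0.6 -> sw = 0.5
    arm = np.array([1] * 3 + [0] * 7)
    ps = np.full(10, 0.3, dtype=float)
    ps[0] = 0.6
    ws = stabilized_weights(_FakeModel(ps), _entries(arm))
    assert ws.sw[0] == pytest.approx(0.5)


def test_stratified_weight_means_near_one(small_prep):
    r = small_prep.estimate(crude=False)
    entries = small_prep.entries
    df = pd.DataFrame(
        {"sw": r["sw"], "arm": entries["arm"], "fy": entries["trial_fy"]}
    )
    means = df.groupby(["fy", "arm"])["sw"].agg(["mean", "size"])
    # the mean-one identity is an expectation; check strata large enough for
    # the 0.05 tolerance to be meaningful
    big = means[means["size"] >= 200]
    assert len(big) >= 8
    assert (np.abs(big["mean"] - 1.0) < 0.05).all()


def test_separation_in_observed_arm_raises():
    from ttemu.ipw import WeightError

    arm = np.array([1, 0, 0, 0])
    ps = np.array([0.0, 0.2, 0.2, 0.2])
    with pytest.raises(WeightError, match="separation"):
        stabilized_weights(_FakeModel(ps), _entries(arm))


# --------------------------------------------------------------------------- #
# standardized mean differences
# --------------------------------------------------------------------------- #

def test_smd_binary_printed_examples():
    assert round(smd(0.627, 0.820), 2) == 0.44
    assert round(smd(0.580, 0.262), 2) == 0.68


def test_smd_identical_groups_zero():
    assert smd(0.5, 0.5) == 0.0
    assert smd((3.0, 2.0), (3.0, 2.0), kind="continuous") == 0.0


@given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
def test_smd_symmetric_in_groups(p1, p0):
    assert smd(p1, p0) == pytest.approx(smd(p0, p1))
    assert smd(p1, p0) >= 0


def test_smd_zero_variance_nonzero_difference_is_infinite():
    with pytest.warns(UserWarning, match="zero pooled variance"):
        assert smd(0.0, 1.0) == np.inf


def test_weighted_smd_reduces_to_unweighted_with_unit_weights():
    rng = np.random.default_rng(12)
    x1, x0 = rng.normal(1, 1, 200), rng.normal(0, 1, 300)
    a = smd_from_samples(x1, x0)
    b = smd_from_samples(x1, x0, w1=np.ones(200), w0=np.ones(300))
    assert a == pytest.approx(b)


def test_balance_report_identity_weights(small_prep):
    cov = small_prep.covariates.reset_index(drop=True)
    rep = balance_report(cov, small_prep.arm_entry, np.ones(len(cov)))
    assert np.allclose(rep.table["smd_unweighted"], rep.table["smd_weighted"])


def test_weighting_improves_balance_of_strong_confounders(small_prep):
    r = small_prep.estimate(crude=False)
    cov = small_prep.covariates.reset_index(drop=True)
    rep = balance_report(cov, small_prep.arm_entry, r["sw"])
    t = rep.table.set_index("covariate")
    # employment is the dominant uptake driver in the generator
    assert t.loc["employed", "smd_unweighted"] > 0.3
    assert t.loc["employed", "smd_weighted"] < t.loc["employed", "smd_unweighted"]


# --------------------------------------------------------------------------- #
# censoring weights
# --------------------------------------------------------------------------- #

def _pp_frame(n_entries, k_dev, K=5, seed=0):
    """Non-SHC person-period table with deviation at k_dev[i] (inf = none)."""
    rows = []
    for i in range(n_entries):
        kd = k_dev[i]
        for k in range(1, K + 1):
            if k > kd:
                break
            rows.append((i, i, 0, k, 0, int(k == K and k < kd),
                         int(k < kd), 0))
    return pd.DataFrame(
        rows,
        columns=["entry_id", "person_id", "arm", "k", "event", "censored",
                 "still_in_non_shc_protocol", "cumulative_shc_sessions"],
    )


def test_perfect_adherence_gives_unit_weights():
    pp = _pp_frame(20, [np.inf] * 20)
    cov = pd.DataFrame({"x": np.zeros(20)}, index=np.arange(20))
    out = ipcw_weights(pp, cov)
    assert np.allclose(out["ipcw"], 1.0)
    assert len(out) == len(pp)


def test_covariate_independent_censoring_weights_near_one():
    rng = np.random.default_rng(13)
    n = 3000
    K = 5
    # geometric deviation with constant probability, independent of x
    kd = rng.geometric(0.2, n).astype(float)
    kd[kd > K] = np.inf
    pp = _pp_frame(n, kd, K=K)
    cov = pd.DataFrame({"x": rng.normal(size=n)}, index=np.arange(n))
    out = ipcw_weights(pp, cov)
    w = out["ipcw"].to_numpy()
    assert abs(w.mean() - 1.0) < 0.02
    assert np.all((w > 0.7) & (w < 1.4))


def test_deviation_interval_removed_from_risk_set():
    pp = _pp_frame(4, [2, np.inf, 3, np.inf], K=4)
    cov = pd.DataFrame({"x": np.zeros(4)}, index=np.arange(4))
    out = ipcw_weights(pp, cov)
    kept = out.groupby("entry_id")["k"].max()
    assert kept.loc[0] == 1 and kept.loc[2] == 2  # censored before deviation
    assert kept.loc[1] == 4 and kept.loc[3] == 4


def test_ipcw_recovers_true_hazard_under_informative_censoring():
    """Artificial censoring driven by a high-risk covariate depletes the risk
    set; the stabilized censoring weights restore the population hazard."""

    rng = np.random.default_rng(44)
    n, K = 40_000, 4
    x = (rng.random(n) < 0.5).astype(float)
    lam = 0.03 + 0.05 * x          # true per-interval event probability
    dev_p = 0.35 * x               # only x=1 entries ever deviate
    rows = []
    for i in range(n):
        for k in range(1, K + 1):
            deviates = rng.random() < dev_p[i]
            if deviates:
                rows.append((i, i, 0, k, 0, 0, 0, 0))
                break
            event = rng.random() < lam[i]
            rows.append((i, i, 0, k, int(event), 0, 1, 0))
            if event:
                break
    pp = pd.DataFrame(
        rows,
        columns=["entry_id", "person_id", "arm", "k", "event", "censored",
                 "still_in_non_shc_protocol", "cumulative_shc_sessions"],
    )
    cov = pd.DataFrame({"x": x}, index=np.arange(n))
    out = ipcw_weights(pp, cov)
    last = out[out["k"] == K]
    # population hazard at k=4 among the event-free (no artificial
    # censoring): survival to k weights the x-mixture
    s1, s0 = (1 - 0.08) ** (K - 1), (1 - 0.03) ** (K - 1)
    truth = (0.5 * s1 * 0.08 + 0.5 * s0 * 0.03) / (0.5 * s1 + 0.5 * s0)
    naive = last["event"].mean()
    weighted = np.average(last["event"], weights=last["ipcw"])
    assert abs(weighted - truth) < 0.004
    assert naive < truth - 0.006  # depleted risk set underestimates the hazard
    assert abs(weighted - truth) < abs(naive - truth)


def test_per_protocol_weighting_corrects_in_bias_direction():
    """Pipeline-level: when deviation is driven by a high-risk condition, the
    unweighted per-protocol estimate overstates the HR and the censoring
    weights pull it back toward the always-vs-never oracle."""

    from ttemu import RunConfig, SimConfig, generate_population, ground_truth
    from ttemu.config import ConfounderSpec
    from ttemu.pipeline import prepare_cohort

    conf = (
        ConfounderSpec("health_anxious", "J30", 0.35, 2.2, 1.2, 0.3),
        ConfounderSpec("upper_resp_infection", "J06", 0.42, 0.0, 0.25, 0.25),
        ConfounderSpec("refraction_disorder", "H52", 0.40, 0.0, 0.20, 0.30),
    )
    cfg = SimConfig(
        n_persons=30_000, seed=41, confounder_spec=conf,
        uptake_female=0.0, uptake_employed=0.0, uptake_age_per_decade=0.0,
        uptake_intercept=-3.2,
    )
    rc = RunConfig.reference(per_protocol=True, horizon_years=5)
    db = generate_population(cfg)
    prep_pp = prepare_cohort(db, rc)
    hr_pp = prep_pp.estimate()["hr"]
    prep_naive = prepare_cohort(db, rc)
    prep_naive.ipcw = None
    hr_naive = prep_naive.estimate()["hr"]
    oracle = ground_truth(cfg, n_mc=50_000, seed=441, horizon_years=5)
    assert hr_naive - hr_pp > 0.02  # correction direction and size
    assert abs(hr_pp - oracle.true_marginal_hr) < 0.1
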