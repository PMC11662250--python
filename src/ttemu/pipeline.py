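"""End-to-end orchestration: simulate-or-load, emulate, weight, estimate,
audit — plus the prepared-cohort fast path the bootstrap loops over.

The bootstrap resamples unique persons with replacement and must rebuild
weights and models per replicate.  ``PreparedCohort`` freezes everything that
does not change under resampling (trial entries, covariate design, person-
period rows, spline knots) and re-estimates via per-person frequency weights,
which is mathematically identical to physically replicating each resampled
person's rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._glm import fit_logit, prune_design, sigmoid
from .config import (
    BootstrapSpec,
    OutcomeDefinition,
    RunConfig,
    SplineSpec,
)
from .hazard_estimation import (
    BootstrapResult,
    EstimateResult,
    _hazard_design,
    bootstrap_cis,
    rcs_knots,
)
from .ipw import balance_report, build_design
from .synthetic_claims import ClaimsDB, generate_population
from .trial_emulation import (
    DBIndex,
    baseline_covariates,
    build_sequential_cohort,
    cohort_summary,
    expand_person_periods,
)

logger = logging.getLogger("ttemu")


def _weighted_percentile(x: np.ndarray, w: np.ndarray, pcts) -> np.ndarray:
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cw = np.cumsum(ws)
    if cw[-1] <= 0:
        return np.percentile(x, pcts)
    grid = (cw - 0.5 * ws) / cw[-1]
    return np.interp(np.asarray(pcts) / 100.0, grid, xs)


def _segmented_cumprod(values: np.ndarray, segment_ids: np.ndarray) -> np.ndarray:
    """Cumulative product within runs of equal consecutive segment_ids."""
    logv = np.log(np.maximum(values, 1e-300))
    cs = np.cumsum(logv)
    is_start = np.diff(segment_ids, prepend=segment_ids[0] - 1) != 0
    seg_no = np.cumsum(is_start) - 1
    starts = np.flatnonzero(is_start)
    base = np.where(starts > 0, cs[np.maximum(starts - 1, 0)], 0.0)
    return np.exp(cs - base[seg_no])


@dataclass
class _IPCWParts:
    """Frozen censoring-model matrices for per-protocol bootstrap refits."""

    Xden: np.ndarray
    Xnum: np.ndarray
    y: np.ndarray  # 1 = remained in non-SHC protocol at this interval
    model_row_pos: np.ndarray  # kept-period positions receiving the weights
    entry_ids: np.ndarray  # entry ids of model rows (sorted runs)
    model_is_kept: np.ndarray | None = None  # model rows with k < k_dev
    model_person: np.ndarray | None = None  # dense person index per model row


@dataclass
class PreparedCohort:
    """Everything frozen before weighting/estimation; see module docstring."""

    entries: pd.DataFrame
    covariates: pd.DataFrame
    periods: pd.DataFrame
    X_prop: np.ndarray
    prop_info: object
    person_ids: np.ndarray  # unique cohort persons
    entry_person: np.ndarray  # dense person index per entry
    period_person: np.ndarray
    period_entry_row: np.ndarray  # row index into entries per period
    fy_codes: np.ndarray  # dense fy index per entry
    n_fy: int
    arm_entry: np.ndarray
    X_haz: np.ndarray
    haz_names: list[str]
    knots: np.ndarray
    y_event: np.ndarray
    horizon_k: int
    interaction: bool
    dose: bool
    truncate_pct: float | None = None
    per_trial_propensity: bool = False
    ipcw: _IPCWParts | None = None
    _beta_prop0: np.ndarray | None = None
    _beta_haz0: np.ndarray | None = None
    _ci_designs: tuple | None = field(default=None, repr=False)

    # ------------------------------------------------------------------ #
    def _sw(self, ps: np.ndarray, w_entry: np.ndarray) -> np.ndarray:
        arm = self.arm_entry
        s1 = np.bincount(self.fy_codes, weights=w_entry * arm, minlength=self.n_fy)
        s = np.bincount(self.fy_codes, weights=w_entry, minlength=self.n_fy)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac1 = np.where(s > 0, s1 / s, 0.5)
        num = np.where(arm == 1, frac1[self.fy_codes], 1.0 - frac1[self.fy_codes])
        den = np.where(arm == 1, ps, 1.0 - ps)
        sw = num / np.clip(den, 1e-12, None)
        if self.truncate_pct is not None:
            lo, hi = _weighted_percentile(
                sw, w_entry, [self.truncate_pct, 100.0 - self.truncate_pct]
            )
            sw = np.clip(sw, lo, hi)
        return sw

    def _ipcw_weights(self, mult: np.ndarray | None) -> np.ndarray:
        p = self.ipcw
        out = np.ones(len(self.periods))
        if p is None or len(p.y) == 0 or p.y.min() == 1.0:
            return out
        wm = np.ones(len(p.y)) if mult is None else mult[p.model_person]
        den = fit_logit(p.Xden, p.y, weights=wm).fitted
        num = fit_logit(p.Xnum, p.y, weights=wm).fitted
        cum = _segmented_cumprod(num / den, p.entry_ids)
        out[p.model_row_pos] = cum[p.model_is_kept]
        return out

    def estimate(
        self,
        mult: np.ndarray | None = None,
        include_curves: bool = False,
        crude: bool = True,
    ):
        """Point estimates for the (possibly resampled) cohort.

        ``mult[i]`` is the bootstrap multiplicity of ``person_ids[i]``; None
        means the original sample.  Returns a dict with hr, rd, crude_hr and
        (optionally) the standardized cumulative-incidence curves.
        """

        w_entry = (
            np.ones(len(self.entries)) if mult is None else mult[self.entry_person]
        )
        w_period_base = (
            np.ones(len(self.periods)) if mult is None else mult[self.period_person]
        )
        if self.per_trial_propensity:
            ps = np.empty(len(self.entries))
            for f in range(self.n_fy):
                rows = np.flatnonzero(self.fy_codes == f)
                fit_f = fit_logit(
                    self.X_prop[rows], self.arm_entry[rows], weights=w_entry[rows]
                )
                ps[rows] = fit_f.fitted
            pf = fit_f  # diagnostics from the last trial's fit
            pf.fitted = ps
        else:
            pf = fit_logit(
                self.X_prop,
                self.arm_entry,
                weights=w_entry,
                start=self._beta_prop0,
            )
            if mult is None:
                self._beta_prop0 = pf.params
        sw = self._sw(pf.fitted, w_entry)
        w = sw[self.period_entry_row] * w_period_base
        if self.ipcw is not None:
            w = w * self._ipcw_weights(mult)
        hf = fit_logit(self.X_haz, self.y_event, weights=w, start=self._beta_haz0)
        if mult is None:
            self._beta_haz0 = hf.params
        hr = float(np.exp(hf.params[1]))
        c1, c0 = self._curves(hf.params)
        rd = float(c1[-1] - c0[-1])
        out = {"hr": hr, "rd": rd, "ps": pf.fitted, "sw": sw,
               "haz_params": hf.params, "prop_fit": pf}
        if crude:
            cf = fit_logit(self.X_haz, self.y_event, weights=w_period_base,
                           start=self._beta_haz0)
            out["crude_hr"] = float(np.exp(cf.params[1]))
            if include_curves:
                cc1, cc0 = self._curves(cf.params)
                out["crude_curve1"], out["crude_curve0"] = cc1, cc0
        if include_curves:
            out["curve1"], out["curve0"] = c1, c0
        return out

    def _curves(self, params: np.ndarray):
        if self._ci_designs is None:
            kv = np.arange(1, self.horizon_k + 1, dtype=np.float64)
            X1, _ = _hazard_design(kv, np.ones_like(kv), self.knots,
                                   self.interaction, None)
            X0, _ = _hazard_design(kv, np.zeros_like(kv), self.knots,
                                   self.interaction, None)
            self._ci_designs = (X1, X0)
        X1, X0 = self._ci_designs
        p = params[: X1.shape[1]]  # dose column, if any, excluded from curves
        lam1 = sigmoid(X1 @ p)
        lam0 = sigmoid(X0 @ p)
        return 1.0 - np.cumprod(1.0 - lam1), 1.0 - np.cumprod(1.0 - lam0)

    def bootstrap_pipeline(self):
        def pipe(mult: np.ndarray):
            r = self.estimate(mult=mult, crude=False)
            return r["hr"], r["rd"]

        return pipe


# --------------------------------------------------------------------------- #
# preparation
# --------------------------------------------------------------------------- #

def _entry_fy_range(db: ClaimsDB, config: RunConfig) -> list[int]:
    from ._dates import fiscal_year_of, to_days

    if len(db.checkups):
        fys = db.checkups["fiscal_year"].to_numpy()
        lo, hi = int(fys.min()), int(fys.max())
    elif len(db.persons):
        d0 = to_days(db.persons["enroll_start"].to_numpy()).min()
        d1 = to_days(db.persons["enroll_end"].to_numpy()).max()
        lo, hi = int(fiscal_year_of([d0])[0]), int(fiscal_year_of([d1])[0])
    else:
        return []
    if config["entry_fy_min"] is not None:
        lo = max(lo, int(config["entry_fy_min"]))
    if config["entry_fy_max"] is not None:
        hi = min(hi, int(config["entry_fy_max"]))
    return list(range(lo, hi + 1))


def prepare_cohort(
    db: ClaimsDB,
    config: RunConfig,
    outcome_name: str | None = None,
    seed: int | None = None,
) -> PreparedCohort:
    idx = DBIndex(db)
    criteria = config.criteria()
    outdef = config.outcome_definition(outcome_name)
    if outdef.name == "negative_control":
        criteria = criteria.replace(extra_exclusion_diag=outdef.diagnosis_codes)
    seed = config["seed"] if seed is None else seed

    entries = build_sequential_cohort(
        idx,
        _entry_fy_range(db, config),
        criteria,
        interval=config["interval"],
        monthly_nonshc_fraction=(
            config["monthly_nonshc_fraction"] if config["interval"] == "month" else None
        ),
        subsample_seed=seed,
    )
    logger.info("cohort: %s", cohort_summary(entries))
    logger.info("attrition: %s", entries.attrs.get("attrition"))
    cov = baseline_covariates(
        idx, entries, prevalence_floor=config["prevalence_floor"],
        lookback_days=config["lookback_days"],
    )
    cov.index = entries["entry_id"].to_numpy()
    periods = expand_person_periods(
        entries, idx, outdef, interval=config["interval"],
        horizon_years=config["horizon_years"],
    )
    logger.info("person-periods: %d rows, %d events",
                len(periods), int(periods["event"].sum()))

    X_raw, names = build_design(cov.reset_index(drop=True))
    X_prop, names, info = prune_design(X_raw, names)

    ipcw_parts = None
    if config["per_protocol"]:
        periods, ipcw_parts = _prepare_per_protocol(periods, cov, entries)

    person_ids, entry_person = np.unique(
        entries["person_id"].to_numpy(), return_inverse=True
    )
    period_person = entry_person[
        pd.Index(entries["entry_id"]).get_indexer(periods["entry_id"].to_numpy())
    ]
    period_entry_row = pd.Index(entries["entry_id"]).get_indexer(
        periods["entry_id"].to_numpy()
    )
    fy_vals, fy_codes = np.unique(entries["trial_fy"].to_numpy(), return_inverse=True)
    if ipcw_parts is not None:
        rows = pd.Index(entries["entry_id"]).get_indexer(ipcw_parts.entry_ids)
        ipcw_parts.model_person = entry_person[rows]

    spline = SplineSpec(n_knots=config["n_knots"]).validate()
    kvals = periods["k"].to_numpy(dtype=np.float64)
    knots = rcs_knots(kvals, spline)
    dose_vals = (
        periods["cumulative_shc_sessions"].to_numpy(dtype=np.float64)
        if config["dose"]
        else None
    )
    X_haz, haz_names = _hazard_design(
        kvals, periods["arm"].to_numpy(dtype=np.float64), knots,
        config["interaction"], dose_vals,
    )
    K_full = config["horizon_years"] * (12 if config["interval"] == "month" else 1)
    horizon_k = int(min(K_full, periods["k"].max() if len(periods) else 1))

    return PreparedCohort(
        entries=entries,
        covariates=cov,
        periods=periods,
        X_prop=X_prop,
        prop_info=info,
        person_ids=person_ids,
        entry_person=entry_person,
        period_person=period_person,
        period_entry_row=period_entry_row,
        fy_codes=fy_codes,
        n_fy=len(fy_vals),
        arm_entry=entries["arm"].to_numpy(dtype=np.float64),
        X_haz=X_haz,
        haz_names=haz_names,
        knots=knots,
        y_event=periods["event"].to_numpy(dtype=np.float64),
        horizon_k=horizon_k,
        interaction=bool(config["interaction"]),
        dose=bool(config["dose"]),
        truncate_pct=config["truncate_pct"],
        per_trial_propensity=config["propensity_pooling"] == "per_trial",
        ipcw=ipcw_parts,
    )


def _prepare_per_protocol(periods: pd.DataFrame, cov: pd.DataFrame, entries):
    """Per-protocol risk set and frozen censoring-model matrices.

    A non-SHC entry whose person first receives an SHC checkup in interval
    ``k_dev`` is censored at the *start* of that interval: it contributes
    outcome periods ``1..k_dev-1`` only.  The censoring model is fitted on
    periods ``1..k_dev`` (response: remained in protocol at that interval),
    and the stabilized cumulative weight for a kept outcome period k is
    ``prod_{j<=k} P_num(uncensored at j) / P_den(uncensored at j)``.
    """

    from .hazard_estimation import rcs_basis

    nonshc = periods["arm"].to_numpy() == 0
    dev_now = nonshc & (periods["still_in_non_shc_protocol"].to_numpy() == 0)
    if not dev_now.any():
        return periods.reset_index(drop=True), None
    first_dev = periods.loc[dev_now].groupby("entry_id")["k"].min()
    k_dev = periods["entry_id"].map(first_dev).fillna(np.inf).to_numpy()
    kk = periods["k"].to_numpy()

    # censoring model: non-SHC periods up to and including the deviation
    cmask = nonshc & (kk <= k_dev)
    y = (kk[cmask] < k_dev[cmask]).astype(np.float64)
    km = kk[cmask].astype(np.float64)
    basis, _ = rcs_basis(km)
    row_ix = pd.Index(cov.index).get_indexer(periods["entry_id"].to_numpy()[cmask])
    Xcov, names = build_design(cov.iloc[row_ix])
    Xden = np.column_stack([Xcov, basis])
    Xden, _, _ = prune_design(Xden, names + [f"t{j}" for j in range(basis.shape[1])])
    Xnum = np.ascontiguousarray(np.column_stack([np.ones(int(cmask.sum())), basis]))

    # outcome risk set: drop deviation interval and everything after it
    keep = ~(nonshc & (kk >= k_dev))
    pp = periods[keep].copy()
    last_kept = pp.groupby("entry_id")["k"].transform("max")
    newly_cens = (
        (pp["arm"].to_numpy() == 0)
        & (pp["k"].to_numpy() == last_kept.to_numpy())
        & (pp["event"].to_numpy() == 0)
    )
    pp.loc[newly_cens, "censored"] = 1
    pp = pp.reset_index(drop=True)

    # map censoring-model rows (k < k_dev) onto kept outcome rows: the kept
    # non-SHC periods of a deviating-or-not entry are exactly its model rows
    # with k < k_dev, in the same order
    model_entry = periods["entry_id"].to_numpy()[cmask]
    model_is_kept = kk[cmask] < k_dev[cmask]
    kept_nonshc_pos = np.flatnonzero(pp["arm"].to_numpy() == 0)
    assert model_is_kept.sum() == len(kept_nonshc_pos)
    parts = _IPCWParts(
        Xden=Xden,
        Xnum=Xnum,
        y=y,
        model_row_pos=kept_nonshc_pos,
        entry_ids=model_entry,
    )
    parts.model_is_kept = model_is_kept
    return pp, parts


# --------------------------------------------------------------------------- #
# single pipeline run
# --------------------------------------------------------------------------- #

def run_pipeline(
    db: ClaimsDB,
    config: RunConfig,
    outcome_name: str | None = None,
    seed: int | None = None,
    prepared: PreparedCohort | None = None,
) -> EstimateResult:
    """Emulate, weight and estimate for one outcome; bootstrap CIs when
    ``config['bootstrap_reps'] > 0``."""

    prep = prepared or prepare_cohort(db, config, outcome_name, seed=seed)
    point = prep.estimate(include_curves=True)
    bal = balance_report(prep.covariates.reset_index(drop=True),
                         prep.arm_entry, point["sw"])
    hr_ci = rd_ci = None
    n_failed = 0
    if config["bootstrap_reps"] > 0:
        spec = BootstrapSpec(
            n_reps=int(config["bootstrap_reps"]),
            seed=config["seed"] if seed is None else seed,
        )
        boot: BootstrapResult = bootstrap_cis(
            prep.bootstrap_pipeline(), prep.person_ids, spec
        )
        hr_ci, rd_ci = boot.hr_ci, boot.rd_ci
        n_failed = boot.n_failed
    summary = cohort_summary(prep.entries)
    result = EstimateResult(
        hr_point=point["hr"],
        hr_ci=hr_ci,
        rd_at_horizon=point["rd"],
        rd_ci=rd_ci,
        curve1=point["curve1"],
        curve0=point["curve0"],
        crude_hr=point["crude_hr"],
        diagnostics={
            "cohort": summary,
            "attrition": prep.entries.attrs.get("attrition"),
            "n_person_periods": int(len(prep.periods)),
            "n_events": int(prep.periods["event"].sum()),
            "weights": {
                "sw_mean": float(np.mean(point["sw"])),
                "sw_max": float(np.max(point["sw"])),
            },
            "balance_all_under_0.1": bool(bal.all_balanced),
            "max_weighted_smd": float(bal.table["smd_weighted"].max())
            if len(bal.table)
            else None,
            "propensity_converged": bool(point["prop_fit"].converged),
            "propensity_separation": bool(point["prop_fit"].separation),
            "bootstrap_failures": n_failed,
            "outcome": (outcome_name or config["outcome"]),
        },
    )
    result.diagnostics["balance_table"] = bal.table
    return result


# --------------------------------------------------------------------------- #
# full artifact run with file outputs
# --------------------------------------------------------------------------- #

def run_emulation(config: RunConfig, out_dir=None) -> dict:
    """simulate-or-load -> emulate -> weights -> estimate -> (bias audit),
    writing every stage's outputs plus the resolved config and a run log."""

    import yaml

    out = Path(out_dir or config["out_dir"] or "ttemu_out")
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        if config["db_dir"]:
            logger.info("loading claims database from %s", config["db_dir"])
            db = ClaimsDB.read_csv(config["db_dir"])
        else:
            sim_cfg = config.sim_config()
            logger.info("simulating claims database (n=%d, seed=%d)",
                        sim_cfg.n_persons, sim_cfg.seed)
            db = generate_population(sim_cfg)
        logger.info(
            "db: %d persons, %d claims, %d checkups",
            len(db.persons), len(db.claims), len(db.checkups),
        )
        prep = prepare_cohort(db, config)
        result = run_pipeline(db, config, prepared=prep)

        prep.entries.drop(columns=["_pos"], errors="ignore").to_csv(
            out / "trial_entries.csv", index=False
        )
        prep.periods.to_csv(out / "person_periods.csv", index=False)
        point = prep.estimate(include_curves=True)
        pd.DataFrame(
            {"entry_id": prep.entries["entry_id"], "ps": point["ps"],
             "sw": point["sw"]}
        ).to_csv(out / "weights.csv", index=False)
        bal = result.diagnostics.pop("balance_table")
        bal.to_csv(out / "balance.csv", index=False)
        curves = pd.DataFrame(
            {
                "interval": np.tile(np.arange(1, prep.horizon_k + 1), 2),
                "arm": np.repeat(["SHC", "non-SHC"], prep.horizon_k),
                "cumulative_incidence": np.concatenate(
                    [result.curve1, result.curve0]
                ),
            }
        )
        curves.to_csv(out / "curves.csv", index=False)

        from .reports import baseline_table

        baseline_table(prep.entries, db).to_csv(out / "baseline_table.csv", index=False)

        bundle = {"results": result.to_dict(), "config": config.to_dict(),
                  "seed": config["seed"]}
        if config["run_bias_audit"]:
            from .bias_audit import bias_audit, negative_control_run

            nc = negative_control_run(db, config)
            audit = bias_audit(
                result.hr_point, nc.hr_point, result.hr_ci, nc.hr_ci,
                outcome_rare=config["outcome_rare"],
            )
            bundle["bias_audit"] = audit.to_dict()
            bundle["negative_control"] = nc.to_dict()
            bundle["negative_control"]["diagnostics"].pop("balance_table", None)
            (out / "bias_audit.json").write_text(
                json.dumps(bundle["bias_audit"], indent=2)
            )
        (out / "results.json").write_text(
            json.dumps(_strip_unjsonable(bundle), indent=2, sort_keys=True)
        )
        with open(out / "effective_config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh)
        logger.info("run complete: hr=%.4f rd=%.4f", result.hr_point,
                    result.rd_at_horizon)
        return bundle
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        logger.error("pipeline failed: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _strip_unjsonable(obj):
    if isinstance(obj, dict):
        return {k: _strip_unjsonable(v) for k, v in obj.items()
                if not isinstance(v, pd.DataFrame)}
    if isinstance(obj, (list, tuple)):
        return [_strip_unjsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
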