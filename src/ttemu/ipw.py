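"""Propensity model, stabilized inverse-probability-of-treatment weights,
per-protocol censoring weights, and covariate-balance diagnostics.

The propensity model is a single pooled logistic regression of arm on the
baseline covariates across all nested trials (fiscal year of entry enters as
a categorical covariate).  Stabilized weights use the within-fiscal-year arm
fraction as numerator, so the weight mean is ~1 inside every arm-by-year
stratum and extreme weights are damped without truncation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._glm import DesignInfo, EstimationError, LogitFit, fit_logit, prune_design


class WeightError(RuntimeError):
    pass


# --------------------------------------------------------------------------- #
# design matrix construction
# --------------------------------------------------------------------------- #

def build_design(covariates: pd.DataFrame, columns: list[str] | None = None):
    """Expand a covariate table into a numeric design matrix with intercept.

    Categorical/object columns are dummy-encoded dropping the first level.
    When ``columns`` is given (a frozen recipe from a previous fit), exactly
    those columns are reproduced, with zeros for levels absent in the data.
    """

    parts = {"const": np.ones(len(covariates))}
    for name in covariates.columns:
        col = covariates[name]
        if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
            cats = pd.Categorical(col)
            for lev in cats.categories[1:]:
                parts[f"{name}[{lev}]"] = (cats == lev).astype(np.float64)
        else:
            parts[name] = col.to_numpy(dtype=np.float64)
    if columns is not None:
        X = np.column_stack(
            [parts.get(c, np.zeros(len(covariates))) for c in columns]
        )
        return np.ascontiguousarray(X), list(columns)
    names = list(parts)
    return np.ascontiguousarray(np.column_stack(list(parts.values()))), names


@dataclass
class PropensityModel:
    """Fitted treatment-assignment model with a frozen design recipe."""

    coefficients: pd.Series
    fitted: np.ndarray
    design_info: DesignInfo
    converged: bool
    n_iter: int
    max_score: float
    separation: bool
    ridge_used: float
    arm: np.ndarray = field(repr=False, default=None)

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        X, _ = build_design(covariates, columns=self.design_info.columns)
        from ._glm import sigmoid

        return sigmoid(X @ self.coefficients.to_numpy())


def fit_propensity(
    covariates: pd.DataFrame,
    arm,
    freq_weights: np.ndarray | None = None,
    design: tuple | None = None,
    start: np.ndarray | None = None,
) -> PropensityModel:
    """Maximum-likelihood logistic fit of arm on the baseline covariates.

    Constant and collinear columns are dropped with a warning; if the plain
    MLE fails (separation-driven singularities), the fit is retried with a
    ridge penalty of 1e-6 and flagged.  ``design``/``start`` let bootstrap
    replicates reuse the frozen design and warm-start the solver.
    """

    arm = np.asarray(arm, dtype=np.float64)
    w = np.ones(len(arm)) if freq_weights is None else np.asarray(freq_weights, float)
    n1 = float(np.sum(w * arm))
    n0 = float(np.sum(w * (1 - arm)))
    if n1 == 0 or n0 == 0:
        raise EstimationError(
            f"propensity fit needs both arms; got weighted counts SHC={n1:g}, "
            f"non-SHC={n0:g}"
        )
    if design is None:
        X_raw, names = build_design(covariates)
        X, names, info = prune_design(X_raw, names)
        if info.dropped_constant or info.dropped_collinear:
            warnings.warn(
                "dropped propensity columns: "
                f"constant={info.dropped_constant}, collinear={info.dropped_collinear}",
                stacklevel=2,
            )
    else:
        X, info = design
        names = info.columns
    fit: LogitFit = fit_logit(X, arm, weights=w, start=start)
    return PropensityModel(
        coefficients=pd.Series(fit.params, index=names),
        fitted=fit.fitted,
        design_info=info,
        converged=fit.converged,
        n_iter=fit.n_iter,
        max_score=fit.max_score,
        separation=fit.separation,
        ridge_used=fit.ridge,
        arm=arm,
    )


# --------------------------------------------------------------------------- #
# stabilized weights
# --------------------------------------------------------------------------- #

@dataclass
class WeightSet:
    """Per-entry propensity scores and stabilized weights."""

    entry_id: np.ndarray
    ps: np.ndarray
    sw: np.ndarray
    summary: dict

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"entry_id": self.entry_id, "ps": self.ps, "sw": self.sw})


def stabilized_weights(
    model: PropensityModel,
    entries: pd.DataFrame,
    truncate_pct: float | None = None,
    freq_weights: np.ndarray | None = None,
) -> WeightSet:
    """sw_i = P(A=a_i | trial_fy_i) / P(A=a_i | L_i).

    The numerator is the (frequency-weighted) arm fraction within the entry's
    fiscal year; the denominator is the fitted propensity.  Optional symmetric
    percentile truncation; none by default, matching reliance on
    stabilization alone.
    """

    arm = entries["arm"].to_numpy(dtype=np.float64)
    ps = np.asarray(model.fitted, dtype=np.float64)
    if len(ps) != len(entries):
        raise WeightError("model was not fitted on these entries")
    bad = ((arm == 1) & (ps <= 0)) | ((arm == 0) & (ps >= 1))
    if np.any(bad):
        raise WeightError(
            f"{int(bad.sum())} entries have fitted probability 0/1 for their "
            "observed arm (separation)"
        )
    w = np.ones(len(entries)) if freq_weights is None else np.asarray(freq_weights, float)
    fy = entries["trial_fy"].to_numpy()
    num = np.empty(len(entries))
    for f in np.unique(fy):
        m = fy == f
        frac1 = np.average(arm[m], weights=w[m])
        num[m] = np.where(arm[m] == 1, frac1, 1.0 - frac1)
    den = np.where(arm == 1, ps, 1.0 - ps)
    sw = num / den
    if truncate_pct is not None:
        lo, hi = np.percentile(sw, [truncate_pct, 100 - truncate_pct])
        sw = np.clip(sw, lo, hi)
    summary = {
        "mean": float(np.average(sw, weights=w)),
        "max": float(sw.max()) if len(sw) else float("nan"),
        "p01": float(np.percentile(sw, 1)) if len(sw) else float("nan"),
        "p99": float(np.percentile(sw, 99)) if len(sw) else float("nan"),
    }
    return WeightSet(
        entry_id=entries["entry_id"].to_numpy(), ps=ps, sw=sw, summary=summary
    )


# --------------------------------------------------------------------------- #
# standardized mean differences
# --------------------------------------------------------------------------- #

def smd(group1, group0, kind: str = "binary") -> float:
    """Absolute standardized mean difference.

    binary: ``group1``/``group0`` are proportions p1, p0 and the pooled
    binary variance (p1(1-p1)+p0(1-p0))/2 is used.  continuous: each group is
    a (mean, variance) pair.  A zero pooled variance with a nonzero
    difference is reported as infinity with a warning.
    """

    if kind == "binary":
        p1, p0 = float(group1), float(group0)
        if not (0 <= p1 <= 1 and 0 <= p0 <= 1):
            raise ValueError("binary smd needs proportions in [0, 1]")
        diff = abs(p1 - p0)
        pooled = (p1 * (1 - p1) + p0 * (1 - p0)) / 2.0
    elif kind == "continuous":
        (m1, v1), (m0, v0) = group1, group0
        diff = abs(m1 - m0)
        pooled = (v1 + v0) / 2.0
    else:
        raise ValueError(f"unknown smd kind {kind!r}")
    if pooled <= 0:
        if diff == 0:
            return 0.0
        warnings.warn("zero pooled variance with nonzero difference", stacklevel=2)
        return float("inf")
    return diff / float(np.sqrt(pooled))


def _wmean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    m = float(np.average(x, weights=w))
    v = float(np.average((x - m) ** 2, weights=w))
    return m, v


def smd_from_samples(x1, x0, kind: str = "continuous", w1=None, w0=None) -> float:
    x1 = np.asarray(x1, float)
    x0 = np.asarray(x0, float)
    w1 = np.ones(len(x1)) if w1 is None else np.asarray(w1, float)
    w0 = np.ones(len(x0)) if w0 is None else np.asarray(w0, float)
    if kind == "binary":
        return smd(np.average(x1, weights=w1), np.average(x0, weights=w0), "binary")
    return smd(_wmean_var(x1, w1), _wmean_var(x0, w0), "continuous")


@dataclass
class BalanceReport:
    table: pd.DataFrame  # covariate, smd_unweighted, smd_weighted, flagged

    @property
    def all_balanced(self) -> bool:
        return bool((self.table["smd_weighted"] < 0.1).all())


def balance_report(
    covariates: pd.DataFrame, arm, weights: WeightSet | np.ndarray
) -> BalanceReport:
    """Unweighted and IPW-weighted SMD for every design column."""

    arm = np.asarray(arm)
    sw = weights.sw if isinstance(weights, WeightSet) else np.asarray(weights, float)
    X, names = build_design(covariates)
    rows = []
    for j, name in enumerate(names):
        if name == "const":
            continue
        col = X[:, j]
        binary = set(np.unique(col)).issubset({0.0, 1.0})
        kind = "binary" if binary else "continuous"
        s_un = smd_from_samples(col[arm == 1], col[arm == 0], kind)
        s_w = smd_from_samples(
            col[arm == 1], col[arm == 0], kind, w1=sw[arm == 1], w0=sw[arm == 0]
        )
        rows.append((name, s_un, s_w, s_w >= 0.1))
    table = pd.DataFrame(
        rows, columns=["covariate", "smd_unweighted", "smd_weighted", "flagged"]
    )
    return BalanceReport(table=table)


# --------------------------------------------------------------------------- #
# inverse probability of censoring weights (per-protocol)
# --------------------------------------------------------------------------- #

def ipcw_weights(
    person_periods: pd.DataFrame,
    covariates: pd.DataFrame,
    spline_basis_fn=None,
) -> pd.DataFrame:
    """Stabilized cumulative censoring weights for the per-protocol analysis.

    A non-SHC entry whose person first receives an SHC checkup in interval
    ``k_dev`` is artificially censored at the start of that interval: its
    outcome periods are ``1..k_dev-1``.  A pooled logistic model of
    remaining-in-protocol per interval (fitted on periods ``1..k_dev``) on
    baseline covariates plus a spline of interval index provides the
    denominator; an intercept+spline-only model the numerator; the weight of
    a kept period k is the cumulative product of their ratio over intervals
    ``1..k``.  SHC-arm periods keep weight 1.

    ``covariates`` has one row per entry, indexed by entry_id.  Returns the
    per-protocol risk set with an ``ipcw`` column.
    """

    from .hazard_estimation import rcs_basis

    pp = person_periods
    nonshc = pp["arm"].to_numpy() == 0
    dev_now = nonshc & (pp["still_in_non_shc_protocol"].to_numpy() == 0)
    kk = pp["k"].to_numpy()
    if not dev_now.any():
        out = pp.copy()
        out["ipcw"] = 1.0
        return out.reset_index(drop=True)
    first_dev = pp.loc[dev_now].groupby("entry_id")["k"].min()
    k_dev = pp["entry_id"].map(first_dev).fillna(np.inf).to_numpy()

    cmask = nonshc & (kk <= k_dev)
    y = (kk[cmask] < k_dev[cmask]).astype(np.float64)
    km = kk[cmask].astype(np.float64)
    spline = rcs_basis(km)[0] if spline_basis_fn is None else spline_basis_fn(km)
    row_ix = pd.Index(covariates.index).get_indexer(pp["entry_id"].to_numpy()[cmask])
    if np.any(row_ix < 0):
        raise WeightError("covariates index must contain every entry_id")
    Xcov, names = build_design(covariates.iloc[row_ix])
    Xden = np.column_stack([Xcov, spline])
    Xden, _, _ = prune_design(Xden, names + [f"t{j}" for j in range(spline.shape[1])])
    Xnum = np.column_stack([np.ones(int(cmask.sum())), spline])
    den = fit_logit(Xden, y).fitted
    num = fit_logit(Xnum, y).fitted
    ratio = pd.Series(num / den, index=pp.index[cmask])
    cum = ratio.groupby(pp.loc[cmask, "entry_id"], sort=False).cumprod()

    keep = ~(nonshc & (kk >= k_dev))
    out = pp[keep].copy()
    out["ipcw"] = 1.0
    kept_model = cum.index.intersection(out.index)
    out.loc[kept_model, "ipcw"] = cum.loc[kept_model]
    last_kept = out.groupby("entry_id")["k"].transform("max")
    newly_cens = (
        (out["arm"].to_numpy() == 0)
        & (out["k"].to_numpy() == last_kept.to_numpy())
        & (out["event"].to_numpy() == 0)
    )
    out.loc[newly_cens, "censored"] = 1
    return out.reset_index(drop=True)
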