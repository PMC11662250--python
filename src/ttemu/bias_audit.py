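"""Negative-control outcome run, bias-calibrated hazard ratio, HR-to-RR
conversion for common outcomes, and E-values.

A negative-control outcome (here depression, which checkup participation is
not believed to affect) estimates the residual bias shared with the primary
contrast: its hazard ratio should be 1 under no unmeasured confounding or
selection.  Dividing the primary HR by the negative-control HR gives a
bias-calibrated HR; the E-value then quantifies the minimum strength of
unmeasured confounding (on the risk-ratio scale, with both exposure and
outcome) needed to explain the calibrated association away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


class DomainError(ValueError):
    pass


@dataclass
class CalibratedHR:
    hr: float
    ci: tuple[float, float] | None


def _se_from_ci(lo: float, hi: float) -> float:
    return (math.log(hi) - math.log(lo)) / (2.0 * 1.959963984540054)


def calibrate_hr(
    hr_primary: float,
    hr_nc: float,
    ci_primary: tuple[float, float] | None = None,
    ci_nc: tuple[float, float] | None = None,
) -> CalibratedHR:
    """Bias-calibrated HR = primary HR / negative-control HR.

    The CI combines the two log-scale standard errors (each recovered from
    its 95% CI half-width) as independent:
    ln(point) +/- 1.96 * sqrt(SE_p^2 + SE_nc^2).
    """

    if hr_primary <= 0 or hr_nc <= 0:
        raise DomainError("hazard ratios must be positive")
    point = hr_primary / hr_nc
    ci = None
    if ci_primary is not None and ci_nc is not None:
        for (lo, hi), pt in ((ci_primary, hr_primary), (ci_nc, hr_nc)):
            if not (0 < lo <= pt <= hi):
                raise DomainError(f"CI ({lo}, {hi}) must contain its point {pt}")
        se = math.sqrt(_se_from_ci(*ci_primary) ** 2 + _se_from_ci(*ci_nc) ** 2)
        z = 1.959963984540054
        ci = (point * math.exp(-z * se), point * math.exp(z * se))
    return CalibratedHR(hr=point, ci=ci)


def hr_to_rr_common(hr: float) -> float:
    """Approximate risk ratio for a common (non-rare) outcome:
    RR = (1 - 0.5^sqrt(HR)) / (1 - 0.5^sqrt(1/HR))."""

    if hr <= 0:
        raise DomainError("hr must be positive")
    if hr == 1.0:
        return 1.0
    num = 1.0 - 0.5 ** math.sqrt(hr)
    den = 1.0 - 0.5 ** math.sqrt(1.0 / hr)
    return num / den


def e_value(rr: float) -> float:
    """E-value on the risk-ratio scale: RR* + sqrt(RR*(RR*-1)) with
    RR* = max(rr, 1/rr); equals 1 exactly at the null."""

    if rr <= 0:
        raise DomainError("rr must be positive")
    rr_star = max(rr, 1.0 / rr)
    if rr_star <= 1.0:
        return 1.0
    return rr_star + math.sqrt(rr_star * (rr_star - 1.0))


def e_value_for_ci(rr_lo: float, rr_hi: float) -> float:
    """E-value for the CI limit closest to the null; infinity-marker (inf)
    when the interval crosses 1 (no finite confounder strength excluded)."""

    if rr_lo <= 0 or rr_hi <= 0 or rr_lo > rr_hi:
        raise DomainError("need 0 < rr_lo <= rr_hi")
    if rr_lo <= 1.0 <= rr_hi:
        return math.inf
    bound = rr_hi if rr_hi < 1.0 else rr_lo
    return e_value(bound)


@dataclass
class BiasAuditResult:
    hr_negative_control: float
    nc_ci: tuple[float, float] | None
    hr_calibrated: float
    calibrated_ci: tuple[float, float] | None
    rr_approx: float
    e_value_point: float
    e_value_ci_bound: float  # may be math.inf

    def to_dict(self) -> dict:
        ev_ci = self.e_value_ci_bound
        return {
            "hr_negative_control": self.hr_negative_control,
            "nc_ci": list(self.nc_ci) if self.nc_ci else None,
            "hr_calibrated": self.hr_calibrated,
            "calibrated_ci": list(self.calibrated_ci) if self.calibrated_ci else None,
            "rr_approx": self.rr_approx,
            "e_value_point": self.e_value_point,
            "e_value_ci_bound": None if math.isinf(ev_ci) else ev_ci,
            "e_value_ci_is_infinite": bool(math.isinf(ev_ci)),
        }


def bias_audit(
    hr_primary: float,
    hr_nc: float,
    ci_primary: tuple[float, float] | None = None,
    ci_nc: tuple[float, float] | None = None,
    outcome_rare: bool = False,
) -> BiasAuditResult:
    """Full audit: calibrate, convert HR to RR, compute E-values.

    ``outcome_rare=False`` (default) applies the common-outcome square-root
    conversion before the E-value formula; the rare-outcome shortcut treats
    the HR as an RR directly.
    """

    cal = calibrate_hr(hr_primary, hr_nc, ci_primary, ci_nc)
    conv = (lambda h: h) if outcome_rare else hr_to_rr_common
    rr = conv(cal.hr)
    ev = e_value(rr)
    if cal.ci is not None:
        ev_ci = e_value_for_ci(conv(cal.ci[0]), conv(cal.ci[1]))
    else:
        ev_ci = math.inf
    return BiasAuditResult(
        hr_negative_control=hr_nc,
        nc_ci=ci_nc,
        hr_calibrated=cal.hr,
        calibrated_ci=cal.ci,
        rr_approx=rr,
        e_value_point=ev,
        e_value_ci_bound=ev_ci,
    )


def negative_control_run(db, config, seed: int | None = None):
    """Re-run the full pipeline with the negative-control outcome.

    Adds a baseline exclusion of prevalent negative-control cases and turns
    the drug conjunction off (the depression definition requires no drug).
    Returns an :class:`~ttemu.hazard_estimation.EstimateResult`.
    """

    from .pipeline import run_pipeline

    return run_pipeline(db, config, outcome_name="negative_control", seed=seed)
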