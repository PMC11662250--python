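"""Configuration objects: simulation, eligibility, outcomes, and run config.

The study protocol being emulated: Japan's Specific Health Checkup (SHC), an
annual no-charge checkup offered to everyone aged 40-74, evaluated against the
composite outcome of incident type 2 diabetes or hypertension under an
intention-to-treat contrast with 10-year follow-up.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional


class ConfigurationError(ValueError):
    """Raised when a configuration field is out of its valid range."""


# --------------------------------------------------------------------------- #
# simulation
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class ConfounderSpec:
    """One binary baseline condition that confounds checkup uptake.

    ``code`` is the 3-character ICD-10 code under which the condition appears
    in simulated claims; effects are on the logit scale.
    """

    name: str
    code: str
    prevalence: float
    effect_uptake: float = 0.0
    effect_outcome: float = 0.0
    effect_nc: float = 0.0


def _default_confounders() -> tuple[ConfounderSpec, ...]:
    # benign chronic conditions echoing the most common preexisting illnesses
    # in employee-insurance claims (rhinitis, URI, refraction disorders)
    return (
        ConfounderSpec("allergic_rhinitis", "J30", 0.43, 0.50, 0.30, 0.35),
        ConfounderSpec("upper_resp_infection", "J06", 0.42, 0.35, 0.25, 0.25),
        ConfounderSpec("refraction_disorder", "H52", 0.40, 0.40, 0.20, 0.30),
    )


def _default_background_codes() -> tuple[tuple[str, float], ...]:
    """Pool of benign 3-digit ICD-10 noise codes with person-level prevalences."""
    codes = (
        "J00", "J01", "J02", "J03", "J20", "K21", "K29", "K52", "K59", "L20",
        "L23", "L30", "M25", "M54", "M79", "N30", "H10", "H66", "R05", "R10",
        "R51", "B35", "L70", "J45", "K02", "G43", "M17",
    )
    prevs = [0.30 * (0.82 ** i) + 0.004 for i in range(len(codes))]
    return tuple(zip(codes, prevs))


@dataclass
class SimConfig:
    """Generative model for a synthetic employee-insurance claims database.

    Defaults are the package's reference study conditions: a mid-sized
    employee-insured population observed over fiscal years 2008-2019 for entry
    with administrative end of follow-up in fiscal 2022, checkup uptake
    confounded by age, sex, employment and chronic conditions, and a true
    conditional checkup effect of exp(log_hr_treatment) on the annual
    discrete-time odds of the composite outcome.
    """

    n_persons: int = 50_000
    fy_start: int = 2008
    fy_end: int = 2019
    admin_end_fy: int = 2022
    age_range_at_entry: tuple[int, int] = (30, 74)
    sex_female_prob: float = 0.65
    employed_prob: float = 0.45
    confounder_spec: tuple[ConfounderSpec, ...] = field(
        default_factory=_default_confounders
    )
    unmeasured_effect_uptake: float = 0.0
    unmeasured_effect_outcome: float = 0.0
    unmeasured_effect_nc: float = 0.0

    # uptake model (annual probability of an SHC checkup, logit scale);
    # never_taker_prob adds a share of persons who structurally never
    # participate (a trait affecting uptake only, hence not a confounder);
    # 0 by default so the true assignment probability is exactly logistic in
    # the measured covariates
    never_taker_prob: float = 0.0
    uptake_intercept: float = -3.0
    uptake_age_per_decade: float = -0.25
    uptake_female: float = -1.00
    uptake_employed: float = 2.00
    # optional state dependence: log-odds penalty from the second
    # participation-eligible year onward for people who have never attended
    uptake_repeat_penalty: float = 0.0
    uptake_fy_trend: float = 0.03
    other_checkup_prob: float = 0.02  # pre-40 voluntary checkups, per year

    # outcome model (composite diabetes/hypertension, annual logit scale)
    baseline_annual_outcome_hazard: float = 0.02
    outcome_age_per_decade: float = 0.55
    outcome_female: float = -0.10
    outcome_employed: float = -0.15
    log_hr_treatment: float = math.log(0.9)

    # negative-control outcome (depression codes), never affected by checkup
    baseline_annual_nc_hazard: float = 0.008
    nc_age_per_decade: float = 0.10
    nc_female: float = 0.35
    nc_employed: float = 0.0

    # enrollment / utilization
    annual_disenroll_prob: float = 0.08
    enroll_pre_years: float = 3.0
    visit_rate_per_year: float = 3.0
    hosp_rate_per_year: float = 0.06
    visit_dispersion_sd: float = 0.5  # sd of log-normal person visit multiplier
    background_codes: tuple[tuple[str, float], ...] = field(
        default_factory=_default_background_codes
    )

    seed: int = 0

    def validate(self) -> "SimConfig":
        probs = {
            "sex_female_prob": self.sex_female_prob,
            "employed_prob": self.employed_prob,
            "baseline_annual_outcome_hazard": self.baseline_annual_outcome_hazard,
            "baseline_annual_nc_hazard": self.baseline_annual_nc_hazard,
            "annual_disenroll_prob": self.annual_disenroll_prob,
            "other_checkup_prob": self.other_checkup_prob,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {p!r}")
        for c in self.confounder_spec:
            if not (0.0 <= c.prevalence <= 1.0):
                raise ConfigurationError(
                    f"confounder {c.name!r} prevalence must be in [0, 1]"
                )
        if self.n_persons < 0:
            raise ConfigurationError("n_persons must be >= 0")
        if not (self.fy_start <= self.fy_end <= self.admin_end_fy):
            raise ConfigurationError(
                "require fy_start <= fy_end <= admin_end_fy, got "
                f"{self.fy_start}, {self.fy_end}, {self.admin_end_fy}"
            )
        lo, hi = self.age_range_at_entry
        if lo > hi:
            raise ConfigurationError(f"age_range_at_entry inverted: ({lo}, {hi})")
        return self

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


# --------------------------------------------------------------------------- #
# emulation
# --------------------------------------------------------------------------- #

DIABETES_HISTORY_DIAG = frozenset({"E10", "E14"})
DIABETES_DRUGS = frozenset({"A10"})
HYPERTENSION_HISTORY_DIAG = frozenset({"I10", "I11", "I12", "I13", "I14", "I15"})
HYPERTENSION_DRUGS = frozenset({"C02", "C03", "C07", "C08", "C09"})


@dataclass
class EligibilityCriteria:
    """Trial eligibility screened at each entry date.

    Mirrors the emulated protocol: age 40-74 at entry, >=12 months of data
    lookback with at least one medical visit, no checkup history, no history
    of either component disease (diagnosis plus matching drug class), and
    exclusion of extreme resource users.
    """

    age_min: int = 40
    age_max: int = 74
    lookback_days: int = 365
    min_visits_in_lookback: int = 1
    require_no_prior_checkup: bool = True
    allow_prior_other_checkups: bool = False
    exclusion_code_sets: tuple[tuple[frozenset, frozenset], ...] = (
        (DIABETES_HISTORY_DIAG, DIABETES_DRUGS),
        (HYPERTENSION_HISTORY_DIAG, HYPERTENSION_DRUGS),
    )
    extra_exclusion_diag: frozenset = frozenset()  # e.g. prevalent depression
    resource_use_exclusion_percentile: float = 99.99

    def validate(self) -> "EligibilityCriteria":
        if self.age_min > self.age_max:
            raise ConfigurationError("age_min must be <= age_max")
        if self.lookback_days < 1:
            raise ConfigurationError("lookback_days must be >= 1")
        return self

    def replace(self, **kw) -> "EligibilityCriteria":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class OutcomeComponent:
    diagnosis_codes: frozenset
    drug_codes: frozenset = frozenset()
    require_drug: bool = True


@dataclass(frozen=True)
class OutcomeDefinition:
    """Claims-based outcome: diagnosis code plus (optionally) a dispensing of a
    matching drug class within ``conjunction_window_days`` of the diagnosis."""

    name: str
    components: tuple[OutcomeComponent, ...]
    conjunction_window_days: int = 90

    def __post_init__(self):
        for c in self.components:
            if not c.diagnosis_codes:
                raise ConfigurationError("diagnosis_codes must be nonempty")

    @property
    def diagnosis_codes(self) -> frozenset:
        out = frozenset()
        for c in self.components:
            out |= c.diagnosis_codes
        return out

    @property
    def drug_codes(self) -> frozenset:
        out = frozenset()
        for c in self.components:
            out |= c.drug_codes
        return out

    @staticmethod
    def preset(
        name: str,
        hypertension_printed_e15: bool = False,
        diabetes_codes: frozenset = frozenset({"E11", "E14"}),
        negative_control_codes: frozenset = frozenset({"F32", "F34", "F35"}),
        conjunction_window_days: int = 90,
    ) -> "OutcomeDefinition":
        # hypertension codes as printed are I10-I13 plus "E15", which is almost
        # certainly a typo for I15 (E15 is hypoglycaemic coma); I15 is default.
        ht = frozenset({"I10", "I11", "I12", "I13"}) | (
            frozenset({"E15"}) if hypertension_printed_e15 else frozenset({"I15"})
        )
        diab = OutcomeComponent(diabetes_codes, DIABETES_DRUGS, True)
        hyp = OutcomeComponent(ht, HYPERTENSION_DRUGS, True)
        nc = OutcomeComponent(negative_control_codes, frozenset(), False)
        presets = {
            "diabetes": (diab,),
            "hypertension": (hyp,),
            "composite": (diab, hyp),
            "negative_control": (nc,),
        }
        if name not in presets:
            raise ConfigurationError(
                f"unknown outcome name {name!r}; choose from {sorted(presets)}"
            )
        return OutcomeDefinition(name, presets[name], conjunction_window_days)


# --------------------------------------------------------------------------- #
# estimation / run
# --------------------------------------------------------------------------- #

@dataclass
class SplineSpec:
    """Restricted cubic spline for the time-since-entry hazard shape."""

    n_knots: int = 4
    knot_quantiles: tuple[float, ...] = (0.05, 0.35, 0.65, 0.95)

    def validate(self) -> "SplineSpec":
        if self.n_knots < 3:
            raise ConfigurationError("restricted cubic spline needs >= 3 knots")
        if len(self.knot_quantiles) != self.n_knots:
            raise ConfigurationError("knot_quantiles length must equal n_knots")
        return self


@dataclass
class BootstrapSpec:
    """Nonparametric bootstrap over unique persons, percentile intervals."""

    n_reps: int = 1000
    seed: int = 0
    ci_level: float = 0.95

    def validate(self) -> "BootstrapSpec":
        if self.n_reps < 2:
            raise ConfigurationError("n_reps must be >= 2")
        return self


_RUN_DEFAULTS = {
    "db_dir": None,
    "out_dir": None,
    "seed": 0,
    # simulation (used when db_dir is None)
    "sim": {},
    # emulation
    "age_max": 74,
    "lookback_days": 365,
    "allow_prior_other_checkups": False,
    "interval": "year",
    "outcome": "composite",
    "hypertension_printed_e15": False,
    "conjunction_window_days": 90,
    "entry_fy_min": None,
    "entry_fy_max": None,
    "per_protocol": False,
    "monthly_nonshc_fraction": 0.1,
    "prevalence_floor": 0.0001,
    # weighting; optional symmetric percentile truncation of the stabilized
    # weights (None = rely on stabilization alone)
    "truncate_pct": None,
    "propensity_pooling": "pooled",  # or "per_trial"
    # estimation
    "n_knots": 4,
    "horizon_years": 10,
    "bootstrap_reps": 0,
    "interaction": False,
    "dose": False,
    # bias audit
    "run_bias_audit": False,
    "outcome_rare": False,
}


@dataclass
class RunConfig:
    """Resolved pipeline configuration; unknown keys are rejected."""

    values: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.values) - set(_RUN_DEFAULTS)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(_RUN_DEFAULTS)
        merged.update(self.values)
        self.values = merged
        if self.values["interval"] not in ("year", "month"):
            raise ConfigurationError("interval must be 'year' or 'month'")

    def __getitem__(self, key):
        return self.values[key]

    def criteria(self) -> EligibilityCriteria:
        return EligibilityCriteria(
            age_max=self.values["age_max"],
            lookback_days=self.values["lookback_days"],
            allow_prior_other_checkups=self.values["allow_prior_other_checkups"],
        ).validate()

    def outcome_definition(self, name: Optional[str] = None) -> OutcomeDefinition:
        return OutcomeDefinition.preset(
            name or self.values["outcome"],
            hypertension_printed_e15=self.values["hypertension_printed_e15"],
            conjunction_window_days=self.values["conjunction_window_days"],
        )

    def sim_config(self) -> SimConfig:
        sim = dict(self.values["sim"] or {})
        if "confounder_spec" in sim:
            sim["confounder_spec"] = tuple(
                ConfounderSpec(**c) if isinstance(c, dict) else c
                for c in sim["confounder_spec"]
            )
        if "age_range_at_entry" in sim:
            sim["age_range_at_entry"] = tuple(sim["age_range_at_entry"])
        cfg = SimConfig(**sim)
        cfg.seed = sim.get("seed", self.values["seed"])
        return cfg.validate()

    @staticmethod
    def reference(**overrides) -> "RunConfig":
        """The reference emulated protocol: annual entries limited to fiscal
        2008-2019 with follow-up through the administrative end (the default
        generator's study window)."""

        values = {"entry_fy_min": 2008, "entry_fy_max": 2019}
        values.update(overrides)
        return RunConfig(values=values)

    @staticmethod
    def from_file(path) -> "RunConfig":
        import json

        import yaml

        with open(path) as fh:
            text = fh.read()
        data = yaml.safe_load(text) if not text.lstrip().startswith("{") else json.loads(text)
        return RunConfig(values=data or {})

    def to_dict(self) -> dict:
        return dict(self.values)
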