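"""Lifetime Markov cohort model of physical activity and chronic disease.

A closed cohort (default 100,000 people aged 59) is followed in annual
cycles to age 88. At the end of the first year each person is either
"active" (>=150 weekly minutes of MVPA in >=10 min bouts) or "inactive";
the interventions raise the probability of being active via an arm-specific
relative risk applied to the usual-care proportion. Active people face
reduced age-specific annual risks of non-fatal coronary heart disease
(CHD), non-fatal stroke and type 2 diabetes (T2D) while the protective
effect persists (configurable duration: 10 years in the base case, 1 or 3
in sensitivity scenarios; relative risks revert to 1 afterwards).

State space (9 states): event-free active, event-free inactive, CHD year-1
(tunnel), CHD post, stroke year-1 (tunnel), stroke post, T2D (chronic),
dead from CVD, dead from other causes. The year-1 tunnel states carry
first-event-year treatment costs; there are no second events (event states
move only to themselves/their post state or death).

Competing risks within a cycle are applied death-first: background
all-cause mortality (plus any post-event excess, attributed to CVD death)
is resolved first, then at most one incident event conditional on
survival. Rows are stochastic by construction, never renormalised; an
implied probability above 1 is rejected naming the offending parameter.

Costs (GBP 2013/14) and QALYs accrue by state occupancy at each cycle and
are discounted at 3.5% a year with the first cycle undiscounted. Model
year-1 costs are the trial-based total costs per person by arm; a second
year of annuitised intervention cost follows. People who become active in
year 1 receive a one-off utility gain. Scenario 3 strips year-1
health-service-use consequences and the psychological gain; scenario 4
additionally adds participant-borne costs.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .econ_metrics import (
    ICERResult,
    IncrementalResult,
    NMBResult,
    discount_stream,
    icer_classify,
    net_monetary_benefit,
)

logger = logging.getLogger(__name__)

__all__ = [
    "STATES",
    "MarkovParameters",
    "CohortTrace",
    "ArmResult",
    "ComparisonResult",
    "load_default_params",
    "build_transition_matrix",
    "apply_scenario",
    "run_cohort",
    "accumulate",
    "compare_arms",
]

STATES = (
    "eventfree_active",
    "eventfree_inactive",
    "chd_year1",
    "chd_post",
    "stroke_year1",
    "stroke_post",
    "t2d",
    "dead_cvd",
    "dead_other",
)
_IX = {s: i for i, s in enumerate(STATES)}
ARMS = ("control", "postal", "nurse")
COMPARISONS = (("postal_vs_control", "postal", "control"),
               ("nurse_vs_control", "nurse", "control"),
               ("nurse_vs_postal", "nurse", "postal"))
SCENARIOS = ("base", "s1", "s2", "s3", "s4")

SCHEMA_VERSION = "pedometer-cea-markov/1"


def _band_lookup(bands: list[dict], age: int, key: str) -> float:
    """Step-function lookup: the last band with from_age <= age applies."""
    val = None
    for band in bands:
        if age >= band["from_age"]:
            val = band[key]
    if val is None:
        raise ValueError(f"no parameter band covers age {age} for {key!r}")
    return float(val)


@dataclass
class MarkovParameters:
    """All inputs of the lifetime decision model.

    Age-indexed quantities are step functions over age bands
    (``from_age`` keyed dicts). All probabilities are annual. The shipped
    default file contains synthetic placeholder values for the disease
    epidemiology, state costs and state utilities.
    """

    cohort_size: float = 100_000
    start_age: int = 59
    end_age: int = 88
    p_active_control: float = 0.35
    rr_active_by_arm: dict = field(default_factory=lambda: {"control": 1.0, "postal": 1.4, "nurse": 1.35})
    rr_disease_given_active: dict = field(default_factory=lambda: {"chd": 0.73, "stroke": 0.75, "t2d": 0.67})
    effect_duration_years: int = 10
    incidence_bands: list = field(default_factory=list)  # from_age, chd, stroke, t2d (inactive)
    mortality_bands: list = field(default_factory=list)  # from_age, all_cause, cvd_fraction
    excess_mortality: dict = field(default_factory=dict)  # state -> added annual death prob
    state_costs: dict = field(default_factory=dict)  # chd_first, chd_subsequent, ... (GBP/year)
    state_utilities: dict = field(default_factory=dict)  # event_free, chd, stroke, t2d
    one_off_utility_gain: float = 0.01
    year1_cost_per_person: dict = field(default_factory=dict)  # trial-based totals by arm
    intervention_cost_year1: dict = field(default_factory=dict)  # intervention-only, by arm
    intervention_cost_year2: dict = field(default_factory=dict)  # annuitised, by arm
    participant_cost_per_person: dict = field(default_factory=dict)
    discount_rate_costs: float = 0.035
    discount_rate_qalys: float = 0.035
    include_year1_hsu_costs: bool = True
    include_psych_benefit: bool = True
    include_participant_costs: bool = False
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.p_active_control <= 1:
            raise ValueError("p_active_control must lie in [0, 1]")
        if self.end_age <= self.start_age:
            raise ValueError("end_age must exceed start_age")
        for name, rr in {**self.rr_active_by_arm, **self.rr_disease_given_active}.items():
            if rr <= 0:
                raise ValueError(f"relative risk {name!r} must be positive, got {rr}")
        for state, u in self.state_utilities.items():
            if u > 1:
                raise ValueError(f"utility for {state!r} exceeds 1")
        if self.incidence_bands:
            ages = [b["from_age"] for b in self.incidence_bands]
            if ages != sorted(ages):
                raise ValueError("incidence band ages must be ascending")

    @property
    def n_cycles(self) -> int:
        return self.end_age - self.start_age + 1

    def incidence(self, age: int, condition: str) -> float:
        return _band_lookup(self.incidence_bands, age, condition)

    def mortality(self, age: int) -> tuple[float, float]:
        q = _band_lookup(self.mortality_bands, age, "all_cause")
        f = _band_lookup(self.mortality_bands, age, "cvd_fraction")
        return q, f

    def copy(self) -> "MarkovParameters":
        return copy.deepcopy(self)

    def to_yaml(self, path) -> None:
        payload = {"schema": SCHEMA_VERSION, **asdict(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MarkovParameters":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "MarkovParameters":
        raw = dict(raw)
        schema = raw.pop("schema", SCHEMA_VERSION)
        if schema != SCHEMA_VERSION:
            raise ValueError(f"unsupported parameter schema {schema!r} (expected {SCHEMA_VERSION})")
        return cls(**raw)


def load_default_params() -> MarkovParameters:
    """Load the packaged default parameter file (synthetic placeholders)."""
    ref = resources.files("pedometer_cea").joinpath("data/synthetic_markov_params.yaml")
    with ref.open() as fh:
        return MarkovParameters.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------


def build_transition_matrix(
    params: MarkovParameters, age: int, rr_applies: bool = True
) -> np.ndarray:
    """Annual transition matrix at one age.

    ``rr_applies`` controls whether the active rows still enjoy the
    protective relative risks (the effect-duration rule). Dead states are
    absorbing; each row sums to 1 by construction.
    """
    if not params.start_age <= age <= params.end_age:
        raise ValueError(f"age {age} outside model range {params.start_age}-{params.end_age}")
    q, cvd_frac = params.mortality(age)
    if not 0 <= q <= 1:
        raise ValueError(f"all_cause mortality at age {age} is {q}, outside [0, 1]")
    q_cvd, q_oth = q * cvd_frac, q * (1 - cvd_frac)
    M = np.zeros((len(STATES), len(STATES)))

    for state, active in (("eventfree_active", True), ("eventfree_inactive", False)):
        p_ev = {}
        for cond in ("chd", "stroke", "t2d"):
            p = params.incidence(age, cond)
            if active and rr_applies:
                p *= params.rr_disease_given_active[cond]
            p_ev[cond] = p
        total_ev = sum(p_ev.values())
        if total_ev > 1:
            raise ValueError(
                f"summed incidence {total_ev:.4f} exceeds 1 at age {age} "
                f"(incidence_bands entry covering this age)"
            )
        i = _IX[state]
        surv = 1.0 - q
        M[i, _IX["chd_year1"]] = surv * p_ev["chd"]
        M[i, _IX["stroke_year1"]] = surv * p_ev["stroke"]
        M[i, _IX["t2d"]] = surv * p_ev["t2d"]
        M[i, i] = surv * (1.0 - total_ev)
        M[i, _IX["dead_cvd"]] = q_cvd
        M[i, _IX["dead_other"]] = q_oth

    chronic = (
        ("chd_year1", "chd_post", "chd_year1"),
        ("chd_post", "chd_post", "chd_post"),
        ("stroke_year1", "stroke_post", "stroke_year1"),
        ("stroke_post", "stroke_post", "stroke_post"),
        ("t2d", "t2d", "t2d"),
    )
    for state, dest, excess_key in chronic:
        excess = float(params.excess_mortality.get(excess_key, 0.0))
        death = q + excess
        if death > 1:
            raise ValueError(
                f"mortality {death:.4f} exceeds 1 at age {age} for state {state!r} "
                f"(excess_mortality[{excess_key!r}] = {excess})"
            )
        i = _IX[state]
        M[i, _IX["dead_cvd"]] = q_cvd + excess  # post-event excess attributed to CVD
        M[i, _IX["dead_other"]] = q_oth
        M[i, _IX[dest]] = 1.0 - death
    M[_IX["dead_cvd"], _IX["dead_cvd"]] = 1.0
    M[_IX["dead_other"], _IX["dead_other"]] = 1.0

    rowsum = M.sum(axis=1)
    if np.max(np.abs(rowsum - 1.0)) > 1e-12:
        raise AssertionError("transition rows do not sum to 1")
    return M


def apply_scenario(params: MarkovParameters, scenario: str = "base") -> MarkovParameters:
    """Return a copy of the parameters configured for one scenario.

    base: 10-year persistence of the protective relative risks.
    s1 / s2: persistence for 1 / 3 years only.
    s3: base persistence, but model year-1 costs reduced to intervention
        costs only (no trial health-service-use consequences) and no
        psychological one-off utility gain.
    s4: s3 plus participant-borne costs.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    p = params.copy()
    p.effect_duration_years = {"base": 10, "s1": 1, "s2": 3, "s3": 10, "s4": 10}[scenario]
    if scenario in ("s3", "s4"):
        p.include_year1_hsu_costs = False
        p.include_psych_benefit = False
    if scenario == "s4":
        p.include_participant_costs = True
    return p


@dataclass
class CohortTrace:
    """State occupancy per annual cycle for one arm.

    Row t (0-based) is the occupancy during model year t+1 (ages
    ``start_age + t``); each row sums to the cohort size.
    """

    occupancy: np.ndarray  # (n_cycles, n_states)
    arm: str
    cohort_size: float

    def __post_init__(self) -> None:
        sums = self.occupancy.sum(axis=1)
        if np.max(np.abs(sums - self.cohort_size)) > 1e-6:
            raise ValueError("cohort mass not conserved in trace")
        alive = self.occupancy[:, : _IX["dead_cvd"]].sum(axis=1)
        if np.any(np.diff(alive) > 1e-9):
            raise ValueError("alive mass must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "cycle", np.arange(1, len(df) + 1))
        df.insert(1, "arm", self.arm)
        return df


def run_cohort(params: MarkovParameters, arm: str) -> CohortTrace:
    """Propagate the cohort for one arm from start_age to end_age.

    Year 1 splits the cohort into active/inactive using the arm's relative
    risk of achieving the activity target applied to the usual-care
    proportion (capped at 1 with a logged warning). Later years apply the
    age-specific transition matrix, with the protective relative risks
    active only while the effect persists.
    """
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}")
    p_active = params.p_active_control * params.rr_active_by_arm[arm]
    if p_active > 1:
        logger.warning(
            "p_active_control * rr_active_by_arm[%s] = %.3f exceeds 1; capping", arm, p_active
        )
        p_active = 1.0
    n = params.n_cycles
    occ = np.zeros((n, len(STATES)))
    occ[0, _IX["eventfree_active"]] = params.cohort_size * p_active
    occ[0, _IX["eventfree_inactive"]] = params.cohort_size * (1 - p_active)
    for t in range(1, n):
        cycle = t  # transition out of model year `cycle` (1-based)
        age = params.start_age + cycle - 1
        M = build_transition_matrix(params, age, rr_applies=cycle <= params.effect_duration_years)
        occ[t] = occ[t - 1] @ M
    return CohortTrace(occupancy=occ, arm=arm, cohort_size=params.cohort_size)


@dataclass
class ArmResult:
    """Lifetime discounted and undiscounted totals for one arm."""

    arm: str
    cost_discounted: float
    qaly_discounted: float
    cost_undiscounted: float
    qaly_undiscounted: float
    cost_by_state: dict
    qaly_by_state: dict

    def __post_init__(self) -> None:
        tol_c = 1e-9 * max(1.0, abs(self.cost_undiscounted))
        tol_q = 1e-9 * max(1.0, abs(self.qaly_undiscounted))
        if self.cost_discounted > self.cost_undiscounted + tol_c:
            raise ValueError("discounted cost exceeds undiscounted for a non-negative stream")
        if self.qaly_discounted > self.qaly_undiscounted + tol_q:
            raise ValueError("discounted QALYs exceed undiscounted for a non-negative stream")


def _state_cost_vector(params: MarkovParameters) -> np.ndarray:
    c = params.state_costs
    vec = np.zeros(len(STATES))
    vec[_IX["chd_year1"]] = c.get("chd_first", 0.0)
    vec[_IX["chd_post"]] = c.get("chd_subsequent", 0.0)
    vec[_IX["stroke_year1"]] = c.get("stroke_first", 0.0)
    vec[_IX["stroke_post"]] = c.get("stroke_subsequent", 0.0)
    vec[_IX["t2d"]] = c.get("t2d_annual", 0.0)
    return vec


def _state_utility_vector(params: MarkovParameters) -> np.ndarray:
    u = params.state_utilities
    vec = np.zeros(len(STATES))
    vec[_IX["eventfree_active"]] = u.get("event_free", 0.0)
    vec[_IX["eventfree_inactive"]] = u.get("event_free", 0.0)
    vec[_IX["chd_year1"]] = u.get("chd", 0.0)
    vec[_IX["chd_post"]] = u.get("chd", 0.0)
    vec[_IX["stroke_year1"]] = u.get("stroke", 0.0)
    vec[_IX["stroke_post"]] = u.get("stroke", 0.0)
    vec[_IX["t2d"]] = u.get("t2d", 0.0)
    return vec


def accumulate(trace: CohortTrace, params: MarkovParameters) -> ArmResult:
    """Lifetime discounted costs and QALYs from a cohort trace.

    Per-cycle disease costs are occupancy-weighted state costs; model
    year-1 adds the per-person arm cost (trial-based totals, or
    intervention-only when year-1 health-service-use consequences are
    excluded, plus participant costs when included), and year-2 adds the
    annuitised intervention cost for people still alive. The optional
    half-cycle correction averages adjacent occupancies for state accrual.
    """
    arm = trace.arm
    occ = trace.occupancy
    if params.half_cycle_correction:
        shifted = np.vstack([occ[1:], occ[-1:]])
        occ_eff = 0.5 * (occ + shifted)
    else:
        occ_eff = occ
    cvec = _state_cost_vector(params)
    uvec = _state_utility_vector(params)
    cost_stream = occ_eff @ cvec
    qaly_stream = occ_eff @ uvec

    if params.include_year1_hsu_costs:
        year1 = params.year1_cost_per_person.get(arm, 0.0)
    else:
        year1 = params.intervention_cost_year1.get(arm, 0.0)
    if params.include_participant_costs:
        year1 += params.participant_cost_per_person.get(arm, 0.0)
    cost_stream = cost_stream.copy()
    cost_stream[0] += year1 * params.cohort_size
    alive_y2 = occ[1, : _IX["dead_cvd"]].sum() if len(occ) > 1 else 0.0
    cost_stream[1] += params.intervention_cost_year2.get(arm, 0.0) * alive_y2

    if params.include_psych_benefit:
        n_active = occ[0, _IX["eventfree_active"]]
        qaly_stream = qaly_stream.copy()
        qaly_stream[0] += params.one_off_utility_gain * n_active

    cost_by_state = {
        s: float((occ_eff[:, _IX[s]] * cvec[_IX[s]]).sum()) for s in STATES if cvec[_IX[s]]
    }
    qaly_by_state = {
        s: float((occ_eff[:, _IX[s]] * uvec[_IX[s]]).sum()) for s in STATES if uvec[_IX[s]]
    }
    return ArmResult(
        arm=arm,
        cost_discounted=discount_stream(cost_stream, params.discount_rate_costs),
        qaly_discounted=discount_stream(qaly_stream, params.discount_rate_qalys),
        cost_undiscounted=float(cost_stream.sum()),
        qaly_undiscounted=float(qaly_stream.sum()),
        cost_by_state=cost_by_state,
        qaly_by_state=qaly_by_state,
    )


@dataclass
class ComparisonResult:
    """Pairwise incremental result of the lifetime model."""

    comparison: str
    incremental: IncrementalResult
    icer: ICERResult
    nmb: NMBResult


def compare_arms(
    params: MarkovParameters,
    scenario: str = "base",
    wtp: float = 20_000.0,
    arms: tuple = ARMS,
) -> dict:
    """Run the scenario for every arm and form pairwise comparisons.

    Returns ``{"arm_results": {arm: ArmResult}, "comparisons":
    {name: ComparisonResult}}`` with incremental cost/QALYs per cohort,
    ICER classification and net monetary benefit at ``wtp``.
    """
    p = apply_scenario(params, scenario)
    arm_results = {a: accumulate(run_cohort(p, a), p) for a in arms}
    comparisons = {}
    for name, hi, lo in COMPARISONS:
        if hi not in arm_results or lo not in arm_results:
            continue
        inc = IncrementalResult(
            delta_cost=arm_results[hi].cost_discounted - arm_results[lo].cost_discounted,
            delta_effect=arm_results[hi].qaly_discounted - arm_results[lo].qaly_discounted,
            effect_unit="qaly",
            comparison=name,
        )
        comparisons[name] = ComparisonResult(
            comparison=name,
            incremental=inc,
            icer=icer_classify(inc),
            nmb=net_monetary_benefit(inc, wtp),
        )
    return {"arm_results": arm_results, "comparisons": comparisons, "scenario": scenario}
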