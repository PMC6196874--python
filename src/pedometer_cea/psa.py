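"""Probabilistic sensitivity analysis for the lifetime decision model.

Every model parameter except baseline mortality (census-based, treated as
known) is given a sampling distribution matched to its point value:

* probabilities and utilities — beta, method-of-moments from the point
  value and a standard error (default 0.05);
* costs — gamma, coefficient of variation (default 0.2);
* relative risks — lognormal with a log-scale SD (default 0.15), the
  location chosen so the *mean* equals the point value;
* age-indexed incidence — one mean-1 lognormal multiplier per condition,
  scaling the whole age profile coherently rather than drawing each age
  band independently.

The uncertainty magnitudes are placeholders (the source model's standard
errors are not published) and are overridable per parameter. Draws are
propagated through the cohort engine; results are summarised as CEACs via
the shared CEAC constructor and empirical 2.5/97.5 percentile intervals
for incremental cost, QALYs and net monetary benefit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .econ_metrics import CEACCurve, ceac_from_samples, default_wtp_grid
from .markov_engine import ARMS, MarkovParameters, compare_arms

logger = logging.getLogger(__name__)

__all__ = [
    "UncertaintyConfig",
    "Prior",
    "PriorSpec",
    "PSASampleSet",
    "build_priors",
    "draw_samples",
    "run_psa",
    "summarize_psa",
]

MEAN_TOL = 1e-6


@dataclass
class UncertaintyConfig:
    """Default uncertainty magnitudes, overridable per parameter.

    ``overrides`` maps parameter name to either a (family, spread) pair or
    "fixed"; spread is the SE for beta, the CV for gamma, the log-SD for
    lognormal.
    """

    cv_cost: float = 0.2
    se_prob: float = 0.05
    log_sd_rr: float = 0.15
    overrides: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Prior:
    """One parameter's sampling distribution (mean equals the point value)."""

    name: str
    family: str  # beta | gamma | lognormal | fixed
    point: float
    a: float = 0.0  # alpha / shape / mu
    b: float = 0.0  # beta / scale / sigma

    def mean(self) -> float:
        if self.family == "fixed":
            return self.point
        if self.family == "beta":
            return self.a / (self.a + self.b)
        if self.family == "gamma":
            return self.a * self.b
        return float(np.exp(self.a + self.b**2 / 2.0))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "fixed":
            return np.full(size, self.point)
        if self.family == "beta":
            return rng.beta(self.a, self.b, size)
        if self.family == "gamma":
            return rng.gamma(self.a, self.b, size)
        return rng.lognormal(self.a, self.b, size)


def _beta_prior(name: str, m: float, se: float) -> Prior:
    if se == 0 or m == 0 or m == 1:
        return Prior(name, "fixed", m)
    if se**2 >= m * (1 - m):
        raise ValueError(
            f"invalid beta hyperparameters for {name!r}: se {se} too large for mean {m}"
        )
    nu = m * (1 - m) / se**2 - 1.0
    return Prior(name, "beta", m, a=m * nu, b=(1 - m) * nu)


def _gamma_prior(name: str, m: float, cv: float) -> Prior:
    if m == 0 or cv == 0:
        return Prior(name, "fixed", m)
    if m < 0:
        raise ValueError(f"invalid gamma hyperparameters for {name!r}: negative mean {m}")
    shape = 1.0 / cv**2
    return Prior(name, "gamma", m, a=shape, b=m / shape)


def _lognormal_prior(name: str, m: float, log_sd: float) -> Prior:
    if m <= 0:
        raise ValueError(f"invalid lognormal hyperparameters for {name!r}: mean {m} must be > 0")
    if log_sd == 0:
        return Prior(name, "fixed", m)
    return Prior(name, "lognormal", m, a=float(np.log(m) - log_sd**2 / 2.0), b=log_sd)


@dataclass
class PriorSpec:
    """The full set of parameter priors; mortality is always fixed."""

    priors: dict  # name -> Prior

    def __post_init__(self) -> None:
        for name, pr in self.priors.items():
            if abs(pr.mean() - pr.point) > MEAN_TOL * max(1.0, abs(pr.point)):
                raise ValueError(f"prior for {name!r} does not centre on its point value")
        for name, pr in self.priors.items():
            if name.startswith("mortality") and pr.family != "fixed":
                raise ValueError("baseline mortality must stay fixed in the PSA")


def build_priors(
    params: MarkovParameters, uncertainty: UncertaintyConfig = UncertaintyConfig()
) -> PriorSpec:
    """Assign a distribution family to every sampled model parameter."""
    u = uncertainty
    priors: dict[str, Prior] = {}

    def add(name, default_builder, *args):
        ov = u.overrides.get(name)
        if ov == "fixed":
            priors[name] = Prior(name, "fixed", args[0])
            return
        if ov is not None:
            family, spread = ov
            builder = {"beta": _beta_prior, "gamma": _gamma_prior, "lognormal": _lognormal_prior}[family]
            priors[name] = builder(name, args[0], spread)
            return
        priors[name] = default_builder(name, *args)

    add("p_active_control", _beta_prior, params.p_active_control, u.se_prob)
    for arm in ("postal", "nurse"):
        add(f"rr_active.{arm}", _lognormal_prior, params.rr_active_by_arm[arm], u.log_sd_rr)
    for cond in ("chd", "stroke", "t2d"):
        add(f"rr_disease.{cond}", _lognormal_prior, params.rr_disease_given_active[cond], u.log_sd_rr)
        add(f"incidence_mult.{cond}", _lognormal_prior, 1.0, u.log_sd_rr)
    for state, val in params.excess_mortality.items():
        add(f"excess_mortality.{state}", _beta_prior, val, min(u.se_prob, 0.5 * np.sqrt(val * (1 - val))))
    for key, val in params.state_costs.items():
        add(f"state_costs.{key}", _gamma_prior, val, u.cv_cost)
    for key, val in params.state_utilities.items():
        add(f"state_utilities.{key}", _beta_prior, val, u.se_prob)
    add("one_off_utility_gain", _beta_prior, params.one_off_utility_gain,
        min(u.se_prob, 0.5 * np.sqrt(params.one_off_utility_gain * (1 - params.one_off_utility_gain))))
    for arm in ARMS:
        add(f"year1_cost.{arm}", _gamma_prior, params.year1_cost_per_person.get(arm, 0.0), u.cv_cost)
        add(f"intervention_cost_year1.{arm}", _gamma_prior,
            params.intervention_cost_year1.get(arm, 0.0), u.cv_cost)
        add(f"intervention_cost_year2.{arm}", _gamma_prior,
            params.intervention_cost_year2.get(arm, 0.0), u.cv_cost)
        add(f"participant_cost.{arm}", _gamma_prior,
            params.participant_cost_per_person.get(arm, 0.0), u.cv_cost)
    # census-based mortality: explicit fixed entries, never sampled
    for i, band in enumerate(params.mortality_bands):
        priors[f"mortality.band{i}"] = Prior(f"mortality.band{i}", "fixed", band["all_cause"])
    return PriorSpec(priors=priors)


@dataclass
class PSASampleSet:
    """Monte Carlo parameter draws (rows) for the sampled parameters."""

    samples: pd.DataFrame
    seed: int

    def __len__(self) -> int:
        return len(self.samples)


def draw_samples(priors: PriorSpec, n: int, seed: int = 0) -> PSASampleSet:
    """Independent draws per parameter; reproducible by seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols = {name: pr.sample(rng, n) for name, pr in priors.priors.items()}
    return PSASampleSet(samples=pd.DataFrame(cols), seed=seed)


def _apply_draw(base: MarkovParameters, row: pd.Series) -> MarkovParameters:
    p = base.copy()
    for name, val in row.items():
        group, _, key = name.partition(".")
        val = float(val)
        if group == "p_active_control":
            p.p_active_control = min(val, 1.0)
        elif group == "rr_active":
            p.rr_active_by_arm[key] = val
        elif group == "rr_disease":
            p.rr_disease_given_active[key] = val
        elif group == "incidence_mult":
            for band in p.incidence_bands:
                band[key] = band[key] * val
        elif group == "excess_mortality":
            p.excess_mortality[key] = val
        elif group == "state_costs":
            p.state_costs[key] = val
        elif group == "state_utilities":
            p.state_utilities[key] = min(val, 1.0)
        elif group == "one_off_utility_gain":
            p.one_off_utility_gain = val
        elif group == "year1_cost":
            p.year1_cost_per_person[key] = val
        elif group == "intervention_cost_year1":
            p.intervention_cost_year1[key] = val
        elif group == "intervention_cost_year2":
            p.intervention_cost_year2[key] = val
        elif group == "participant_cost":
            p.participant_cost_per_person[key] = val
        elif group == "mortality":
            pass  # fixed by construction
        else:
            raise ValueError(f"unknown sampled parameter {name!r}")
    return p


def run_psa(
    samples: PSASampleSet,
    base_params: MarkovParameters,
    scenario: str = "base",
    wtp: float = 20_000.0,
) -> pd.DataFrame:
    """Propagate every draw through the cohort engine.

    Returns a tidy frame (draw, comparison, delta_cost, delta_qaly, nmb);
    draws where the engine rejects the parameter set are skipped and
    logged, with the skip count attached as frame metadata.
    """
    records = []
    n_failed = 0
    for i, row in samples.samples.iterrows():
        try:
            res = compare_arms(_apply_draw(base_params, row), scenario=scenario, wtp=wtp)
        except ValueError as exc:
            n_failed += 1
            logger.warning("PSA draw %d skipped: %s", i, exc)
            continue
        for comp, cr in res["comparisons"].items():
            records.append(
                {
                    "draw": i,
                    "comparison": comp,
                    "delta_cost": cr.incremental.delta_cost,
                    "delta_qaly": cr.incremental.delta_effect,
                    "nmb": cr.nmb.nmb,
                }
            )
    out = pd.DataFrame.from_records(records)
    out.attrs["n_failed"] = n_failed
    out.attrs["n_requested"] = len(samples)
    if n_failed:
        logger.warning("PSA: %d of %d draws failed and were skipped", n_failed, len(samples))
    return out


def summarize_psa(results: pd.DataFrame, wtp_grid: Optional[np.ndarray] = None) -> dict:
    """CEACs and percentile summaries per comparison.

    Requires at least two successful draws. Intervals are empirical
    2.5/97.5 percentiles of incremental cost, incremental QALYs and NMB.
    """
    if results["draw"].nunique() < 2:
        raise ValueError("need >= 2 PSA draws to summarise")
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    out = {}
    for comp, grp in results.groupby("comparison"):
        pairs = grp[["delta_cost", "delta_qaly"]].to_numpy()
        intervals = {
            col: (float(np.percentile(grp[col], 2.5)), float(np.percentile(grp[col], 97.5)))
            for col in ("delta_cost", "delta_qaly", "nmb")
        }
        out[comp] = {
            "ceac": ceac_from_samples(pairs, grid, comparison=comp),
            "intervals": intervals,
            "means": {col: float(grp[col].mean()) for col in ("delta_cost", "delta_qaly", "nmb")},
        }
    return out
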