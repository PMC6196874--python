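"""Synthetic participant-level trial data with the PACE-UP structure.

Generates three-arm, household-clustered trial datasets whose arm-level
means and spreads default to the published PACE-UP summary tables: EQ-5D
utility indices at baseline, 3 and 12 months; daily step counts and weekly
minutes of MVPA in >=10 min bouts at the same time points; and per-person
cost components (fixed set-up and delivery costs, right-skewed health
service use, participant-borne costs).

Distribution families (chosen to respect support and skew; only means and
SDs are published):

* utilities — truncated normal on (0, 1], with the underlying normal
  moment-matched numerically so the *truncated* mean/SD equal the targets;
* cost components — gamma, matched by moments (zero-SD components are
  exact constants);
* steps and MVPA — lognormal, matched by moments.

Correlation structure uses a Gaussian copula over structured standard
normal scores: a household random intercept (allocation is randomised by
household, so household members share an arm and are positively
correlated), a person-level latent "activity" factor shared between steps
and MVPA, and a person factor linking repeated measures of the same
outcome over time. Margins stay exactly the matched families.

Missingness is applied separately (`apply_missingness`), MCAR per field or
MAR via a logistic model on a covariate, with the pre-deletion values kept
in a truth channel so imputation accuracy can be tested.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from . import published

__all__ = [
    "ArmOutcomeConfig",
    "SyntheticConfig",
    "TrialDataset",
    "generate_trial",
    "apply_missingness",
    "truncnorm_match_moments",
]

MEASURED_FIELDS = (
    "utility_0",
    "utility_3",
    "utility_12",
    "steps_0",
    "steps_3",
    "steps_12",
    "mvpa_0",
    "mvpa_3",
    "mvpa_12",
    "cost_health_service_3",
    "cost_health_service_12",
    "cost_participant_3",
    "cost_participant",
)

COLUMN_DICTIONARY = {
    "pid": "participant id (unique)",
    "hid": "household id; members share an arm",
    "arm": "control | postal | nurse",
    "age": "years at baseline (45-75)",
    "sex": "1 = female",
    "ethnicity_white": "1 = white",
    "disease_count": "number of chronic conditions",
    "has_accelerometry": "1 = provided accelerometry data (main analysis set)",
    "utility_0": "EQ-5D utility index at baseline",
    "utility_3": "EQ-5D utility index at 3 months",
    "utility_12": "EQ-5D utility index at 12 months",
    "steps_0": "average daily steps at baseline",
    "steps_3": "average daily steps at 3 months",
    "steps_12": "average daily steps at 12 months",
    "mvpa_0": "weekly minutes of MVPA in >=10 min bouts, baseline",
    "mvpa_3": "weekly minutes of MVPA in >=10 min bouts, 3 months",
    "mvpa_12": "weekly minutes of MVPA in >=10 min bouts, 12 months",
    "cost_setup": "intervention set-up cost, GBP (fixed per arm)",
    "cost_delivery_3": "intervention delivery cost incurred by 3 months, GBP",
    "cost_delivery": "intervention delivery cost over 12 months, GBP",
    "cost_health_service_3": "general health service use cost, months 0-3, GBP",
    "cost_health_service_12": "general health service use cost, months 4-12, GBP",
    "cost_sae": "alternative costing of serious adverse events (self-report), GBP",
    "cost_participant_3": "participant-borne costs, months 1-3, GBP",
    "cost_participant": "participant-borne costs, months 9-12 block, GBP",
}


def _mt(key: str, arm: str, block: str = "0-12m") -> tuple[float, float]:
    return published.ARM_SUMMARY[block][key][arm]


def _default_arm(arm: str) -> "ArmOutcomeConfig":
    s12 = published.ARM_SUMMARY["0-12m"]
    s3 = published.ARM_SUMMARY["0-3m"]
    hsu3 = s3["health_service_use"][arm]
    hsu12_total = s12["health_service_use"][arm]
    # months 4-12 block so the two blocks sum to the 0-12 total
    hsu_late_mean = hsu12_total[0] - hsu3[0]
    hsu_late_sd = float(np.sqrt(max(hsu12_total[1] ** 2 - hsu3[1] ** 2, 1.0)))
    inc3 = published.ADJUSTED_INCREMENTALS["3m"]
    inc12 = published.ADJUSTED_INCREMENTALS["12m"]
    key = f"{arm}_vs_control"
    d_steps3 = inc3["steps"].get(key, 0)
    d_steps12 = inc12["steps"].get(key, 0)
    d_mvpa3 = inc3["mvpa_min"].get(key, 0)
    d_mvpa12 = inc12["mvpa_min"].get(key, 0)
    return ArmOutcomeConfig(
        utility_mean={"0": s12["eq5d_baseline"][arm][0], "3": s12["eq5d_3m"][arm][0], "12": s12["eq5d_12m"][arm][0]},
        utility_sd={"0": s12["eq5d_baseline"][arm][1], "3": s12["eq5d_3m"][arm][1], "12": s12["eq5d_12m"][arm][1]},
        steps_mean={"0": 7500.0, "3": 7650.0 + d_steps3, "12": 7600.0 + d_steps12},
        steps_sd={"0": 2600.0, "3": 2700.0, "12": 2700.0},
        mvpa_mean={"0": 90.0, "3": 95.0 + d_mvpa3, "12": 100.0 + d_mvpa12},
        mvpa_sd={"0": 90.0, "3": 95.0, "12": 95.0},
        cost_setup=float(s12["setup"][arm][0]),
        cost_delivery_3=_mt("delivery", arm, "0-3m"),
        cost_delivery_12=s12["delivery"][arm],
        cost_hsu_3=hsu3,
        cost_hsu_4_12=(hsu_late_mean, hsu_late_sd),
        cost_participant_3=(15.0, 25.0) if arm != "control" else (8.0, 15.0),
        cost_participant_9_12=(10.0, 18.0) if arm != "control" else (5.0, 10.0),
    )


@dataclass
class ArmOutcomeConfig:
    """Outcome and cost distribution targets for one trial arm.

    Means/SDs are on the observed scale; keys "0", "3", "12" index the
    measurement time in months. Cost components are (mean, sd) pairs; an SD
    of zero makes the component an exact constant.
    """

    utility_mean: dict
    utility_sd: dict
    steps_mean: dict
    steps_sd: dict
    mvpa_mean: dict
    mvpa_sd: dict
    cost_setup: float
    cost_delivery_3: tuple
    cost_delivery_12: tuple
    cost_hsu_3: tuple
    cost_hsu_4_12: tuple
    cost_participant_3: tuple
    cost_participant_9_12: tuple


@dataclass
class SyntheticConfig:
    """Full configuration of the synthetic trial generator.

    Defaults reproduce the published PACE-UP arm-level summaries with 320
    participants per arm, a fifth of households contributing two members,
    and no missingness (apply it explicitly with `apply_missingness`).
    """

    n_per_arm: int = 320
    household_pair_fraction: float = 0.2
    seed: int = 0
    # variance shares of the structured normal scores (Gaussian copula)
    household_icc: float = 0.05
    activity_corr: float = 0.7  # steps-MVPA cross-outcome correlation
    time_corr: float = 0.35  # same-outcome correlation across time points
    accelerometry_fraction: float = 0.96
    sae_prob: float = 0.05
    sae_cost: tuple = (1500.0, 1200.0)
    # covariates
    age_range: tuple = (45, 75)
    female_fraction: float = 0.64
    white_fraction: float = 0.80
    disease_count_mean: float = 1.0
    # additive utility shift for participants active at 12 months
    # (>=150 weekly MVPA-bout minutes); 0 disables the injected effect
    active_utility_shift: float = 0.0
    missingness: dict = field(default_factory=dict)  # field -> MCAR rate
    mar: dict = field(default_factory=dict)  # field -> (intercept, slope) logit on z-age
    arms: dict = field(default_factory=lambda: {a: _default_arm(a) for a in published.ARMS})

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        for name, frac in (
            ("household_pair_fraction", self.household_pair_fraction),
            ("household_icc", self.household_icc),
            ("activity_corr", self.activity_corr),
            ("time_corr", self.time_corr),
            ("accelerometry_fraction", self.accelerometry_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {frac}")
        for fld, rate in self.missingness.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness rate for {fld} must lie in [0, 1], got {rate}")
        for arm, cfg in self.arms.items():
            for d in (cfg.utility_sd, cfg.steps_sd, cfg.mvpa_sd):
                if any(v < 0 for v in d.values()):
                    raise ValueError(f"negative SD in arm {arm!r}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        arms = raw.pop("arms", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "arms"})
        if arms:
            cfg.arms = {
                a: ArmOutcomeConfig(**{k: tuple(v) if isinstance(v, list) and k.startswith("cost_") and k != "cost_setup" else v for k, v in spec.items()})
                for a, spec in arms.items()
            }
        return cfg


@dataclass
class TrialDataset:
    """A generated trial table plus provenance and an optional truth channel.

    ``data`` holds one row per participant (see ``COLUMN_DICTIONARY``);
    ``truth`` keeps pre-missingness values of any field that
    `apply_missingness` blanked, for imputation-accuracy checks only —
    analysis code must never read it.
    """

    data: pd.DataFrame
    seed: int
    config_hash: str
    truth: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.data["pid"].duplicated().any():
            raise ValueError("participant ids must be unique")
        arms_per_hh = self.data.groupby("hid")["arm"].nunique()
        if (arms_per_hh > 1).any():
            raise ValueError("households must be allocated to a single arm")

    def to_csv(self, path) -> None:
        buf = io.StringIO()
        buf.write(f"# pedometer-cea synthetic trial | seed={self.seed} | config={self.config_hash}\n")
        self.data.to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_csv(cls, path) -> "TrialDataset":
        with open(path) as fh:
            header = fh.readline()
            seed, config_hash = 0, "unknown"
            if header.startswith("#"):
                for tok in header.strip("#\n").split("|"):
                    k, _, v = tok.strip().partition("=")
                    if k == "seed":
                        seed = int(v)
                    elif k == "config":
                        config_hash = v
                df = pd.read_csv(fh)
            else:
                fh.seek(0)
                df = pd.read_csv(fh)
        return cls(data=df, seed=seed, config_hash=config_hash)


# ---------------------------------------------------------------------------
# moment matching


import functools


@functools.lru_cache(maxsize=1024)
def truncnorm_match_moments(
    mean: float, sd: float, lower: float = 0.0, upper: float = 1.0
) -> tuple[float, float]:
    """Underlying (mu, sigma) whose [lower, upper]-truncated normal has the
    requested mean and SD.

    Raises ``ValueError`` when the moment pair is infeasible on the bounded
    support (e.g. SD too large for a mean near the boundary).
    """
    if sd == 0:
        if not lower < mean <= upper:
            raise ValueError(f"degenerate mean {mean} outside support ({lower}, {upper}]")
        return mean, 0.0
    span = upper - lower
    if sd >= span / 2 or not lower < mean < upper:
        raise ValueError(
            f"moments (mean={mean}, sd={sd}) infeasible for a distribution on [{lower}, {upper}]"
        )

    def resid(p):
        mu, log_sig = p
        sig = np.exp(log_sig)
        a, b = (lower - mu) / sig, (upper - mu) / sig
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.least_squares(resid, x0=[mean, np.log(sd)], xtol=1e-14, ftol=1e-14)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
        raise ValueError(
            f"could not match truncated-normal moments (mean={mean}, sd={sd}) on "
            f"[{lower}, {upper}]; residual {sol.fun}"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _truncnorm_from_z(z, mean, sd, lower=0.0, upper=1.0):
    """Map structured standard-normal scores to truncated-normal margins."""
    if sd == 0:
        return np.full_like(z, mean, dtype=float)
    mu, sig = truncnorm_match_moments(mean, sd, lower, upper)
    a, b = (lower - mu) / sig, (upper - mu) / sig
    u = stats.norm.cdf(z)
    return stats.truncnorm.ppf(np.clip(u, 1e-12, 1 - 1e-12), a, b, loc=mu, scale=sig)


def _lognorm_from_z(z, mean, sd):
    if sd == 0:
        return np.full_like(z, mean, dtype=float)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return np.exp(mu + np.sqrt(sigma2) * z)


def _gamma_draw(rng, mean, sd, size):
    if mean == 0:
        return np.zeros(size)
    if sd == 0:
        return np.full(size, float(mean))
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size)


# ---------------------------------------------------------------------------
# generation


def generate_trial(config: SyntheticConfig) -> TrialDataset:
    """Generate a full trial dataset from the configuration.

    Reproducible: the same configuration (including seed) yields a
    byte-identical table. Households are built first (a configurable
    fraction contribute two members), whole households are allocated to
    arms, and all outcome scores share the copula structure described in
    the module docstring.
    """
    rng = np.random.default_rng(config.seed)
    n_arm = config.n_per_arm
    rows = []
    pid = 0
    hid = 0
    w_h = np.sqrt(config.household_icc)
    for arm in published.ARMS:
        # build households until the arm has n_arm members
        members_hid = []
        while len(members_hid) < n_arm:
            size = 2 if (rng.random() < config.household_pair_fraction and len(members_hid) + 2 <= n_arm) else 1
            members_hid.extend([hid] * size)
            hid += 1
        members_hid = members_hid[:n_arm]
        n_h = max(members_hid) + 1
        b_house = rng.standard_normal(n_h)[members_hid]

        acfg = config.arms[arm]
        # latent factors: activity (shared steps/MVPA), per-outcome person
        # factors, and iid noise per outcome x time
        a_act = rng.standard_normal(n_arm)
        p_util = rng.standard_normal(n_arm)
        p_steps = rng.standard_normal(n_arm)
        p_mvpa = rng.standard_normal(n_arm)

        def z_score(person_factor, use_activity, t_key):
            # activity outcomes: the shared activity factor doubles as the
            # persistent person factor, giving cross-outcome and over-time
            # correlation activity_corr; utilities use their own person
            # factor with over-time correlation time_corr
            if use_activity:
                w_p2 = max(config.activity_corr - config.household_icc, 0.0)
                factor = a_act
            else:
                w_p2 = config.time_corr
                factor = person_factor
            w_e2 = 1.0 - config.household_icc - w_p2
            if w_e2 < 0:
                raise ValueError("variance shares (household icc + correlation) exceed 1")
            eps = rng.standard_normal(n_arm)
            return w_h * b_house + np.sqrt(w_p2) * factor + np.sqrt(w_e2) * eps

        util = {
            t: _truncnorm_from_z(z_score(p_util, False, t), acfg.utility_mean[t], acfg.utility_sd[t])
            for t in ("0", "3", "12")
        }
        steps = {
            t: _lognorm_from_z(z_score(p_steps, True, t), acfg.steps_mean[t], acfg.steps_sd[t])
            for t in ("0", "3", "12")
        }
        mvpa = {
            t: _lognorm_from_z(z_score(p_mvpa, True, t), acfg.mvpa_mean[t], acfg.mvpa_sd[t])
            for t in ("0", "3", "12")
        }
        if config.active_utility_shift:
            active = mvpa["12"] >= 150.0
            util["12"] = np.minimum(util["12"] + config.active_utility_shift * active, 1.0)

        hsu3 = _gamma_draw(rng, *acfg.cost_hsu_3, n_arm)
        hsu_late = _gamma_draw(rng, *acfg.cost_hsu_4_12, n_arm)
        deliv3 = _gamma_draw(rng, *acfg.cost_delivery_3, n_arm)
        deliv12 = _gamma_draw(rng, *acfg.cost_delivery_12, n_arm)
        deliv12 = np.maximum(deliv12, deliv3)  # cumulative cost cannot fall
        part3 = _gamma_draw(rng, *acfg.cost_participant_3, n_arm)
        part912 = _gamma_draw(rng, *acfg.cost_participant_9_12, n_arm)
        sae = np.where(
            rng.random(n_arm) < config.sae_prob, _gamma_draw(rng, *config.sae_cost, n_arm), 0.0
        )

        lo, hi = config.age_range
        age = rng.integers(lo, hi + 1, n_arm)
        sex = (rng.random(n_arm) < config.female_fraction).astype(int)
        white = (rng.random(n_arm) < config.white_fraction).astype(int)
        disease = rng.poisson(config.disease_count_mean, n_arm)
        accel = (rng.random(n_arm) < config.accelerometry_fraction).astype(int)

        for i in range(n_arm):
            rows.append(
                dict(
                    pid=pid + i,
                    hid=members_hid[i],
                    arm=arm,
                    age=int(age[i]),
                    sex=int(sex[i]),
                    ethnicity_white=int(white[i]),
                    disease_count=int(disease[i]),
                    has_accelerometry=int(accel[i]),
                    utility_0=util["0"][i],
                    utility_3=util["3"][i],
                    utility_12=util["12"][i],
                    steps_0=steps["0"][i],
                    steps_3=steps["3"][i],
                    steps_12=steps["12"][i],
                    mvpa_0=mvpa["0"][i],
                    mvpa_3=mvpa["3"][i],
                    mvpa_12=mvpa["12"][i],
                    cost_setup=acfg.cost_setup,
                    cost_delivery_3=deliv3[i],
                    cost_delivery=deliv12[i],
                    cost_health_service_3=hsu3[i],
                    cost_health_service_12=hsu_late[i],
                    cost_sae=sae[i],
                    cost_participant_3=part3[i],
                    cost_participant=part912[i],
                )
            )
        pid += n_arm
    df = pd.DataFrame(rows)
    return TrialDataset(data=df, seed=config.seed, config_hash=config.config_hash())


def apply_missingness(ds: TrialDataset, config: SyntheticConfig) -> TrialDataset:
    """Blank measured fields per the configured missingness model.

    MCAR: each field in ``config.missingness`` is independently missing at
    its rate. MAR: fields in ``config.mar`` are missing with probability
    ``expit(intercept + slope * z_age)`` where z_age is the within-dataset
    standardised age. Pre-deletion values go to the truth channel.
    """
    df = ds.data.copy()
    rng = np.random.default_rng(np.random.SeedSequence([ds.seed, 0x5EED]))
    touched = sorted(set(config.missingness) | set(config.mar))
    for fld in touched:
        if fld not in MEASURED_FIELDS:
            raise ValueError(f"cannot apply missingness to non-measured field {fld!r}")
    truth = ds.data[["pid", *touched]].copy() if touched else None
    z_age = (df["age"] - df["age"].mean()) / max(df["age"].std(ddof=0), 1e-9)
    for fld in touched:
        if fld in config.mar:
            intercept, slope = config.mar[fld]
            p = 1.0 / (1.0 + np.exp(-(intercept + slope * z_age)))
        else:
            p = np.full(len(df), config.missingness[fld])
        mask = rng.random(len(df)) < p
        df.loc[mask, fld] = np.nan
    return TrialDataset(data=df, seed=ds.seed, config_hash=ds.config_hash, truth=truth)
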