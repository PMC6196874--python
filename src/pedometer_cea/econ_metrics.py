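"""Core health-economics arithmetic.

Discounting of annual cost/QALY streams, incremental cost-effectiveness
ratios with cost-effectiveness-plane quadrant and dominance classification,
net monetary benefit at a willingness-to-pay threshold, and
cost-effectiveness acceptability curves (CEACs) built from paired
(incremental cost, incremental effect) draws.

Conventions
-----------
* Money is GBP at 2013/14 prices throughout.
* Discounting treats the first cycle as undiscounted: present value of a
  stream ``v_1..v_N`` at annual rate ``r`` is ``sum v_t / (1+r)**(t-1)``,
  so a zero rate is an exact identity.
* A CEAC counts a draw as cost-effective when its net monetary benefit is
  strictly positive; an NMB of exactly zero counts as not cost-effective.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "IncrementalResult",
    "ICERResult",
    "NMBResult",
    "CEACCurve",
    "discount_stream",
    "icer_classify",
    "net_monetary_benefit",
    "ceac_from_samples",
    "round_half_away",
    "default_wtp_grid",
]

EFFECT_UNITS = ("qaly", "steps", "mvpa_min")


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with halves away from zero (the convention of printed CEA tables).

    Python's builtin ``round`` uses banker's rounding; published
    cost-effectiveness tables round 0.5 up in magnitude.
    """
    d = decimal.Decimal(repr(float(x))).quantize(
        decimal.Decimal(1).scaleb(-ndigits), rounding=decimal.ROUND_HALF_UP
    )
    return float(d)


@dataclass(frozen=True)
class IncrementalResult:
    """Paired incremental cost and effect for one arm comparison.

    ``delta_cost`` in GBP; ``delta_effect`` in the unit named by
    ``effect_unit`` (QALYs, daily steps, or weekly minutes of MVPA in
    >=10 min bouts). Optional 95% interval bounds for each.
    """

    delta_cost: float
    delta_effect: float
    effect_unit: str = "qaly"
    ci_cost: Optional[tuple[float, float]] = None
    ci_effect: Optional[tuple[float, float]] = None
    comparison: str = ""

    def __post_init__(self) -> None:
        if self.effect_unit not in EFFECT_UNITS:
            raise ValueError(f"effect_unit must be one of {EFFECT_UNITS}, got {self.effect_unit!r}")
        for ci, point, name in (
            (self.ci_cost, self.delta_cost, "cost"),
            (self.ci_effect, self.delta_effect, "effect"),
        ):
            if ci is not None and not (ci[0] <= point <= ci[1]):
                raise ValueError(f"95% interval for {name} does not bracket the point estimate")


@dataclass(frozen=True)
class ICERResult:
    """ICER with cost-effectiveness-plane quadrant and dominance label.

    ``value`` is defined only for ``label`` in {"icer", "saved_per_unit_lost"}:
    a conventional ratio in the north-east quadrant, or savings per unit of
    effect lost in the south-west quadrant.
    """

    quadrant: str  # NE | NW | SE | SW | axis
    value: Optional[float]
    label: str  # icer | dominant | dominated | saved_per_unit_lost | equivalent

    def __post_init__(self) -> None:
        has_value = self.label in ("icer", "saved_per_unit_lost")
        if has_value != (self.value is not None):
            raise ValueError("value defined iff label is icer or saved_per_unit_lost")


@dataclass(frozen=True)
class NMBResult:
    """Net monetary benefit ``wtp * delta_effect - delta_cost`` (GBP)."""

    wtp: float
    nmb: float
    ci: Optional[tuple[float, float]] = None


@dataclass
class CEACCurve:
    """Probability cost-effective over an ascending willingness-to-pay grid."""

    wtp_grid: np.ndarray
    probability: np.ndarray
    comparison: str = ""

    def __post_init__(self) -> None:
        self.wtp_grid = np.asarray(self.wtp_grid, dtype=float)
        self.probability = np.asarray(self.probability, dtype=float)
        if self.wtp_grid.ndim != 1 or np.any(np.diff(self.wtp_grid) <= 0):
            raise ValueError("wtp_grid must be one-dimensional and strictly ascending")
        if self.probability.shape != self.wtp_grid.shape:
            raise ValueError("probability and wtp_grid must have the same shape")
        if np.any((self.probability < 0) | (self.probability > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"wtp": self.wtp_grid, "probability": self.probability, "comparison": self.comparison}
        )


def default_wtp_grid() -> np.ndarray:
    """£0 to £50,000 per QALY in £1,000 steps (51 points)."""
    return np.arange(0.0, 50_001.0, 1_000.0)


def discount_stream(values: Sequence[float], rate: float) -> float:
    """Present value of an annual stream with the first cycle undiscounted.

    Parameters
    ----------
    values : sequence of per-cycle amounts (money or QALYs), cycle 1 first.
    rate : annual discount rate as a fraction (e.g. 0.035).

    Returns ``sum_t values[t] / (1 + rate)**t`` for t = 0..N-1.
    """
    if rate < 0:
        raise ValueError(f"discount rate must be non-negative, got {rate}; a negative rate would inflate future values")
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be a one-dimensional stream")
    factors = (1.0 + rate) ** (-np.arange(v.size, dtype=float))
    return float(v @ factors)


def icer_classify(inc: IncrementalResult) -> ICERResult:
    """Classify an incremental result on the cost-effectiveness plane.

    North-east (costlier, more effective) gives a conventional ICER
    ``delta_cost / delta_effect``; south-east is dominant (cheaper, more
    effective); north-west is dominated; south-west reports savings per
    unit of effect lost. A zero effect difference with nonzero cost sits on
    the axis with no defined ratio; zero on both is "equivalent".
    """
    dc, de = inc.delta_cost, inc.delta_effect
    if de > 0:
        if dc >= 0:
            return ICERResult("NE", dc / de, "icer")
        return ICERResult("SE", None, "dominant")
    if de < 0:
        if dc > 0:
            return ICERResult("NW", None, "dominated")
        return ICERResult("SW", abs(dc) / abs(de), "saved_per_unit_lost")
    if dc == 0:
        return ICERResult("axis", None, "equivalent")
    return ICERResult("axis", None, "dominated" if dc > 0 else "dominant")


def net_monetary_benefit(inc: IncrementalResult, wtp: float) -> NMBResult:
    """NMB = wtp * delta_QALY - delta_cost; requires a QALY effect unit."""
    if inc.effect_unit != "qaly":
        raise ValueError(
            f"net monetary benefit requires QALY effects; got effect_unit={inc.effect_unit!r}"
        )
    return NMBResult(wtp=wtp, nmb=wtp * inc.delta_effect - inc.delta_cost)


def ceac_from_samples(
    pairs: np.ndarray | Sequence[tuple[float, float]],
    wtp_grid: Optional[np.ndarray] = None,
    comparison: str = "",
) -> CEACCurve:
    """CEAC from paired (delta_cost, delta_QALY) draws.

    At each willingness-to-pay value the probability is the fraction of
    draws with strictly positive net monetary benefit; an NMB of exactly
    zero counts as not cost-effective.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
        raise ValueError("pairs must be a non-empty (n, 2) array of (delta_cost, delta_effect) draws")
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    dc, de = arr[:, 0], arr[:, 1]
    nmb = grid[:, None] * de[None, :] - dc[None, :]
    prob = (nmb > 0).mean(axis=1)
    return CEACCurve(wtp_grid=grid, probability=prob, comparison=comparison)
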