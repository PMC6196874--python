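"""Published summary statistics from the PACE-UP trial economic evaluation.

PACE-UP (ISRCTN98538934) was a three-arm cluster-randomised trial
(randomised by household) of pedometer-based walking interventions in
South London primary care: usual care (control), a pedometer with written
materials posted to the participant (postal), and the same pack delivered
through three practice-nurse physical-activity consultations (nurse).

These dictionaries transcribe the published per-arm cost and EQ-5D summary
tables, the adjusted (regression-based) incremental costs and effects at 3
and 12 months, and the lifetime decision-model incrementals per 100,000
people. They serve two purposes:

* defaults for the synthetic-trial generator, so simulated datasets carry
  the trial's arm-level means and spreads; and
* inputs to worked examples that re-derive the published ICERs, net
  monetary benefits and QALY areas under the curve from the printed
  summary numbers.

All money is GBP at 2013/14 prices.
"""

from __future__ import annotations

ARMS = ("control", "postal", "nurse")

# Per-arm means (SDs) of costs and EQ-5D utility indices, imputed data,
# participants who provided accelerometry. Keyed by horizon block.
ARM_SUMMARY = {
    "0-3m": {
        "n": {"control": 318, "postal": 317, "nurse": 319},
        "total_cost": {"control": (107, 254), "postal": (122, 107), "nurse": (249, 215)},
        "setup": {"control": (0, 0), "postal": (45, 0), "nurse": (105, 0)},
        "delivery": {"control": (0, 0), "postal": (7, 0), "nurse": (50, 18)},
        "health_service_use": {"control": (107, 254), "postal": (71, 107), "nurse": (95, 214)},
        "eq5d_baseline": {"control": (0.839, 0.14), "postal": (0.853, 0.12), "nurse": (0.851, 0.12)},
        "eq5d_3m": {"control": (0.844, 0.14), "postal": (0.848, 0.14), "nurse": (0.841, 0.14)},
        "qalys": {"control": (0.194, 0.03), "postal": (0.196, 0.03), "nurse": (0.195, 0.03)},
    },
    "0-12m": {
        "n": {"control": 323, "postal": 312, "nurse": 321},
        "total_cost": {"control": (461, 916), "postal": (375, 611), "nurse": (603, 987)},
        "setup": {"control": (0, 0), "postal": (45, 0), "nurse": (105, 0)},
        "delivery": {"control": (0, 0), "postal": (10, 0), "nurse": (52, 18)},
        "health_service_use": {"control": (461, 916), "postal": (320, 611), "nurse": (447, 987)},
        "eq5d_baseline": {"control": (0.837, 0.14), "postal": (0.850, 0.12), "nurse": (0.849, 0.13)},
        "eq5d_3m": {"control": (0.840, 0.14), "postal": (0.847, 0.13), "nurse": (0.837, 0.14)},
        "eq5d_12m": {"control": (0.833, 0.15), "postal": (0.836, 0.13), "nurse": (0.831, 0.14)},
        "qalys": {"control": (0.837, 0.13), "postal": (0.843, 0.11), "nurse": (0.836, 0.13)},
    },
}

# Adjusted incremental estimates (recycled-prediction margins, household-
# clustered SEs). Comparisons: postal vs control, nurse vs control,
# nurse vs postal.
ADJUSTED_INCREMENTALS = {
    "3m": {
        "cost": {"postal_vs_control": 15, "nurse_vs_control": 135, "nurse_vs_postal": 120},
        "qaly": {
            "postal_vs_control": -0.0005,
            "nurse_vs_control": -0.0009,
            "nurse_vs_postal": -0.0004,
        },
        "steps": {"postal_vs_control": 692, "nurse_vs_control": 1172, "nurse_vs_postal": 481},
        "mvpa_min": {"postal_vs_control": 43, "nurse_vs_control": 61, "nurse_vs_postal": 18},
    },
    "12m": {
        "cost": {"postal_vs_control": -91, "nurse_vs_control": 126, "nurse_vs_postal": 217},
        "qaly": {
            "postal_vs_control": -0.0043,  # printed -0.004; unrounded value implied by
            # the published "£21,162 saved per QALY lost" alongside the -£91 cost saving
            "nurse_vs_control": -0.007,
            "nurse_vs_postal": -0.002,
        },
        "steps": {"postal_vs_control": 642, "nurse_vs_control": 677, "nurse_vs_postal": 36},
        "mvpa_min": {"postal_vs_control": 33, "nurse_vs_control": 35, "nurse_vs_postal": 2},
    },
}

# Lifetime decision-model incrementals per 100,000 people aged 59-88
# (costs in GBP, QALYs in QALYs; published as £ million and whole QALYs).
LIFETIME_INCREMENTALS = {
    "cost": {
        "postal_vs_control": -11e6,
        "nurse_vs_control": 11e6,
        "nurse_vs_postal": 22e6,
    },
    "qaly": {
        "postal_vs_control": 759,
        "nurse_vs_control": 671,
        "nurse_vs_postal": -108,
    },
}

# Trial-based year-1 total cost per person by arm (adjusted 12-month means)
# used as model year-1 costs in the lifetime evaluation.
YEAR1_COST_PER_PERSON = {"control": 467.0, "postal": 376.0, "nurse": 593.0}

# Annuitised second-year intervention cost per person.
YEAR2_INTERVENTION_COST = {"control": 0.0, "postal": 5.03, "nurse": 4.14}
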