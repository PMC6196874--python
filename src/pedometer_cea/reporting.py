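"""Result formatting and file output with provenance headers.

Rounding conventions follow the published tables: ICERs to 2 decimal
places (half away from zero), net monetary benefit to the nearest £million,
QALYs to 3 decimal places. Every CSV written by the pipeline carries a
one-line provenance comment (tool, seed, config hash) sufficient to
reproduce it.
"""

from __future__ import annotations

import io
from typing import Optional

import pandas as pd

from .econ_metrics import ICERResult, round_half_away

__all__ = [
    "format_icer",
    "format_money",
    "format_nmb_millions",
    "format_qaly",
    "write_csv_with_provenance",
    "read_csv_with_provenance",
    "within_trial_table",
    "markov_table",
]


def format_money(x: float, ndigits: int = 2) -> str:
    v = round_half_away(x, ndigits)
    if ndigits == 0:
        return f"£{v:,.0f}"
    return f"£{v:,.{ndigits}f}"


def format_icer(icer: ICERResult, unit: str = "QALY") -> str:
    if icer.label == "icer":
        return format_money(icer.value)
    if icer.label == "dominant":
        return "dominates"
    if icer.label == "dominated":
        return "dominated"
    if icer.label == "saved_per_unit_lost":
        return f"{format_money(icer.value, 0)} saved per {unit} lost"
    return "equivalent"


def format_nmb_millions(nmb: float) -> str:
    return f"{round_half_away(nmb / 1e6, 0):.0f}"


def format_qaly(q: float) -> str:
    return f"{round_half_away(q, 3):.3f}"


def write_csv_with_provenance(
    df: pd.DataFrame, path, seed: Optional[int] = None, config_hash: str = ""
) -> None:
    buf = io.StringIO()
    buf.write(f"# pedometer-cea | seed={seed} | config={config_hash}\n")
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_csv_with_provenance(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def within_trial_table(results: dict) -> pd.DataFrame:
    """Tidy per-comparison summary of a within-trial run."""
    rows = []
    for comp, inc in results["incrementals"].items():
        icer = results["icers"][comp]
        rows.append(
            {
                "comparison": comp,
                "delta_cost": round_half_away(inc.delta_cost, 2),
                "delta_cost_lo": round_half_away(inc.ci_cost[0], 2) if inc.ci_cost else None,
                "delta_cost_hi": round_half_away(inc.ci_cost[1], 2) if inc.ci_cost else None,
                "delta_qaly": round_half_away(inc.delta_effect, 4),
                "delta_qaly_lo": round_half_away(inc.ci_effect[0], 4) if inc.ci_effect else None,
                "delta_qaly_hi": round_half_away(inc.ci_effect[1], 4) if inc.ci_effect else None,
                "icer": format_icer(icer),
            }
        )
    return pd.DataFrame(rows)


def markov_table(results: dict) -> pd.DataFrame:
    """Tidy lifetime-model summary (per-arm totals and comparisons)."""
    rows = []
    for arm, ar in results["arm_results"].items():
        rows.append(
            {
                "row": f"arm:{arm}",
                "cost_millions": round_half_away(ar.cost_discounted / 1e6, 1),
                "qalys": round_half_away(ar.qaly_discounted, 0),
                "icer": "",
                "nmb_millions": "",
            }
        )
    for comp, cr in results["comparisons"].items():
        rows.append(
            {
                "row": f"cmp:{comp}",
                "cost_millions": round_half_away(cr.incremental.delta_cost / 1e6, 1),
                "qalys": round_half_away(cr.incremental.delta_effect, 0),
                "icer": format_icer(cr.icer),
                "nmb_millions": format_nmb_millions(cr.nmb.nmb),
            }
        )
    return pd.DataFrame(rows)
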