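"""Standardised report writers: base-case table, JSON summaries, run manifest.

The base-case report mirrors the canonical outcome table of this kind of
evaluation: an incidence block (per 1,000 exposures, 4 dp), a cost block
split into direct medical and direct non-medical categories (THB, 2 dp, with
an optional USD column at the fixed 31 THB/USD display rate), cohort QALYs,
and the ICER.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import __version__
from .cohort import CEResult, StrategyOutcome
from .parameters import THB_PER_USD, ModelParameters

__all__ = ["basecase_table", "ce_result_dict", "write_json", "write_manifest"]

_COST_ROWS = [
    ("test", "Cost of genotyping"),
    ("drug", "Annual drug cost"),
    ("sjs_management", "Cost for SJS/TEN"),
    ("gout_management", "Annual cost for gout"),
    ("des_management", "Annual cost for DES"),
    ("sjs_nonmedical", "Cost for SJS/TEN visiting"),
    ("gout_nonmedical", "Cost for gout visiting"),
    ("des_nonmedical", "Cost for DES visiting"),
]


def relative_reduction_pct(usual: float, testing: float) -> float:
    """Percent reduction achieved by testing, at full precision."""
    if usual == 0.0:
        return 0.0
    return 100.0 * (1.0 - testing / usual)


def basecase_table(
    testing: StrategyOutcome,
    usual: StrategyOutcome,
    ce: CEResult,
    usd: bool = False,
) -> pd.DataFrame:
    """Outcome table with incidence, cost-by-category, QALY and ICER blocks."""
    rows: List[Dict[str, object]] = []

    def add(block: str, measure: str, g: float, u: float, ndp: int) -> None:
        row: Dict[str, object] = {
            "block": block,
            "measure": measure,
            "genetic_testing": round(g, ndp),
            "usual_care": round(u, ndp),
            "difference": round(g - u, ndp),
        }
        if usd:
            row["difference_usd"] = round((g - u) / THB_PER_USD, 2)
        rows.append(row)

    ev_t, ev_u = testing.events, usual.events
    add("incidence_per_1000", "SJS/TEN", ev_t.sjs_cases_per_1000, ev_u.sjs_cases_per_1000, 4)
    add(
        "incidence_per_1000",
        "Death in SJS/TEN cases",
        ev_t.sjs_deaths_per_1000,
        ev_u.sjs_deaths_per_1000,
        4,
    )
    for key, label in _COST_ROWS[:5]:
        add("direct_medical_costs_thb", label, testing.cost_by_category[key], usual.cost_by_category[key], 2)
    add(
        "direct_medical_costs_thb",
        "Subtotal direct medical",
        testing.direct_medical_cost,
        usual.direct_medical_cost,
        2,
    )
    for key, label in _COST_ROWS[5:]:
        add("direct_nonmedical_costs_thb", label, testing.cost_by_category[key], usual.cost_by_category[key], 2)
    add(
        "direct_nonmedical_costs_thb",
        "Subtotal direct non-medical",
        testing.direct_nonmedical_cost,
        usual.direct_nonmedical_cost,
        2,
    )
    add("totals", "Total costs (THB)", testing.total_cost, usual.total_cost, 2)
    add("totals", "QALY", testing.total_qaly, usual.total_qaly, 2)
    icer_row: Dict[str, object] = {
        "block": "totals",
        "measure": "ICER (THB per QALY)",
        "genetic_testing": round(ce.icer, 2) if ce.icer is not None else ce.dominance,
        "usual_care": "",
        "difference": "",
    }
    if usd:
        icer_row["difference_usd"] = (
            round(ce.icer / THB_PER_USD, 2) if ce.icer is not None else ""
        )
    rows.append(icer_row)
    return pd.DataFrame(rows)


def ce_result_dict(ce: CEResult) -> Dict[str, object]:
    d = dataclasses.asdict(ce)
    d["icer_usd"] = None if ce.icer is None else ce.icer / THB_PER_USD
    return d


def write_json(path: Path, payload: object) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def write_manifest(
    outdir: Path,
    subcommand: str,
    params: ModelParameters,
    outputs: List[Path],
    seeds: Optional[Dict[str, int]] = None,
    overridden: Optional[Dict[str, object]] = None,
) -> Path:
    """Write a single-JSON run manifest listing every produced file."""
    manifest = {
        "subcommand": subcommand,
        "software_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "seeds": seeds or {},
        "overridden_parameters": overridden or {},
        "resolved_parameters": params.to_flat_dict(),
        "outputs": [p.name for p in outputs],
    }
    path = outdir / "manifest.json"
    write_json(path, manifest)
    for p in outputs:
        if not p.exists():
            raise FileNotFoundError(f"manifest lists missing output {p}")
    return path
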