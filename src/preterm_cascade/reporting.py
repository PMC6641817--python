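"""Presentation of scenario results: rounded tables of deaths and lives saved.

Death counts are reported rounded to the nearest 100; percent reductions are
computed from the unrounded totals and printed to one decimal, matching the
source publication's table layout.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .cohort_cascade import MortalityResult
from .scenario_engine import ScenarioResult, deaths_prevented

__all__ = ["ScenarioReportRow", "round_nearest_100", "build_report", "write_report"]

#: Column headers mirroring the published scenario tables.
REPORT_COLUMNS = [
    "Scenario No.",
    "Scenario",
    "Incremental Change Model: Preterm Deaths, No.",
    "Incremental Change Model: Preterm Deaths Prevented Compared With Current Level of Care, No.",
    "Incremental Change Model: Preterm Deaths Prevented Compared With Current Level of Care, %",
    "Universal Coverage Model: Preterm Deaths, No.",
    "Universal Coverage Model: Preterm Deaths Prevented Compared With Current Level of Care, No.",
    "Universal Coverage Model: Preterm Deaths Prevented Compared With Current Level of Care, %",
]


def round_nearest_100(x: float) -> int:
    """Nearest multiple of 100; ties round half-up. Deterministic."""
    if x < 0:
        raise ValueError(f"negative death count {x}")
    return int(math.floor(x / 100.0 + 0.5)) * 100


@dataclasses.dataclass(frozen=True)
class ScenarioReportRow:
    scenario_id: str
    number: int
    description: str
    incremental_deaths: int
    incremental_prevented: int
    incremental_percent: float
    universal_deaths: int
    universal_prevented: int
    universal_percent: float


def build_report(
    results: Sequence[ScenarioResult], baseline: MortalityResult
) -> list[ScenarioReportRow]:
    """One row per scenario, in library order.

    Every result must share the baseline's subcondition group; rounding is
    applied last, and percents derive from unrounded totals.
    """
    rows = []
    for res in results:
        inc_abs, inc_pct = deaths_prevented(baseline, res.incremental)
        uni_abs, uni_pct = deaths_prevented(baseline, res.universal)
        rows.append(
            ScenarioReportRow(
                scenario_id=res.spec.id,
                number=res.spec.number,
                description=res.spec.description,
                incremental_deaths=round_nearest_100(res.incremental.total_deaths),
                incremental_prevented=round_nearest_100(max(inc_abs, 0.0)),
                incremental_percent=round(inc_pct, 1),
                universal_deaths=round_nearest_100(res.universal.total_deaths),
                universal_prevented=round_nearest_100(max(uni_abs, 0.0)),
                universal_percent=round(uni_pct, 1),
            )
        )
    return rows


def report_frame(rows: Sequence[ScenarioReportRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                REPORT_COLUMNS[0]: r.number,
                REPORT_COLUMNS[1]: r.description,
                REPORT_COLUMNS[2]: r.incremental_deaths,
                REPORT_COLUMNS[3]: r.incremental_prevented,
                REPORT_COLUMNS[4]: f"{r.incremental_percent:.1f}",
                REPORT_COLUMNS[5]: r.universal_deaths,
                REPORT_COLUMNS[6]: r.universal_prevented,
                REPORT_COLUMNS[7]: f"{r.universal_percent:.1f}",
            }
            for r in rows
        ],
        columns=REPORT_COLUMNS,
    )


def write_report(
    rows: Sequence[ScenarioReportRow], out_dir: Path, stem: str
) -> tuple[Path, Path]:
    """Emit CSV and JSON mirrors under ``out_dir``; returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    json_path = out_dir / f"{stem}.json"
    report_frame(rows).to_csv(csv_path, index=False)
    json_path.write_text(
        json.dumps([dataclasses.asdict(r) for r in rows], indent=2) + "\n"
    )
    return csv_path, json_path
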