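"""Traffic-light indicators for genetic-diversity monitoring.

Three indicators, each classified green (acceptable) / yellow (warning) /
red (alarm):

* **Delta-H** — within-population change in a diversity measure (He, Ho,
  An, or Ar) over a monitoring period, converted to the expected retention
  over 100 years assuming a constant proportional rate of change:
  retention_100 = (after/before)^(100/t_years).  Retention >= 95% is green,
  75-94% yellow, < 75% red; a significant *increase* is yellow when a known
  anthropogenic cause is on record, otherwise green with a note.

* **Ne** — the 50/500 rule applied to the larger of the temporal and LD
  estimates (both downward-biased for local inbreeding effective size in
  subdivided systems, so the max is the less pessimistic choice):
  Ne > 500 green, 50 < Ne <= 500 yellow, Ne <= 50 red.

* **Delta-FST** — change in pairwise divergence mapped to change in gene
  flow through the island model Nm = (1/FST - 1)/4.  A significant change
  implying a 50-100% increase or 25-50% reduction in migrants is yellow;
  > 100% increase or > 50% reduction is red.

The per-period per-population statuses are assembled into a machine-readable
report (TSV/JSON), the tabular analogue of the traffic-light figure used in
national monitoring programs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "IndicatorStatus",
    "delta_h_classify",
    "ne_classify",
    "delta_fst_classify",
    "fst_to_nm",
    "expected_het_retention",
    "indicator_report",
]

GREEN, YELLOW, RED = "green", "yellow", "red"


@dataclass
class IndicatorStatus:
    indicator: str              # "dH" | "Ne" | "dFST"
    status: str                 # green | yellow | red
    direction: str              # "up" | "down" | "horizontal"
    significant: bool | None = None
    measure: str | None = None  # for dH: He | Ho | An | Ar
    period_years: float | None = None
    before: float | None = None
    after: float | None = None
    retention_100y: float | None = None
    estimate: float | None = None       # for Ne
    gene_flow_change_pct: float | None = None  # for dFST
    anthropogenic: bool | None = None
    note: str = ""


# ---------------------------------------------------------------------------

def expected_het_retention(ne: float, generations: float = 1) -> float:
    """Expected fraction of heterozygosity retained after drift.

    Per generation a fraction 1/(2Ne) is lost; over t generations the
    retention is (1 - 1/(2Ne))^t.  At Ne = 10 a single generation loses 5%
    and retains 95%.
    """
    if ne <= 0:
        raise ValueError("Ne must be positive")
    if math.isinf(ne):
        return 1.0
    return (1.0 - 1.0 / (2.0 * ne)) ** generations


def delta_h_classify(
    before: float,
    after: float,
    t_years: float,
    significant: bool,
    anthropogenic_flag: bool = False,
    measure: str = "He",
) -> IndicatorStatus:
    """Classify a within-population diversity change.

    The observed ratio is compounded to 100 years at a constant proportional
    rate: retention_100 = (after/before)^(100/t_years).  Non-significant
    changes are green.  Significant decreases: >= 0.95 green, [0.75, 0.95)
    yellow, < 0.75 red.  Significant increases are yellow when coupled with
    a known anthropogenic cause, else green with a note.
    """
    if before <= 0 or t_years <= 0 or after <= 0:
        raise ValueError("before, after and t_years must be positive")
    retention = (after / before) ** (100.0 / t_years)
    if after > before:
        direction = "up"
    elif after < before:
        direction = "down"
    else:
        direction = "horizontal"
    note = ""
    if not significant:
        status = GREEN
    elif after < before:
        if retention >= 0.95:
            status = GREEN
        elif retention >= 0.75:
            status = YELLOW
        else:
            status = RED
    else:  # significant increase
        if anthropogenic_flag:
            status = YELLOW
        else:
            status = GREEN
            note = "significant increase without a recorded anthropogenic cause"
    return IndicatorStatus(
        indicator="dH", status=status, direction=direction,
        significant=significant, measure=measure, period_years=t_years,
        before=before, after=after, retention_100y=retention,
        anthropogenic=anthropogenic_flag, note=note,
    )


def ne_classify(ne_v: float | None, ne_ld_harmonic: float | None) -> IndicatorStatus:
    """50/500 rule on the max of the temporal and LD estimates.

    Ne > 500 green; 50 < Ne <= 500 yellow; Ne <= 50 red (the published
    thresholds are strict '> 500' and '< 50'; the boundaries therefore fall
    to the more cautious class).
    """
    candidates = [v for v in (ne_v, ne_ld_harmonic)
                  if v is not None and not (isinstance(v, float) and math.isnan(v))]
    if not candidates:
        raise ValueError("at least one Ne estimate is required")
    est = max(candidates)
    if est > 500:
        status = GREEN
    elif est > 50:
        status = YELLOW
    else:
        status = RED
    return IndicatorStatus(indicator="Ne", status=status, direction="horizontal",
                           estimate=float(est))


def fst_to_nm(fst: float) -> float:
    """Island-model effective number of migrants: Nm = (1/FST - 1)/4."""
    if not 0 < fst < 1:
        raise ValueError("FST must lie strictly within (0, 1)")
    return (1.0 / fst - 1.0) / 4.0


def delta_fst_classify(
    fst_before: float,
    fst_after: float,
    significant: bool,
) -> IndicatorStatus:
    """Classify a change in between-population divergence.

    Both FST values are mapped to island-model migrant numbers; the percent
    change in Nm drives the call.  Significant 50-100% increase or 25-50%
    reduction -> yellow; > 100% increase or > 50% reduction -> red;
    otherwise (or if not significant) green.
    """
    nm_before = fst_to_nm(fst_before)
    nm_after = fst_to_nm(fst_after)
    change_pct = 100.0 * (nm_after / nm_before - 1.0)
    if fst_after < fst_before:
        direction = "down"       # divergence down = gene flow up
    elif fst_after > fst_before:
        direction = "up"
    else:
        direction = "horizontal"
    if not significant:
        status = GREEN
    elif change_pct > 100 or change_pct < -50:
        status = RED
    elif 50 <= change_pct <= 100 or -50 <= change_pct <= -25:
        status = YELLOW
    else:
        status = GREEN
    return IndicatorStatus(
        indicator="dFST", status=status, direction=direction,
        significant=significant, before=fst_before, after=fst_after,
        gene_flow_change_pct=change_pct,
    )


# ---------------------------------------------------------------------------

@dataclass
class IndicatorReport:
    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.rows.to_dict(orient="records"), fh, indent=1,
                      default=str)


_STATUS_RANK = {GREEN: 0, YELLOW: 1, RED: 2}


def indicator_report(
    cells: dict[tuple[str, str], list[IndicatorStatus]],
) -> IndicatorReport:
    """Assemble per-(population, period) indicator statuses into one table.

    ``cells`` maps (population, period) to the list of IndicatorStatus
    values computed for it.  Per-measure Delta-H rows are kept separate and
    an overall Delta-H roll-up (worst status across measures) is appended,
    labeled ``dH:rollup``.  Missing inputs are the caller's responsibility:
    every requested cell must be present.
    """
    records = []
    for (pop, period), statuses in sorted(cells.items()):
        if not statuses:
            raise ValueError(f"no statuses for cell ({pop}, {period})")
        dh = [s for s in statuses if s.indicator == "dH"]
        for s in statuses:
            rec = asdict(s)
            rec["population"] = pop
            rec["period"] = period
            rec["label"] = (f"dH:{s.measure}" if s.indicator == "dH"
                            else s.indicator)
            records.append(rec)
        if dh:
            worst = max(dh, key=lambda s: _STATUS_RANK[s.status])
            rec = asdict(worst)
            rec["population"] = pop
            rec["period"] = period
            rec["label"] = "dH:rollup"
            rec["note"] = "worst status across diversity measures"
            records.append(rec)
    frame = pd.DataFrame(records)
    front = ["population", "period", "label", "status", "direction"]
    frame = frame[front + [c for c in frame.columns if c not in front]]
    return IndicatorReport(rows=frame)
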