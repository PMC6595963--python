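"""Topography of selected regions: anterior proportions and DMN splits.

Turns a significance-based region selection into the headline summary: how
many selected regions are anterior, what percentage that is (half-up
rounding to one decimal, matching how such proportions are conventionally
printed), the same split restricted to DMN members and to non-members, and
the NC minus SCD difference of the anterior percentage at three levels
(whole brain, in DMN, out of DMN).  The "non-anterior" complement pools
posterior and subcortical regions.

Percentages are undefined (``None``), not zero, when the denominator is
empty.  Reports are pure functions of (selection, region table).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

from .atlas import RegionTable, classify_selection
from .stats import SelectionResult

logger = logging.getLogger(__name__)

LEVELS = ("whole_brain", "in_DMN", "out_DMN")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (so 43.45 -> 43.5, not banker's 43.4)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _pct(count: int, denom: int) -> float | None:
    if denom == 0:
        return None
    return round_half_up(100.0 * count / denom, 1)


@dataclass
class TopographyReport:
    """Anterior/DMN accounting of one selection."""

    group: str
    measure: str
    spec_label: str
    n_selected: int
    n_anterior: int
    pct_anterior: float | None
    n_dmn: int
    dmn_n_anterior: int
    dmn_pct_anterior: float | None
    n_non_dmn: int
    non_dmn_n_anterior: int
    non_dmn_pct_anterior: float | None

    @property
    def pct_other(self) -> float | None:
        """Complement of the anterior percentage (posterior + subcortical)."""
        if self.pct_anterior is None:
            return None
        return round_half_up(100.0 - self.pct_anterior, 1)

    @property
    def dmn_pct_other(self) -> float | None:
        if self.dmn_pct_anterior is None:
            return None
        return round_half_up(100.0 - self.dmn_pct_anterior, 1)


@dataclass
class GroupDifference:
    """NC minus SCD anterior percentage at one level."""

    level: str
    delta_pct: float


def build_report(selection: SelectionResult, table: RegionTable) -> TopographyReport:
    """Classify a selection into anterior counts at all three levels."""
    sel = set(selection.selected)
    whole = classify_selection(sel, table)
    in_dmn = [i for i in sel if table.region(i).dmn]
    out_dmn = [i for i in sel if not table.region(i).dmn]
    c_in = classify_selection(in_dmn, table)
    c_out = classify_selection(out_dmn, table)
    return TopographyReport(
        group=selection.group,
        measure=selection.measure,
        spec_label=selection.spec_label,
        n_selected=whole["n_selected"],
        n_anterior=whole["anterior"],
        pct_anterior=_pct(whole["anterior"], whole["n_selected"]),
        n_dmn=c_in["n_selected"],
        dmn_n_anterior=c_in["anterior"],
        dmn_pct_anterior=_pct(c_in["anterior"], c_in["n_selected"]),
        n_non_dmn=c_out["n_selected"],
        non_dmn_n_anterior=c_out["anterior"],
        non_dmn_pct_anterior=_pct(c_out["anterior"], c_out["n_selected"]),
    )


def group_difference(
    report_nc: TopographyReport, report_scd: TopographyReport
) -> list[GroupDifference]:
    """NC minus SCD anterior percentage at whole-brain / in-DMN / out-DMN.

    Levels where either group's percentage is undefined are omitted (with a
    logged reason).  Both reports must come from the same measure and
    threshold condition.
    """
    if (report_nc.measure, report_nc.spec_label) != (
        report_scd.measure, report_scd.spec_label
    ):
        raise ValueError("reports compare different measures or thresholds")
    pairs = {
        "whole_brain": (report_nc.pct_anterior, report_scd.pct_anterior),
        "in_DMN": (report_nc.dmn_pct_anterior, report_scd.dmn_pct_anterior),
        "out_DMN": (report_nc.non_dmn_pct_anterior, report_scd.non_dmn_pct_anterior),
    }
    out = []
    for level in LEVELS:
        a, b = pairs[level]
        if a is None or b is None:
            logger.info("level %s omitted: undefined percentage", level)
            continue
        out.append(GroupDifference(level, round_half_up(a - b, 1)))
    return out


def largest_difference(diffs: Sequence[GroupDifference]) -> GroupDifference:
    if not diffs:
        raise ValueError("no defined levels")
    return max(diffs, key=lambda d: d.delta_pct)


def validation_sweep(
    cohort,
    phenotypes,
    table: RegionTable,
    specs: Iterable | None = None,
    modes: Sequence[str] = ("static", "dynamic"),
    scores: Sequence[str] | None = None,
    alpha: float = 0.05,
    window_length: int = 25,
    step: int = 1,
):
    """Run the full pipeline under every (threshold, mode) condition.

    Defaults to the four validation thresholds (absolute r = 0.2 and 0.25;
    proportional sparsity = 0.2 and 0.25 on variance-stabilized weights)
    crossed with static and dynamic analysis.  One condition failing does
    not abort the sweep: its entry records the error.  Returns
    ``(results, stability)`` where ``results`` maps (mode, spec label) to a
    ConditionResult and ``stability`` summarizes the overlap of
    significant-region sets across conditions.
    """
    from .graphs import ThresholdSpec
    from .pipeline import run_condition, selection_overlap

    if specs is None:
        specs = (
            ThresholdSpec("absolute", 0.25),
            ThresholdSpec("absolute", 0.2),
            ThresholdSpec("proportional", 0.2, "variance_stabilized"),
            ThresholdSpec("proportional", 0.25, "variance_stabilized"),
        )
    results = {}
    for mode in modes:
        for spec in specs:
            key = (mode, spec.label)
            try:
                results[key] = run_condition(
                    cohort, phenotypes, table, spec, mode=mode,
                    scores=scores, alpha=alpha,
                    window_length=window_length, step=step,
                )
            except Exception as exc:  # noqa: BLE001 - sweep must not abort
                logger.warning("condition %s failed: %s", key, exc)
                results[key] = exc
    stability = selection_overlap(results)
    return results, stability
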