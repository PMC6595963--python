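"""End-to-end orchestration of one analysis condition.

A *condition* is a threshold specification crossed with an analysis mode:
``dynamic`` (per-subject hub probability over sliding windows) or
``static`` (per-subject Z-scored degree of the full-scan graph).  For each
condition the pipeline computes the per-subject, per-region measure, the
per-region NC-vs-SCD t-test table, the (region, score) regression tables
for the NC, SCD and pooled groups, the significance-based region
selections, and the anterior/DMN topography reports with their NC-SCD
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import RegionTable
from .connectivity import SubjectTimeSeries, sliding_windows
from .graphs import ThresholdSpec, hub_probability, static_centrality
from .stats import (DEFAULT_SCORES, SelectionResult, per_region_group_test,
                    regression_table, select_regions)
from .topography import (GroupDifference, TopographyReport, build_report,
                         group_difference)

ANALYSIS_GROUPS = ("NC", "SCD", "ALL")


def dynamic_measures(
    cohort: Sequence[SubjectTimeSeries],
    spec: ThresholdSpec,
    window_length: int = 25,
    step: int = 1,
) -> pd.DataFrame:
    """Per-subject hub-probability profiles as a (subjects x regions) frame."""
    rows = {}
    for ts in cohort:
        prof = hub_probability(sliding_windows(ts, window_length, step), spec)
        rows[ts.subject_id] = prof.prob
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = np.arange(1, frame.shape[1] + 1)
    return frame


def static_measures(
    cohort: Sequence[SubjectTimeSeries], spec: ThresholdSpec
) -> pd.DataFrame:
    """Per-subject full-scan Z-scored degree as a (subjects x regions) frame."""
    rows = {ts.subject_id: static_centrality(ts, spec).zscore for ts in cohort}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = np.arange(1, frame.shape[1] + 1)
    return frame


@dataclass
class ConditionResult:
    """Everything computed for one (threshold, mode) condition."""

    spec: ThresholdSpec
    mode: str
    measure_name: str
    measures: pd.DataFrame  # subjects x regions
    group_tests: pd.DataFrame
    regressions: Mapping[str, pd.DataFrame] = field(default_factory=dict)
    selections: Mapping[str, SelectionResult] = field(default_factory=dict)
    reports: Mapping[str, TopographyReport] = field(default_factory=dict)
    differences: Sequence[GroupDifference] = field(default_factory=tuple)

    @property
    def significant_regions(self) -> tuple[int, ...]:
        sig = self.group_tests.loc[self.group_tests["significant"], "region"]
        return tuple(int(r) for r in sig)


def run_condition(
    cohort: Sequence[SubjectTimeSeries],
    phenotypes: pd.DataFrame,
    table: RegionTable,
    spec: ThresholdSpec,
    mode: str = "dynamic",
    scores: Sequence[str] | None = None,
    alpha: float = 0.05,
    window_length: int = 25,
    step: int = 1,
    variant: str = "student",
) -> ConditionResult:
    """Full pipeline for one condition; see module docstring."""
    if mode not in ("static", "dynamic"):
        raise ValueError(f"mode must be 'static' or 'dynamic', got {mode!r}")
    if scores is None:
        scores = [s for s in DEFAULT_SCORES if s in phenotypes.columns]
    ids = [ts.subject_id for ts in cohort]
    if list(phenotypes["subject_id"]) != ids:
        raise ValueError("phenotype rows are not aligned with the cohort")
    if mode == "dynamic":
        measures = dynamic_measures(cohort, spec, window_length, step)
        measure_name = "hub_probability"
    else:
        measures = static_measures(cohort, spec)
        measure_name = "static_degree"
    groups = phenotypes["group"].to_numpy()
    tests = per_region_group_test(measures, groups, variant=variant, alpha=alpha)
    regressions, selections, reports = {}, {}, {}
    for g in ANALYSIS_GROUPS:
        reg = regression_table(measures, phenotypes, scores=scores, group=g)
        regressions[g] = reg
        selections[g] = select_regions(
            reg, alpha=alpha, measure=measure_name, spec_label=spec.label
        )
        reports[g] = build_report(selections[g], table)
    diffs = group_difference(reports["NC"], reports["SCD"])
    return ConditionResult(
        spec=spec, mode=mode, measure_name=measure_name, measures=measures,
        group_tests=tests, regressions=regressions, selections=selections,
        reports=reports, differences=tuple(diffs),
    )


def selection_overlap(results: Mapping) -> pd.DataFrame:
    """Pairwise overlap of significant-region sets across sweep conditions.

    For every pair of successful conditions, reports the sizes of the two
    group-test significant sets and of their intersection — the stability
    summary of the threshold-validation sweep.
    """
    ok = {k: v for k, v in results.items() if isinstance(v, ConditionResult)}
    rows = []
    keys = list(ok)
    for a_i, a in enumerate(keys):
        for b in keys[a_i + 1:]:
            sa, sb = set(ok[a].significant_regions), set(ok[b].significant_regions)
            rows.append({
                "condition_a": "/".join(a), "condition_b": "/".join(b),
                "n_a": len(sa), "n_b": len(sb),
                "n_overlap": len(sa & sb),
            })
    return pd.DataFrame(rows)
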