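"""Plain-text input/output.

The pipeline's contract starts at parcellated time series; everything is
tab-separated text or JSON so any parcellation tool can feed it:

* time-series TSV — header row of region abbreviations in atlas index
  order, then one row per volume;
* phenotype TSV — subject_id, group, age, sex, education plus one column
  per score;
* ground-truth JSON from the simulator;
* result writers for t-test tables, regression tables, selections and
  topography reports.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .atlas import RegionTable
from .connectivity import SubjectTimeSeries
from .stats import SelectionResult
from .topography import GroupDifference, TopographyReport


class FormatError(ValueError):
    """Raised on malformed input files, naming file and line."""


def _region_header(n_regions: int, table: RegionTable | None) -> list[str]:
    if table is not None and len(table) == n_regions:
        return table.abbreviations
    return [f"R{i:03d}" for i in range(1, n_regions + 1)]


def write_timeseries(path, ts: SubjectTimeSeries, table: RegionTable | None = None) -> None:
    header = _region_header(ts.n_regions, table)
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in ts.data:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_timeseries(path, tr_seconds: float = 2.0) -> SubjectTimeSeries:
    """Read one subject's time-series TSV; ragged or non-numeric rows are
    errors naming the file and line."""
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    n = len(header)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != n:
            raise FormatError(
                f"{path}: line {lineno}: expected {n} columns, found {len(cells)}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError:
            bad = next(c for c in cells if not _is_float(c))
            raise FormatError(
                f"{path}: line {lineno}: non-numeric cell {bad!r}"
            ) from None
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return SubjectTimeSeries(path.stem, np.array(rows), tr_seconds)


def _is_float(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def read_timeseries_dir(directory, tr_seconds: float = 2.0) -> list[SubjectTimeSeries]:
    directory = Path(directory)
    paths = sorted(directory.glob("*.tsv"))
    if not paths:
        raise FormatError(f"no .tsv time-series files found in {directory}")
    return [read_timeseries(p, tr_seconds) for p in paths]


def write_phenotypes(path, phenotypes: pd.DataFrame) -> None:
    phenotypes.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    required = {"subject_id", "group", "age", "sex", "education"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: phenotype table missing columns {sorted(missing)}")
    bad = frame.loc[~frame["group"].isin(("NC", "SCD"))]
    if len(bad):
        raise FormatError(
            f"{path}: unknown group {bad.iloc[0]['group']!r} for subject "
            f"{bad.iloc[0]['subject_id']}"
        )
    frame["subject_id"] = frame["subject_id"].astype(str)
    return frame


def match_cohort(
    cohort: Sequence[SubjectTimeSeries], phenotypes: pd.DataFrame
) -> tuple[list[SubjectTimeSeries], pd.DataFrame]:
    """Align time series with phenotype rows; mismatched ids are an error."""
    ts_ids = [ts.subject_id for ts in cohort]
    ph_ids = list(phenotypes["subject_id"])
    orphan_ts = sorted(set(ts_ids) - set(ph_ids))
    orphan_ph = sorted(set(ph_ids) - set(ts_ids))
    if orphan_ts or orphan_ph:
        parts = []
        if orphan_ts:
            parts.append(f"time series without phenotype row: {orphan_ts}")
        if orphan_ph:
            parts.append(f"phenotype rows without time series: {orphan_ph}")
        raise FormatError("; ".join(parts))
    order = {sid: k for k, sid in enumerate(ts_ids)}
    phen = phenotypes.sort_values("subject_id", key=lambda s: s.map(order))
    return list(cohort), phen.reset_index(drop=True)


# ---------------------------------------------------------------------------
# JSON helpers


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return super().default(o)


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")


def write_ground_truth(path, ground_truth: dict) -> None:
    write_json(path, ground_truth)


def read_ground_truth(path) -> dict:
    with open(path) as fh:
        gt = json.load(fh)
    for key in ("true_hub_prob", "state_sequences"):
        if key in gt:
            gt[key] = np.array(gt[key])
    if "expected_hub_prob" in gt:
        gt["expected_hub_prob"] = {
            g: np.array(v) for g, v in gt["expected_hub_prob"].items()
        }
    return gt


def write_selection(path, selection: SelectionResult) -> None:
    write_json(path, {
        "group": selection.group,
        "measure": selection.measure,
        "threshold": selection.spec_label,
        "alpha": selection.alpha,
        "selected": sorted(selection.selected),
        "min_p": {str(k): v for k, v in sorted(selection.min_p.items())},
    })


def report_row(report: TopographyReport) -> dict:
    return dataclasses.asdict(report)


def write_reports(path, reports: Iterable[TopographyReport]) -> None:
    write_json(path, [report_row(r) for r in reports])


def write_differences(path, diffs: Iterable[GroupDifference]) -> None:
    write_json(path, [dataclasses.asdict(d) for d in diffs])
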