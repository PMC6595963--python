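"""Group-level inference on per-region centrality measures.

Three building blocks:

* per-region two-sample t-tests on hub probability (or static Z-degree)
  between the NC and SCD groups, uncorrected, two-tailed;
* the same t-test computed from printed summary statistics
  (mean, sd, n per group), used to recompute demographic-table p-values;
* one ordinary-least-squares regression per (region, score) pair with the
  centrality measure as the predictor of interest and age, sex and
  education as nuisance covariates; the readout is the standardized beta
  of the measure and its two-tailed p-value.

A region is *selected* for a group when the minimum over scores of its
regression p-values is below alpha (default 0.05, uncorrected — one test
per region and score, no multiplicity correction; a Benjamini-Hochberg
option exists but is off by default).  Sex is coded M=0, F=1 (the p-value
is invariant to the coding).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

DEFAULT_SCORES = ("AVLT-I", "AVLT-D", "AVLT-R", "MMSE", "MoCA", "CDT")
ALL_SCORES = DEFAULT_SCORES + ("CDR", "CES-DS", "HIS", "ADL")
COVARIATES = ("age", "sex", "education")


class StatsError(ValueError):
    """Raised on invalid inputs to the inference routines."""


class CollinearityError(StatsError):
    """Raised when regression predictors are exactly collinear."""


@dataclass
class PhenotypeRecord:
    """One subject's group label, demographics and neuropsychological scores."""

    subject_id: str
    group: str
    age: float
    sex: str  # "M" or "F"
    education: float
    scores: Mapping[str, float]

    def __post_init__(self):
        if self.group not in ("NC", "SCD"):
            raise StatsError(f"group must be NC or SCD, got {self.group!r}")
        if self.sex not in ("M", "F"):
            raise StatsError(f"sex must be M or F, got {self.sex!r}")


def records_to_frame(records: Iterable[PhenotypeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "group": r.group, "age": r.age,
               "sex": r.sex, "education": r.education}
        row.update(r.scores)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[PhenotypeRecord]:
    meta = {"subject_id", "group", "age", "sex", "education"}
    score_cols = [c for c in frame.columns if c not in meta]
    return [
        PhenotypeRecord(
            subject_id=str(row["subject_id"]), group=row["group"],
            age=float(row["age"]), sex=row["sex"],
            education=float(row["education"]),
            scores={c: float(row[c]) for c in score_cols},
        )
        for _, row in frame.iterrows()
    ]


@dataclass
class RegressionRecord:
    """Measure coefficient of one (region, score) regression."""

    region: int
    score: str
    beta_std: float
    p: float
    n: int
    flagged: bool = False
    reason: str = ""


@dataclass
class SelectionResult:
    """Regions whose centrality measure relates to any configured score."""

    group: str  # NC, SCD or ALL
    measure: str  # hub_probability or static_degree
    selected: tuple[int, ...]
    alpha: float
    min_p: Mapping[int, float] = field(default_factory=dict)
    spec_label: str = ""


# ---------------------------------------------------------------------------
# t-tests


def t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    variant: str = "student",
) -> tuple[float, float]:
    """Two-sample t-test from group summaries; returns (t, two-tailed p).

    ``variant="student"`` pools the variances (df = n1 + n2 - 2);
    ``"welch"`` uses the unequal-variance form.  Degenerate zero-variance
    input yields (0, 1) when the means agree and (inf, 0) when they differ.
    """
    if sd1 < 0 or sd2 < 0:
        raise StatsError("standard deviations must be nonnegative")
    if n1 < 2 or n2 < 2:
        raise StatsError("need n >= 2 per group")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, 1.0
        return float(np.sign(mean1 - mean2)) * np.inf, 0.0
    res = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "student")
    )
    return float(res.statistic), float(res.pvalue)


def per_region_group_test(
    measures: np.ndarray | pd.DataFrame,
    groups: Sequence[str],
    variant: str = "student",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region two-sample t-test of a centrality measure, NC vs SCD.

    ``measures`` is (n_subjects, n_regions); ``groups`` holds "NC"/"SCD" per
    subject.  Returns one row per region with columns ``region``,
    ``mean_nc``, ``mean_scd``, ``t``, ``p``, ``significant`` and
    ``degenerate`` (True where both groups have zero variance, leaving the
    p-value undefined).  Uncorrected, two-tailed.
    """
    X = measures.to_numpy() if isinstance(measures, pd.DataFrame) else np.asarray(measures, float)
    groups = np.asarray(groups)
    nc, scd = X[groups == "NC"], X[groups == "SCD"]
    if len(nc) < 2 or len(scd) < 2:
        raise StatsError("need at least 2 subjects per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.ttest_ind(nc, scd, axis=0, equal_var=(variant == "student"))
    t, p = np.asarray(res.statistic, float), np.asarray(res.pvalue, float)
    degenerate = (nc.std(axis=0) == 0) & (scd.std(axis=0) == 0)
    out = pd.DataFrame({
        "region": np.arange(1, X.shape[1] + 1),
        "mean_nc": nc.mean(axis=0),
        "mean_scd": scd.mean(axis=0),
        "t": t,
        "p": p,
        "degenerate": degenerate,
    })
    out.loc[degenerate, ["t", "p"]] = np.nan
    out["significant"] = out["p"] < alpha
    return out


# ---------------------------------------------------------------------------
# regressions


def _design_matrix(frame: pd.DataFrame, measure: np.ndarray) -> pd.DataFrame:
    X = pd.DataFrame({
        "measure": np.asarray(measure, float),
        "age": frame["age"].to_numpy(float),
        "sex": (frame["sex"].to_numpy() == "F").astype(float),
        "education": frame["education"].to_numpy(float),
    })
    return X


def _find_collinear_pair(X: pd.DataFrame) -> tuple[str, str] | None:
    cols = [c for c in X.columns if X[c].std() > 0]
    if len(cols) >= 2:
        C = np.corrcoef(X[cols].to_numpy().T)
        for a in range(len(cols)):
            for b in range(a + 1, len(cols)):
                if abs(C[a, b]) > 1 - 1e-12:
                    return cols[a], cols[b]
    return None


def region_score_regression(
    measures: np.ndarray | pd.DataFrame,
    phenotypes: pd.DataFrame,
    region: int,
    score: str,
) -> RegressionRecord:
    """OLS of one score on one region's measure plus age/sex/education.

    ``measures`` is (n_subjects, n_regions) aligned row-wise with
    ``phenotypes``; ``region`` is 1-based.  Reports the measure
    coefficient's standardized beta (coefficient * sd(measure)/sd(score))
    and its two-tailed p-value.  A zero-variance measure yields a flagged
    record (excluded from selection); exact collinearity among predictors
    raises, naming the collinear pair.
    """
    X_all = measures.to_numpy() if isinstance(measures, pd.DataFrame) else np.asarray(measures, float)
    if len(X_all) != len(phenotypes):
        raise StatsError("measures and phenotypes are not aligned")
    if score not in phenotypes.columns:
        raise StatsError(f"score {score!r} missing from phenotype table")
    m = X_all[:, int(region) - 1]
    y = phenotypes[score].to_numpy(float)
    n = len(y)
    if np.isnan(y).any() or np.isnan(m).any():
        raise StatsError(f"missing values in score {score!r} or measure")
    if np.ptp(m) == 0:
        return RegressionRecord(int(region), score, np.nan, np.nan, n,
                                flagged=True, reason="zero-variance measure")
    if np.ptp(y) == 0:
        return RegressionRecord(int(region), score, np.nan, np.nan, n,
                                flagged=True, reason="zero-variance score")
    X = _design_matrix(phenotypes, m)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        pair = _find_collinear_pair(X)
        if pair is not None:
            raise CollinearityError(
                f"predictors {pair[0]!r} and {pair[1]!r} are exactly collinear"
            )
        raise CollinearityError("design matrix is rank-deficient")
    if n < design.shape[1] + 2:
        raise StatsError(
            f"need at least {design.shape[1] + 2} subjects, got {n}"
        )
    fit = sm.OLS(y, design).fit()
    beta_std = float(fit.params["measure"] * m.std() / y.std())
    return RegressionRecord(int(region), score, beta_std,
                            float(fit.pvalues["measure"]), n)


def regression_table(
    measures: np.ndarray | pd.DataFrame,
    phenotypes: pd.DataFrame,
    scores: Sequence[str] = DEFAULT_SCORES,
    group: str = "ALL",
) -> pd.DataFrame:
    """All (region, score) regressions for one group as a DataFrame.

    ``group`` of "NC"/"SCD" restricts to that group's subjects; "ALL" uses
    everyone (with no group term, so group differences are absorbed into
    the residual).
    """
    X = measures.to_numpy() if isinstance(measures, pd.DataFrame) else np.asarray(measures, float)
    if group != "ALL":
        keep = (phenotypes["group"] == group).to_numpy()
        X, phen = X[keep], phenotypes.loc[keep].reset_index(drop=True)
    else:
        phen = phenotypes.reset_index(drop=True)
    rows = []
    for region in range(1, X.shape[1] + 1):
        for score in scores:
            rec = region_score_regression(X, phen, region, score)
            rows.append({
                "group": group, "region": rec.region, "score": rec.score,
                "beta_std": rec.beta_std, "p": rec.p, "n": rec.n,
                "flagged": rec.flagged, "reason": rec.reason,
            })
    return pd.DataFrame(rows)


def select_regions(
    records: pd.DataFrame,
    alpha: float = 0.05,
    measure: str = "hub_probability",
    fdr: bool = False,
    spec_label: str = "",
) -> SelectionResult:
    """Regions with min-over-scores regression p < alpha (strict).

    ``records`` is a regression table for one group; flagged records are
    ignored.  ``fdr=True`` applies Benjamini-Hochberg across all
    region-score tests before selection (off by default, matching the
    uncorrected procedure).
    """
    if not 0 < alpha < 1:
        raise StatsError("alpha must be in (0, 1)")
    groups = records["group"].unique()
    if len(groups) != 1:
        raise StatsError("records must come from a single group")
    ok = records.loc[~records["flagged"]].copy()
    if fdr and len(ok):
        from statsmodels.stats.multitest import multipletests
        ok["p"] = multipletests(ok["p"].to_numpy(), method="fdr_bh")[1]
    min_p = ok.groupby("region")["p"].min()
    selected = tuple(int(r) for r in min_p.index[min_p < alpha])
    return SelectionResult(
        group=str(groups[0]), measure=measure, selected=selected,
        alpha=alpha, min_p={int(k): float(v) for k, v in min_p.items()},
        spec_label=spec_label,
    )
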