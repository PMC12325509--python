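"""Cohort filtering and two-group statistics.

Implements the study-design layer of the pipeline: inclusion/exclusion rules
for postmortem cases, an automated normality gate (Shapiro-Wilk replacing
visual QQ-plot inspection), Student's t-test for parametric variables and
the Wilcoxon rank-sum (Mann-Whitney) test for nonparametric ones, plus
descriptive subgroup tables (asphyxia subtypes are too small for testing, so
they are summarised without p-values).

Conventions: quartiles use linear interpolation (numpy default, "type 7");
SD uses the n-1 denominator; all tests are two-sided; the rank-sum test uses
the exact null distribution for small tie-free samples (min group size <= 8)
and otherwise a normal approximation with tie and continuity corrections;
the t-test pools variances by default with Welch available by flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_ct import ParameterError

log = logging.getLogger(__name__)

GROUPS = ("HA", "CH", "LS", "MS", "SM", "control")
ASPHYXIA_SUBTYPES = ("HA", "CH", "LS", "MS", "SM")

#: control causes of death that severely affect lung density
EXCLUDED_CONTROL_CAUSES = frozenset(
    {"exsanguination", "burn", "cold_exposure", "opioid_intoxication"})

COHORT_CSV_COLUMNS = [
    "case_id", "group", "age", "sex", "height_cm", "weight_kg", "pmi_days",
    "putrefaction", "chest_trauma", "lung_disease", "hospitalized",
    "control_cause",
]


@dataclass
class CaseRecord:
    """One individual: metadata plus (optionally) a densitometry result."""

    case_id: str
    group: str                      # HA / CH / LS / MS / SM / control
    age: float
    sex: str = "M"
    height_cm: float = float("nan")
    weight_kg: float = float("nan")
    pmi_days: float = 0.0
    putrefaction: str = "none"
    chest_trauma: bool = False
    lung_disease: bool = False
    hospitalized: bool = False
    control_cause: str | None = None
    densitometry: object | None = None   # DensitometryResult

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ParameterError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.age < 0 or self.pmi_days < 0:
            raise ParameterError("age and PMI must be non-negative")

    @property
    def is_control(self) -> bool:
        return self.group == "control"


def apply_inclusion_criteria(records):
    """Filter records by the study's exclusion rules.

    Returns ``(included, exclusion_log)`` where the log holds one
    ``(case_id, reason)`` entry per excluded record, with the first matching
    reason in the documented priority order.  Idempotent by construction.
    """
    included, excluded = [], []
    for r in records:
        reason = None
        if r.pmi_days > 5:
            reason = "PMI > 5 days"
        elif r.age > 80:
            reason = "age above 80"
        elif r.age < 16:
            reason = "age below 16"
        elif r.chest_trauma:
            reason = "penetrating chest injury"
        elif r.lung_disease:
            reason = "prior or current lung disease"
        elif r.putrefaction == "severe":
            reason = "severe putrefaction"
        elif r.is_control and (r.control_cause in EXCLUDED_CONTROL_CAUSES):
            reason = f"control cause of death: {r.control_cause}"
        elif r.is_control and r.hospitalized:
            reason = "death following hospitalization or intensive care"
        if reason is None:
            included.append(r)
        else:
            excluded.append((r.case_id, reason))
            log.info("excluded %s: %s", r.case_id, reason)
    return included, excluded


def assess_normality(values, alpha: float = 0.05) -> str:
    """Shapiro-Wilk gate: ``"parametric"`` if p >= alpha, else ``"nonparametric"``.

    Degenerate inputs (n < 3 or constant data) default to nonparametric with
    a logged warning, since the test is undefined there.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        log.warning("normality check with n=%d < 3; defaulting to nonparametric", v.size)
        return "nonparametric"
    if np.ptp(v) == 0:
        log.warning("normality check on constant data; defaulting to nonparametric")
        return "nonparametric"
    stat, p = stats.shapiro(v)
    route = "parametric" if p >= alpha else "nonparametric"
    log.debug("Shapiro-Wilk W=%.4f p=%.4g -> %s", stat, p, route)
    return route


def summarize_group(values, style: str) -> dict:
    """Mean/SD (parametric) or median/Q1/Q3 (nonparametric) summary."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ParameterError("cannot summarise an empty group")
    if style == "parametric":
        return {"n": int(v.size), "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else None}
    if style == "nonparametric":
        q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
        return {"n": int(v.size), "median": float(med),
                "q1": float(q1), "q3": float(q3)}
    raise ParameterError(f"unknown summary style {style!r}")


@dataclass
class ComparisonResult:
    """Outcome of one two-group comparison."""

    method: str                  # "t_test" or "wilcoxon"
    statistic: float
    p_value: float
    group_summaries: tuple[dict, dict]
    n_per_group: tuple[int, int]
    variant: str | None = None   # pooled / welch / exact / asymptotic
    df: float | None = None      # t-tests only

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ParameterError(f"p-value {self.p_value} outside [0, 1]")


def _wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> ComparisonResult:
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if min(a.size, b.size) <= 8 and not ties:
        method = "exact"
    else:
        method = "asymptotic"   # scipy applies tie + continuity corrections
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ComparisonResult(
        method="wilcoxon", statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_summaries=(summarize_group(a, "nonparametric"),
                         summarize_group(b, "nonparametric")),
        n_per_group=(int(a.size), int(b.size)), variant=method)


def compare_groups(a, b, mode: str = "auto", alpha: float = 0.05,
                   t_variant: str = "pooled") -> ComparisonResult:
    """Two-sided two-group comparison.

    ``auto`` uses Student's t only when both groups pass the Shapiro-Wilk
    gate, otherwise the Wilcoxon rank-sum test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be nonempty")
    if mode == "auto":
        if min(a.size, b.size) < 3:
            raise ParameterError("auto mode requires n >= 3 per group")
        parametric = (assess_normality(a, alpha) == "parametric"
                      and assess_normality(b, alpha) == "parametric")
        mode = "t_test" if parametric else "wilcoxon"
    if mode == "wilcoxon":
        return _wilcoxon_rank_sum(a, b)
    if mode == "t_test":
        if a.size < 2 or b.size < 2:
            raise ParameterError("t-test requires n >= 2 per group")
        res = stats.ttest_ind(a, b, equal_var=(t_variant == "pooled"))
        return ComparisonResult(
            method="t_test", statistic=float(res.statistic),
            p_value=float(res.pvalue),
            group_summaries=(summarize_group(a, "parametric"),
                             summarize_group(b, "parametric")),
            n_per_group=(int(a.size), int(b.size)), variant=t_variant,
            df=float(res.df))
    raise ParameterError(f"unknown comparison mode {mode!r}")


def ttest_from_summary(mean1, sd1, n1, mean2, sd2, n2,
                       variant: str = "pooled") -> ComparisonResult:
    """Two-sample t-test from printed summary statistics (mean, SD, n)."""
    if n1 < 2 or n2 < 2:
        raise ParameterError("summary t-test requires n >= 2 per group")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ParameterError("SDs must be non-negative and not both zero")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=(variant == "pooled"))
    if variant == "pooled":
        df = float(n1 + n2 - 2)
    else:  # Welch-Satterthwaite
        va, vb = sd1 ** 2 / n1, sd2 ** 2 / n2
        df = (va + vb) ** 2 / (va ** 2 / (n1 - 1) + vb ** 2 / (n2 - 1))
    return ComparisonResult(
        method="t_test", statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_summaries=({"n": int(n1), "mean": float(mean1), "sd": float(sd1)},
                         {"n": int(n2), "mean": float(mean2), "sd": float(sd2)}),
        n_per_group=(int(n1), int(n2)), variant=variant, df=df)


_ENDPOINT_FIELDS = ["laa950", "laa910", "perc15", "pd15", "volume_ml"]


def subgroup_summary(records) -> pd.DataFrame:
    """Descriptive per-subtype table (n, median + IQR per endpoint); no p-values.

    Empty subtypes are omitted; a single-case subtype reports its own value
    as a degenerate median/IQR.
    """
    rows = []
    for sub in ASPHYXIA_SUBTYPES:
        cases = [r for r in records if r.group == sub and r.densitometry is not None]
        if not cases:
            continue
        row = {"subgroup": sub, "n": len(cases)}
        for f in _ENDPOINT_FIELDS:
            vals = [getattr(r.densitometry, f) for r in cases]
            s = summarize_group(vals, "nonparametric")
            row[f"{f}_median"] = s["median"]
            row[f"{f}_q1"] = s["q1"]
            row[f"{f}_q3"] = s["q3"]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def records_to_dataframe(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in COHORT_CSV_COLUMNS}
        if r.densitometry is not None:
            row.update(r.densitometry.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def dataframe_to_records(df: pd.DataFrame):
    from .densitometry import DensitometryResult  # deferred: avoid cycle
    records = []
    for _, row in df.iterrows():
        dens = None
        if "laa950_pct" in row and pd.notna(row.get("laa950_pct")):
            dens = DensitometryResult(
                laa950=float(row["laa950_pct"]), laa910=float(row["laa910_pct"]),
                perc15=float(row["perc15_hu"]), pd15=float(row["pd15_gl"]),
                volume_ml=float(row["volume_ml"]), n_voxels=int(row["n_voxels"]),
                mean_hu=float(row["mean_hu"]))
        cause = row.get("control_cause")
        records.append(CaseRecord(
            case_id=str(row["case_id"]), group=str(row["group"]),
            age=float(row["age"]), sex=str(row.get("sex", "M")),
            height_cm=float(row.get("height_cm", float("nan"))),
            weight_kg=float(row.get("weight_kg", float("nan"))),
            pmi_days=float(row.get("pmi_days", 0.0)),
            putrefaction=str(row.get("putrefaction", "none")),
            chest_trauma=bool(row.get("chest_trauma", False)),
            lung_disease=bool(row.get("lung_disease", False)),
            hospitalized=bool(row.get("hospitalized", False)),
            control_cause=None if pd.isna(cause) else str(cause),
            densitometry=dens))
    return records


def write_cohort_csv(records, path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)


def read_cohort_csv(path):
    return dataframe_to_records(pd.read_csv(path))
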