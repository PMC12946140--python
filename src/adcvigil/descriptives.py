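"""Baseline accounting: stratified demographic/outcome tables, group
comparisons and onset-time summaries.

Percentages are computed with half-up rounding so that any printed-style
cell "n (xx.xx)" recomputes exactly from its counts.  Continuous variables
are gated through Shapiro-Wilk: when both samples look normal a two-sample
t-test is used, otherwise Mann-Whitney U; summaries are median (Q1, Q3)
with linear-interpolation quantiles.  Onset time is the interval in days
from the earliest suspect-ADC therapy start to the earliest recorded event
date; missing dates and negative intervals are excluded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from adcvigil.report_store import CaseReport, OutcomeCode, ReporterType, Sex
from adcvigil.stratify_contingency import Stratum, report_in_stratum

__all__ = [
    "percent",
    "cramers_v",
    "OnsetSummary",
    "onset_times",
    "group_compare_continuous",
    "age_bin",
    "AGE_BINS",
    "descriptive_tallies",
    "baseline_table",
]


def percent(numerator: int, denominator: int, dp: int = 2) -> float:
    """``100 * numerator / denominator`` rounded half-up to ``dp`` decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    quantum = Decimal(1).scaleb(-dp)
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def cramers_v(table: Sequence[Sequence[int]] | np.ndarray) -> tuple[float, float]:
    """Cramer's V = sqrt(chi2 / (N * min(r-1, c-1))) with the chi-square
    p-value (no continuity correction).  Degenerate margins give (nan, nan)."""
    obs = np.asarray(table, dtype=float)
    if obs.min() < 0:
        raise ValueError("negative count")
    n = obs.sum()
    if n <= 0:
        raise ValueError("empty table")
    # drop all-zero rows/columns: they carry no information and break chi2
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    r, c = obs.shape
    if r < 2 or c < 2:
        return (float("nan"), float("nan"))
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    v = float(np.sqrt(chi2 / (n * min(r - 1, c - 1))))
    return (v, float(p))


@dataclass
class OnsetSummary:
    """Onset-time distribution for one stratum after exclusions."""

    n_used: int
    n_excluded_missing: int
    n_excluded_implausible: int
    median: float
    q1: float
    q3: float

    def as_dict(self) -> dict:
        return {
            "n_used": self.n_used,
            "n_excluded_missing": self.n_excluded_missing,
            "n_excluded_implausible": self.n_excluded_implausible,
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
        }


def _onset_days(report: CaseReport, stratum: Stratum) -> float | None | str:
    """Days from earliest member-drug therapy start to earliest event date;
    'missing' when either date is absent."""
    starts = [
        d.therapy_start_date
        for d in report.drugs
        if d.is_suspect()
        and d.therapy_start_date is not None
        and not stratum.member_drugs.isdisjoint({_norm(d.drug_name)})
    ]
    if not starts or report.event_date is None:
        return "missing"
    return float((report.event_date - min(starts)).days)


def _norm(name: str) -> str:
    from adcvigil.report_store import normalize_drug_name

    return normalize_drug_name(name)


def onset_times(reports: Sequence[CaseReport], stratum: Stratum) -> OnsetSummary:
    """Summarize onset time over the stratum's exposed reports.

    Exclusions: missing therapy-start or event date; negative (implausible)
    intervals.  Quantiles use linear interpolation between order statistics.
    """
    used: list[float] = []
    n_missing = 0
    n_implausible = 0
    for r in reports:
        if not report_in_stratum(r, stratum):
            continue
        ot = _onset_days(r, stratum)
        if ot == "missing":
            n_missing += 1
        elif ot < 0:
            n_implausible += 1
        else:
            used.append(ot)
    if not used:
        return OnsetSummary(0, n_missing, n_implausible, float("nan"), float("nan"), float("nan"))
    arr = np.asarray(used)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return OnsetSummary(len(used), n_missing, n_implausible, float(med), float(q1), float(q3))


def group_compare_continuous(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05, gate_max_n: int = 5000
) -> tuple[str, float, float]:
    """Two-group comparison with a Shapiro-Wilk normality gate.

    Both samples normal at ``alpha`` (gate on at most ``gate_max_n`` values)
    -> two-sample t-test; otherwise Mann-Whitney U with normal approximation
    and tie correction.  Returns (test name, statistic, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")

    def _normal(sample: np.ndarray) -> bool:
        if sample.size < 3:
            return False
        sub = sample[:gate_max_n]
        if np.ptp(sub) == 0:
            return False
        return stats.shapiro(sub).pvalue > alpha

    if _normal(x) and _normal(y):
        res = stats.ttest_ind(x, y)
        return ("t", float(res.statistic), float(res.pvalue))
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return ("mannwhitney", float(res.statistic), float(res.pvalue))


#: age bins: <18 | [18, 65) | [65, 85] | >85 (disjoint, exhaustive)
AGE_BINS = ("<18", "18-64", "65-85", ">85", "unspecified")


def age_bin(age_years: float | None) -> str:
    if age_years is None:
        return "unspecified"
    if age_years < 18:
        return "<18"
    if age_years < 65:
        return "18-64"
    if age_years <= 85:
        return "65-85"
    return ">85"


def descriptive_tallies(
    reports: Sequence[CaseReport], strata: Sequence[Stratum] | None = None
) -> dict[str, pd.Series | pd.DataFrame | int]:
    """Report-level and PT-level counts with demographic breakdowns.

    Returns report counts by sex, age bin, outcome, reporter type, country
    and receipt year, the total report count and the total PT-level event
    count (sum over reports of distinct PTs — the two units are deliberately
    separate).  With ``strata``, adds per-stratum report and PT-level counts.
    """
    rows = pd.DataFrame(
        {
            "sex": [r.sex.value for r in reports],
            "age_bin": [age_bin(r.age_years) for r in reports],
            "reporter": [r.reporter_type.value for r in reports],
            "serious": ["serious" if r.serious else "non_serious" for r in reports],
            "country": [r.country or "unspecified" for r in reports],
            "year": [r.receipt_date.year if r.receipt_date else 0 for r in reports],
            "n_pts": [len(set(r.events)) for r in reports],
        }
    )
    out: dict[str, pd.Series | pd.DataFrame | int] = {
        "n_reports": len(reports),
        "n_pt_level_events": int(rows["n_pts"].sum()),
        "by_sex": rows["sex"].value_counts(),
        "by_age_bin": rows["age_bin"].value_counts().reindex(AGE_BINS, fill_value=0),
        "by_reporter": rows["reporter"].value_counts(),
        "by_seriousness": rows["serious"].value_counts(),
        "by_country": rows["country"].value_counts(),
        "by_year": rows["year"].value_counts().sort_index(),
    }
    outcome_counts = {
        o.value: sum(1 for r in reports if o in r.outcomes) for o in OutcomeCode
    }
    out["by_outcome"] = pd.Series(outcome_counts)
    if strata is not None:
        per = []
        for s in strata:
            exposed = [r for r in reports if report_in_stratum(r, s)]
            per.append(
                {
                    "kind": s.kind,
                    "stratum": s.label,
                    "n_reports": len(exposed),
                    "n_pt_level_events": sum(len(set(r.events)) for r in exposed),
                }
            )
        out["by_stratum"] = pd.DataFrame(per)
    return out


def baseline_table(
    reports: Sequence[CaseReport], strata: Sequence[Stratum], dp: int = 2
) -> pd.DataFrame:
    """Table-1-style baseline: per-stratum "n (%)" for sex, age bin,
    seriousness and outcomes, with Cramer's V + p per variable, plus
    continuous age and onset-time summaries.

    Long format: one row per (variable, level) with per-stratum count and
    percentage columns.  Percentages are within-stratum, of the stratum's
    report total.
    """
    groups = {s.label: [r for r in reports if report_in_stratum(r, s)] for s in strata}
    totals = {label: len(rs) for label, rs in groups.items()}

    def levels_of(var: str, extractor) -> dict[str, dict[str, int]]:
        counts: dict[str, dict[str, int]] = {}
        for label, rs in groups.items():
            for r in rs:
                for level in extractor(r):
                    counts.setdefault(level, {}).setdefault(label, 0)
                    counts[level][label] += 1
        return counts

    variables = {
        "sex": lambda r: [r.sex.value],
        "age_bin": lambda r: [age_bin(r.age_years)],
        "seriousness": lambda r: ["serious" if r.serious else "non_serious"],
        "outcome": lambda r: [o.value for o in r.outcomes],
    }
    records = []
    for var, extract in variables.items():
        counts = levels_of(var, extract)
        level_names = sorted(counts)
        # association statistic over the full level x stratum count matrix
        mat = [[counts[lv].get(label, 0) for label in groups] for lv in level_names]
        v, p = cramers_v(mat) if len(level_names) >= 2 and len(groups) >= 2 else (float("nan"), float("nan"))
        for lv in level_names:
            rec: dict = {"variable": var, "level": lv, "cramers_v": v, "p": p}
            for label in groups:
                n = counts[lv].get(label, 0)
                rec[f"{label}_n"] = n
                rec[f"{label}_pct"] = percent(n, totals[label], dp) if totals[label] else float("nan")
            records.append(rec)

    # continuous rows: age and onset time as median (Q1, Q3)
    for var, values_of in (
        ("age_years", lambda rs: [r.age_years for r in rs if r.age_years is not None]),
    ):
        rec = {"variable": var, "level": "median_q1_q3", "cramers_v": float("nan"), "p": float("nan")}
        for label, rs in groups.items():
            vals = values_of(rs)
            if vals:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                rec[f"{label}_n"] = len(vals)
                rec[f"{label}_pct"] = float("nan")
                rec[f"{label}_summary"] = f"{med:g} ({q1:g}, {q3:g})"
            else:
                rec[f"{label}_n"] = 0
                rec[f"{label}_summary"] = ""
        records.append(rec)
    strata_by_label = {s.label: s for s in strata}
    rec = {"variable": "onset_days", "level": "median_q1_q3", "cramers_v": float("nan"), "p": float("nan")}
    for label in groups:
        summ = onset_times(reports, strata_by_label[label])
        rec[f"{label}_n"] = summ.n_used
        rec[f"{label}_pct"] = float("nan")
        rec[f"{label}_summary"] = (
            f"{summ.median:g} ({summ.q1:g}, {summ.q3:g})" if summ.n_used else ""
        )
    records.append(rec)
    return pd.DataFrame.from_records(records)
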