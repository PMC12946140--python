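"""Consensus signal detection, prioritization and the FDR sensitivity layer.

The multi-method consensus criterion (MCC) flags a stratum-event pair as a
positive signal only when all four estimators (ROR, PRR, IC, EBGM) meet
their thresholds simultaneously.  Positive signals are ranked by ROR within
each stratum and the top 20 are designated "strong signals" (a stratum whose
total positive count is small keeps all of them).  As a sensitivity layer,
every pair gets a two-sided Fisher exact p-value, Benjamini-Hochberg
adjusted within one stratification scheme; the concordance report compares
the MCC set against its FDR-significant subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from adcvigil.dispro_engine import (
    AlgorithmConfig,
    GammaPoissonPrior,
    ebgm_stats,
    fit_ebgm_prior,
    ic_stats,
    prr_stats,
    ror_stats,
)
from adcvigil.report_store import CaseReport, ComponentRegistry, MeddraMap
from adcvigil.stratify_contingency import KINDS, ContingencyTable, build_strata, tabulate

log = logging.getLogger(__name__)

__all__ = [
    "SignalFrame",
    "StrongSignalSet",
    "ConcordanceReport",
    "AnalysisResult",
    "screen_tables",
    "apply_mcc",
    "prioritize",
    "fisher_exact",
    "fisher_exact_batch",
    "bh_adjust",
    "concordance",
    "analyze_reports",
]

#: columns carried by every screened signal row
SIGNAL_COLUMNS = [
    "kind", "stratum", "item", "a", "b", "c", "d", "n", "expected",
    "ror", "ror_lo", "ror_hi", "prr", "chi2", "ic", "ic025", "ebgm", "eb05",
    "flag_ror", "flag_prr", "flag_ic", "flag_ebgm", "mcc", "fisher_p", "q",
]

SignalFrame = pd.DataFrame  # alias: a DataFrame with SIGNAL_COLUMNS


# --------------------------------------------------------------------------
# Fisher exact (two-sided, point-probability method)


def fisher_exact(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p for one table (sum of hypergeometric
    outcomes no more probable than the observed one).  Degenerate margins
    give p = 1."""
    if t.degenerate or (t.b + t.d) == 0 or (t.c + t.d) == 0:
        return 1.0
    return float(stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")[1])


def fisher_exact_batch(a, b, c, d, chunk: int = 4096) -> np.ndarray:
    """Vectorized two-sided Fisher exact p-values by full hypergeometric
    enumeration of each table's support (point-probability method)."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    n = a + b + c + d
    K = a + c          # event margin
    m = a + b          # stratum margin
    out = np.ones(a.shape, dtype=float)
    ok = (K > 0) & (K < n) & (m > 0) & (m < n)
    idx = np.flatnonzero(ok)
    from scipy.special import gammaln

    def _log_pmf(k, n_s, K_s, m_s):
        # log C(K,k) + log C(N-K, m-k) - log C(N, m)
        return (
            gammaln(K_s + 1) - gammaln(k + 1) - gammaln(K_s - k + 1)
            + gammaln(n_s - K_s + 1) - gammaln(m_s - k + 1) - gammaln(n_s - K_s - m_s + k + 1)
            - (gammaln(n_s + 1) - gammaln(m_s + 1) - gammaln(n_s - m_s + 1))
        )

    for start in range(0, idx.size, chunk):
        sl = idx[start : start + chunk]
        n_s, K_s, m_s, a_s = n[sl], K[sl], m[sl], a[sl]
        k_lo = np.maximum(0, m_s + K_s - n_s)
        k_hi = np.minimum(m_s, K_s)
        width = int((k_hi - k_lo).max()) + 1
        k = k_lo[:, None] + np.arange(width)[None, :]
        valid = k <= k_hi[:, None]
        logpmf = _log_pmf(
            np.where(valid, k, k_lo[:, None]), n_s[:, None], K_s[:, None], m_s[:, None]
        )
        pmf = np.where(valid, np.exp(logpmf), 0.0)
        p_obs = np.exp(_log_pmf(a_s, n_s, K_s, m_s))
        take = pmf <= p_obs[:, None] * (1 + 1e-7)
        out[sl] = np.minimum((pmf * take).sum(axis=1), 1.0)
    return out


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------------
# screening


def screen_tables(
    tables: SignalFrame,
    cfg: AlgorithmConfig = AlgorithmConfig(),
    prior: GammaPoissonPrior | None = None,
) -> SignalFrame:
    """Attach all four estimators, flags, MCC, Fisher p and q to a table
    frame produced by :func:`adcvigil.stratify_contingency.tabulate`.

    ``prior`` is the fitted gamma-Poisson mixture; when ``None`` it is fitted
    on the rows of ``tables`` themselves.
    """
    df = tables.copy()
    a, b, c, d = (df[k].to_numpy() for k in "abcd")
    if "expected" not in df.columns:
        n = a + b + c + d
        df["expected"] = (a + b) * (a + c) / n
    e = df["expected"].to_numpy()
    if prior is None:
        prior = fit_ebgm_prior(a, e, cfg)
    for part in (
        ror_stats(a, b, c, d, cfg),
        prr_stats(a, b, c, d, cfg),
        ic_stats(a, e, cfg),
        ebgm_stats(a, e, prior, cfg),
    ):
        for key, val in part.items():
            df[key] = val
    df["mcc"] = df["flag_ror"] & df["flag_prr"] & df["flag_ic"] & df["flag_ebgm"]
    df["fisher_p"] = fisher_exact_batch(a, b, c, d)
    df["q"] = np.nan
    df.attrs["prior"] = prior
    return df


def apply_mcc(results: SignalFrame) -> SignalFrame:
    """Consensus subset: rows whose four per-method flags are all True.
    An undefined flag (NaN statistic) counts as False."""
    raw = results[["flag_ror", "flag_prr", "flag_ic", "flag_ebgm"]].to_numpy(dtype=float)
    mcc = pd.Series(np.nan_to_num(raw, nan=0.0).astype(bool).all(axis=1), index=results.index)
    out = results.copy()
    out["mcc"] = mcc
    return out[mcc]


# --------------------------------------------------------------------------
# prioritization


@dataclass
class StrongSignalSet:
    """Top signals of one stratum, ordered by descending ROR (ties: larger
    a, then lexicographic item)."""

    kind: str
    stratum: str
    results: pd.DataFrame
    top_k: int
    exception_applied: bool

    def items(self) -> list[str]:
        return list(self.results["item"])


def prioritize(
    results: SignalFrame,
    top_k: int = 20,
    small_class_threshold: int = 10,
) -> StrongSignalSet:
    """Rank the MCC-positive signals of one stratum by ROR and keep the top
    ``top_k``; when the stratum's total positive count is at most
    ``small_class_threshold`` every signal is kept (small-class exception)."""
    if len(results) == 0:
        return StrongSignalSet("", "", results.copy(), top_k, False)
    kinds = results["kind"].unique()
    strata = results["stratum"].unique()
    if len(kinds) > 1 or len(strata) > 1:
        raise ValueError("prioritize expects signals of a single stratum")
    ordered = results.sort_values(
        ["ror", "a", "item"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    exception = len(ordered) <= small_class_threshold
    kept = ordered if exception else ordered.head(top_k)
    return StrongSignalSet(str(kinds[0]), str(strata[0]), kept.reset_index(drop=True), top_k, exception)


# --------------------------------------------------------------------------
# concordance


@dataclass(frozen=True)
class ConcordanceReport:
    n_mcc: int
    n_fdr: int
    n_both: int

    @property
    def jaccard(self) -> float:
        union = self.n_mcc + self.n_fdr - self.n_both
        return self.n_both / union if union else 1.0

    def as_dict(self) -> dict:
        return {
            "n_mcc": self.n_mcc,
            "n_fdr": self.n_fdr,
            "n_both": self.n_both,
            "jaccard": self.jaccard,
        }


def concordance(mcc_set: Iterable, fdr_set: Iterable) -> ConcordanceReport:
    """Overlap between the consensus signal set and the FDR-significant set
    (both as collections of (stratum, item) keys over the same universe)."""
    m, f = set(mcc_set), set(fdr_set)
    return ConcordanceReport(len(m), len(f), len(m & f))


# --------------------------------------------------------------------------
# orchestration


@dataclass
class AnalysisResult:
    """Everything one full run produces."""

    signals: SignalFrame                      # all (scheme, stratum, item) rows
    strong: dict[tuple[str, str], StrongSignalSet]
    concordance: dict[str, ConcordanceReport]
    prior: GammaPoissonPrior
    counts: dict[str, int] = field(default_factory=dict)

    def mcc_signals(self) -> SignalFrame:
        return self.signals[self.signals["mcc"]]


def analyze_reports(
    reports: Sequence[CaseReport],
    registry: ComponentRegistry,
    meddra: MeddraMap | None = None,
    kinds: Sequence[str] = KINDS,
    cfg: AlgorithmConfig = AlgorithmConfig(),
    comparator: str = "all",
    fdr_scope: str = "scheme",
    top_k: int = 20,
    small_class_threshold: int = 10,
    alpha_fdr: float = 0.05,
    soc_level: bool = False,
) -> AnalysisResult:
    """Run the full stratified analysis on deduplicated, annotated reports.

    The EBGM prior is fitted once, on the per-drug (ADC x PT) tables of the
    collection, and reused for every stratification scheme.  BH adjustment
    runs within one scheme (``fdr_scope='scheme'``) or over all schemes
    jointly (``'global'``).  ``comparator='all'`` keeps every other report in
    the background; ``'adc_only'`` restricts the collection to reports naming
    at least one included ADC before tabulating.
    """
    if not reports:
        raise ValueError("empty report collection")
    unknown = set(kinds) - set(KINDS)
    if unknown:
        raise ValueError(f"unknown stratification kind(s): {sorted(unknown)}")
    if fdr_scope not in ("scheme", "global"):
        raise ValueError(f"unknown fdr_scope: {fdr_scope!r}")
    if comparator not in ("all", "adc_only"):
        raise ValueError(f"unknown comparator: {comparator!r}")
    if comparator == "adc_only":
        adc_names = set(registry.included_names())
        reports = [r for r in reports if not adc_names.isdisjoint(r.suspect_names())]
        if not reports:
            raise ValueError("no reports name an included ADC")

    # database-wide shrinkage: prior from the drug-level tables
    drug_tables = tabulate(reports, build_strata(registry, "drug"), level="pt")
    prior = fit_ebgm_prior(drug_tables["a"], drug_tables["expected"], cfg)

    frames = []
    for kind in kinds:
        strata = build_strata(registry, kind)
        if kind == "drug":
            tables = drug_tables
        else:
            tables = tabulate(reports, strata, level="pt")
        screened = screen_tables(tables, cfg, prior=prior)
        screened["level"] = "pt"
        frames.append(screened)
        if soc_level:
            if meddra is None:
                raise ValueError("soc_level=True requires a MeddraMap")
            soc_tables = tabulate(reports, strata, level="soc", meddra=meddra)
            soc_screened = screen_tables(soc_tables, cfg, prior=prior)
            soc_screened["level"] = "soc"
            frames.append(soc_screened)
    signals = pd.concat(frames, ignore_index=True)

    # BH family: per stratification scheme (kind) or global
    if fdr_scope == "global":
        signals["q"] = bh_adjust(signals["fisher_p"].to_numpy())
    else:
        for kind in signals["kind"].unique():
            mask = signals["kind"] == kind
            signals.loc[mask, "q"] = bh_adjust(signals.loc[mask, "fisher_p"].to_numpy())

    strong: dict[tuple[str, str], StrongSignalSet] = {}
    conc: dict[str, ConcordanceReport] = {}
    pt_signals = signals[signals["level"] == "pt"]
    for kind in kinds:
        sub = pt_signals[pt_signals["kind"] == kind]
        mcc_sub = sub[sub["mcc"]]
        for stratum in sub["stratum"].unique():
            sset = prioritize(
                mcc_sub[mcc_sub["stratum"] == stratum],
                top_k=top_k,
                small_class_threshold=small_class_threshold,
            )
            sset.kind, sset.stratum = kind, str(stratum)
            strong[(kind, str(stratum))] = sset
        keys = list(zip(mcc_sub["stratum"], mcc_sub["item"]))
        fdr_keys = [
            k for k, q in zip(keys, mcc_sub["q"]) if q < alpha_fdr
        ]
        conc[kind] = concordance(keys, fdr_keys)

    counts = {
        "n_reports": len(reports),
        "n_tables": int(len(signals)),
        "n_mcc": int(signals["mcc"].sum()),
        "n_strong": int(sum(len(s.results) for s in strong.values())),
        "n_fdr_significant": int(((signals["q"] < alpha_fdr) & signals["mcc"]).sum()),
    }
    return AnalysisResult(signals=signals, strong=strong, concordance=conc, prior=prior, counts=counts)
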