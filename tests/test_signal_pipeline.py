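"""Consensus flags, prioritization, Fisher/BH layer and orchestration."""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from adcvigil.report_store import annotate_components
from adcvigil.signal_pipeline import (
    analyze_reports,
    apply_mcc,
    bh_adjust,
    concordance,
    fisher_exact,
    fisher_exact_batch,
    prioritize,
    screen_tables,
)
from adcvigil.stratify_contingency import ContingencyTable
from adcvigil.synthetic_faers import PlantedEffect, SimConfig, generate


# ------------------------------------------------------------------ MCC


def _frame(rows):
    return pd.DataFrame(rows)


def test_mcc_is_conjunction_of_flags():
    rows = [
        dict(kind="drug", stratum="s", item="p1", flag_ror=True, flag_prr=True,
             flag_ic=True, flag_ebgm=True),
        dict(kind="drug", stratum="s", item="p2", flag_ror=True, flag_prr=True,
             flag_ic=True, flag_ebgm=False),
        dict(kind="drug", stratum="s", item="p3", flag_ror=np.nan, flag_prr=True,
             flag_ic=True, flag_ebgm=True),
    ]
    out = apply_mcc(_frame(rows))
    assert list(out["item"]) == ["p1"]  # undefined flag counts as False


def test_mcc_subset_of_each_method(registry):
    """On a synthetic run, the consensus set never exceeds any single
    method's positive set."""
    cfg = SimConfig(
        n_cases=4000, n_events=20, n_background_drugs=8, seed=21,
        planted_effects=(
            PlantedEffect("drug", "brentuximab vedotin", "PT_0005", 15.0),
            PlantedEffect("payload", "dna_damaging", "PT_0011", 8.0),
        ),
    )
    reports, _ = generate(cfg)
    annotate_components(reports, registry)
    res = analyze_reports(reports, registry, kinds=("drug", "payload"))
    sig = res.signals
    n_mcc = int(sig["mcc"].sum())
    assert n_mcc >= 1
    for flag in ("flag_ror", "flag_prr", "flag_ic", "flag_ebgm"):
        assert n_mcc <= int(sig[flag].sum())
        assert (sig["mcc"] <= sig[flag]).all()


# ------------------------------------------------------------------ prioritize


def _signal_rows(n, stratum="IgG1", kind="antibody"):
    rng = np.random.default_rng(3)
    return pd.DataFrame(
        {
            "kind": kind,
            "stratum": stratum,
            "item": [f"PT_{i:04d}" for i in range(n)],
            "ror": rng.uniform(2, 50, n),
            "a": rng.integers(3, 60, n),
        }
    )


def test_prioritize_caps_at_top_k():
    out = prioritize(_signal_rows(25), top_k=20, small_class_threshold=10)
    assert len(out.results) == 20 and not out.exception_applied
    rors = out.results["ror"].to_numpy()
    assert (np.diff(rors) <= 0).all()


def test_prioritize_small_class_keeps_all():
    out = prioritize(_signal_rows(8), top_k=20, small_class_threshold=10)
    assert len(out.results) == 8 and out.exception_applied


def test_prioritize_tiebreaks_on_count_then_item():
    df = pd.DataFrame(
        {
            "kind": "drug", "stratum": "s",
            "item": ["PT_B", "PT_A", "PT_C"],
            "ror": [5.0, 5.0, 5.0],
            "a": [3, 7, 7],
        }
    )
    out = prioritize(df, top_k=2, small_class_threshold=0)
    assert list(out.results["item"]) == ["PT_A", "PT_C"]


def test_prioritize_order_independent():
    df = _signal_rows(30)
    base = prioritize(df)
    for perm_seed in (1, 2, 3):
        shuffled = df.sample(frac=1, random_state=perm_seed).reset_index(drop=True)
        again = prioritize(shuffled)
        pd.testing.assert_frame_equal(base.results, again.results)


def test_prioritize_rejects_mixed_strata():
    df = pd.concat([_signal_rows(3, stratum="IgG1"), _signal_rows(3, stratum="IgG4")])
    with pytest.raises(ValueError, match="single stratum"):
        prioritize(df)


def test_prioritize_empty_input():
    out = prioritize(_signal_rows(0))
    assert len(out.results) == 0 and not out.exception_applied


# ------------------------------------------------------------------ Fisher


def fisher_oracle(a, b, c, d):
    """Full hypergeometric enumeration, point-probability two-sided rule."""
    n, K, m = a + b + c + d, a + c, a + b
    if K == 0 or K == n or m == 0 or m == n:
        return 1.0
    denom = comb(n, m)
    p_obs = comb(K, a) * comb(n - K, m - a) / denom
    total = 0.0
    for k in range(max(0, m + K - n), min(m, K) + 1):
        p_k = comb(K, k) * comb(n - K, m - k) / denom
        if p_k <= p_obs * (1 + 1e-7):
            total += p_k
    return min(total, 1.0)


def test_fisher_worked_examples():
    assert fisher_exact(ContingencyTable(3, 1, 1, 3)) == pytest.approx(34 / 70)
    assert fisher_exact(ContingencyTable(5, 5, 5, 5)) == pytest.approx(1.0)
    assert fisher_exact(ContingencyTable(10, 0, 0, 10)) == pytest.approx(2 / comb(20, 10))


def test_fisher_degenerate_margin():
    assert fisher_exact(ContingencyTable(0, 5, 0, 5)) == 1.0


def test_fisher_batch_equals_enumeration_on_random_tables():
    rng = np.random.default_rng(17)
    a, b, c, d = (rng.integers(0, 30, 400) for _ in range(4))
    got = fisher_exact_batch(a, b, c, d)
    for i in range(a.size):
        assert got[i] == pytest.approx(fisher_oracle(a[i], b[i], c[i], d[i]), abs=1e-12)


# ------------------------------------------------------------------ BH


def bh_oracle(p):
    """Brute-force step-up definition."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def test_bh_worked_examples():
    assert bh_adjust([0.03]) == pytest.approx([0.03])
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert bh_adjust([0.001, 0.01, 0.02, 0.5]) == pytest.approx(
        [0.004, 0.02, 0.0266667, 0.5], rel=1e-5
    )
    assert bh_adjust([]).size == 0


@given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40))
def test_bh_matches_bruteforce_stepup(pvals):
    assert bh_adjust(pvals) == pytest.approx(bh_oracle(np.array(pvals)), abs=1e-12)


# ------------------------------------------------------------------ concordance


def test_concordance_identical_and_disjoint():
    ten = {(f"s", f"p{i}") for i in range(10)}
    rep = concordance(ten, ten)
    assert rep.jaccard == 1.0 and rep.n_both == 10
    other = {("s", f"q{i}") for i in range(5)}
    rep2 = concordance(ten, other)
    assert rep2.jaccard == 0.0 and rep2.n_both == 0
    assert rep2.n_both <= min(rep2.n_mcc, rep2.n_fdr)


# ------------------------------------------------------------------ orchestration


def test_analyze_planted_signal_lands_in_strong_set(registry):
    cfg = SimConfig(
        n_cases=6000, n_events=25, n_background_drugs=10, seed=5,
        planted_effects=(PlantedEffect("drug", "belantamab mafodotin", "PT_0009", 20.0),),
    )
    reports, truth = generate(cfg)
    annotate_components(reports, registry)
    res = analyze_reports(reports, registry, kinds=("drug",))
    strong = res.strong[("drug", "belantamab mafodotin")]
    assert "PT_0009" in strong.items()
    # manifest-style counts only shrink along the pipeline
    assert res.counts["n_mcc"] >= res.counts["n_fdr_significant"]
    assert res.counts["n_tables"] >= res.counts["n_mcc"]


def test_analyze_rejects_bad_options(registry):
    reports, _ = generate(SimConfig(n_cases=50, seed=1))
    annotate_components(reports, registry)
    with pytest.raises(ValueError, match="unknown stratification"):
        analyze_reports(reports, registry, kinds=("drug", "flavour"))
    with pytest.raises(ValueError, match="fdr_scope"):
        analyze_reports(reports, registry, fdr_scope="per-test")
    with pytest.raises(ValueError, match="empty"):
        analyze_reports([], registry)


def test_screen_tables_carries_all_columns(registry):
    from adcvigil.stratify_contingency import build_strata, tabulate

    reports, _ = generate(SimConfig(n_cases=400, n_events=10, seed=2))
    annotate_components(reports, registry)
    tables = tabulate(reports, build_strata(registry, "antibody"))
    out = screen_tables(tables)
    for col in ("ror", "ror_lo", "ror_hi", "prr", "chi2", "ic", "ic025",
                "ebgm", "eb05", "mcc", "fisher_p"):
        assert col in out.columns
    assert ((out["fisher_p"] > 0) & (out["fisher_p"] <= 1)).all()
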