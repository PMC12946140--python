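"""Analysis strata and 2x2 contingency tables.

A stratum is either a single ADC or a pooled component class (antibody
subtype, linker type, payload category, DAR class).  For every stratum-event
pair a 2x2 table is built at the report level:

====  =========================================  =========================
cell  meaning                                     margin
====  =========================================  =========================
a     stratum reports listing the event           a+b = stratum reports
b     stratum reports without the event
c     comparator reports listing the event        a+c = event reports
d     comparator reports without the event        N = a+b+c+d
====  =========================================  =========================

A report is "in the stratum" when any suspect-role drug belongs to the
stratum's member set; it contributes to ``a`` at most once per event
(unique report x unique PT counting).  The comparator is every other report
in the analyzed collection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from adcvigil.report_store import (
    Antibody,
    CaseReport,
    ComponentRegistry,
    DarClass,
    Linker,
    MeddraMap,
    Payload,
    normalize_drug_name,
)

__all__ = [
    "KINDS",
    "Stratum",
    "ContingencyTable",
    "build_strata",
    "report_in_stratum",
    "build_table",
    "build_soc_table",
    "tabulate",
]

#: supported stratification kinds
KINDS = ("drug", "antibody", "linker", "payload", "dar")


@dataclass(frozen=True)
class Stratum:
    """One analysis stratum: a kind, its label and the member drug names
    (normalized)."""

    kind: str
    label: str
    member_drugs: frozenset[str]

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown stratum kind: {self.kind!r}")
        if not self.member_drugs:
            raise ValueError(f"stratum {self.label!r} has no member drugs")


@dataclass(frozen=True)
class ContingencyTable:
    """The a, b, c, d cells of one stratum-event 2x2 table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.n == 0:
            raise ValueError("empty table (N = 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected a-count under row/column independence: (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    @property
    def degenerate(self) -> bool:
        """True when a margin is empty (the event or the stratum is absent)."""
        return (self.a + self.c) == 0 or (self.a + self.b) == 0

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


_KIND_LABELS = {
    "antibody": [e.value for e in Antibody],
    "linker": [e.value for e in Linker],
    "payload": [e.value for e in Payload],
    "dar": [e.value for e in DarClass],
}


def build_strata(registry: ComponentRegistry, kind: str) -> list[Stratum]:
    """Strata of one kind over the registry's included ADCs.

    ``kind='drug'`` gives one stratum per included ADC; component kinds give
    one stratum per class label that has at least one member drug, so the
    strata of a kind partition the included ADCs.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown stratum kind: {kind!r}")
    included = registry.included()
    if kind == "drug":
        return [
            Stratum("drug", normalize_drug_name(m.drug_name), frozenset({normalize_drug_name(m.drug_name)}))
            for m in sorted(included, key=lambda m: m.drug_name)
        ]
    attr = "dar_class" if kind == "dar" else kind
    strata = []
    for label in _KIND_LABELS[kind]:
        members = frozenset(
            normalize_drug_name(m.drug_name)
            for m in included
            if getattr(m, attr).value == label
        )
        if members:
            strata.append(Stratum(kind, label, members))
    return strata


def report_in_stratum(report: CaseReport, stratum: Stratum) -> bool:
    """True when any suspect-role drug of the report is a stratum member."""
    return not stratum.member_drugs.isdisjoint(report.suspect_names())


def build_table(reports: Sequence[CaseReport], stratum: Stratum, pt: str) -> ContingencyTable:
    """Report-level 2x2 table for one stratum-PT pair (reference path;
    :func:`tabulate` is the batch equivalent)."""
    if not reports:
        raise ValueError("empty report collection")
    a = b = c = d = 0
    for r in reports:
        exposed = report_in_stratum(r, stratum)
        has_event = pt in r.events
        if exposed and has_event:
            a += 1
        elif exposed:
            b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def build_soc_table(
    reports: Sequence[CaseReport], stratum: Stratum, soc: str, meddra: MeddraMap
) -> ContingencyTable:
    """2x2 table at SOC level: a report contributes to ``a`` once when exposed
    and at least one of its events maps to the SOC."""
    if not reports:
        raise ValueError("empty report collection")
    a = b = c = d = 0
    for r in reports:
        exposed = report_in_stratum(r, stratum)
        has_soc = any(meddra.soc(pt) == soc for pt in r.events)
        if exposed and has_soc:
            a += 1
        elif exposed:
            b += 1
        elif has_soc:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def _exposure_matrix(reports: Sequence[CaseReport], strata: Sequence[Stratum]) -> np.ndarray:
    """Boolean matrix (n_strata x n_reports) of stratum membership."""
    suspect_sets = [r.suspect_names() for r in reports]
    mat = np.zeros((len(strata), len(reports)), dtype=bool)
    for i, s in enumerate(strata):
        mat[i] = [not s.member_drugs.isdisjoint(names) for names in suspect_sets]
    return mat


def tabulate(
    reports: Sequence[CaseReport],
    strata: Sequence[Stratum],
    level: str = "pt",
    meddra: MeddraMap | None = None,
    items: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Cells for every stratum x item pair in one pass.

    ``level='pt'`` counts unique (report, PT) pairs; ``level='soc'`` maps each
    event through ``meddra`` first and counts unique (report, SOC) pairs.
    ``items`` restricts/extends the item universe (default: every item seen
    in the data).  Returns a DataFrame with columns
    ``kind, stratum, item, a, b, c, d``.
    """
    if not reports:
        raise ValueError("empty report collection")
    if level not in ("pt", "soc"):
        raise ValueError(f"unknown level: {level!r}")
    if level == "soc" and meddra is None:
        raise ValueError("SOC level requires a MeddraMap")

    ridx = np.repeat(np.arange(len(reports)), [len(set(r.events)) for r in reports])
    labels: list[str] = []
    for r in reports:
        uniq = list(dict.fromkeys(r.events))
        if level == "soc":
            labels.extend(meddra.soc(pt) for pt in uniq)
        else:
            labels.extend(uniq)
    long = pd.DataFrame({"ridx": ridx, "item": labels}).drop_duplicates()

    universe = sorted(set(long["item"])) if items is None else list(items)
    item_totals = long.groupby("item").size()
    n_reports = len(reports)
    expo = _exposure_matrix(reports, strata)

    frames = []
    for i, s in enumerate(strata):
        n_strat = int(expo[i].sum())
        a = (
            long[expo[i][long["ridx"].to_numpy()]]
            .groupby("item")
            .size()
            .reindex(universe, fill_value=0)
        )
        tot = item_totals.reindex(universe, fill_value=0)
        frames.append(
            pd.DataFrame(
                {
                    "kind": s.kind,
                    "stratum": s.label,
                    "item": universe,
                    "a": a.to_numpy(),
                    "b": n_strat - a.to_numpy(),
                    "c": (tot - a).to_numpy(),
                    "d": n_reports - n_strat - (tot - a).to_numpy(),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["n"] = out[["a", "b", "c", "d"]].sum(axis=1)
    out["expected"] = (out["a"] + out["b"]) * (out["a"] + out["c"]) / out["n"]
    return out
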