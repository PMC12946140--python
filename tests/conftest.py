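"""Shared fixtures: report factories, tiny registries, simulated datasets."""

from __future__ import annotations

from datetime import date

import pytest
from hypothesis import settings

from adcvigil.report_store import (
    CaseReport,
    ComponentMeta,
    ComponentRegistry,
    DrugEntry,
    DrugRole,
    OutcomeCode,
    ReporterType,
    Sex,
    builtin_registry,
    default_meddra_map,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_report(
    case_id: str,
    drugs: list[tuple[str, str]] | None = None,
    events: list[str] | None = None,
    version_id: str = "1",
    receipt_date: date | None = date(2022, 1, 1),
    sex: str = "female",
    age_years: float | None = 60.0,
    serious: bool = True,
    outcomes: tuple[str, ...] = ("hospitalization",),
    therapy_start: date | None = None,
    event_date: date | None = None,
    country: str | None = "US",
) -> CaseReport:
    """Terse report builder for fixtures; drugs are (name, role) pairs."""
    return CaseReport(
        case_id=case_id,
        version_id=version_id,
        receipt_date=receipt_date,
        sex=Sex(sex),
        age_years=age_years,
        reporter_type=ReporterType.healthcare_professional,
        serious=serious,
        outcomes=frozenset(OutcomeCode(o) for o in outcomes) if serious else frozenset(),
        drugs=[
            DrugEntry(name, DrugRole(role), therapy_start_date=therapy_start)
            for name, role in (drugs or [("drugX", "primary_suspect")])
        ],
        events=events if events is not None else ["PT_0001"],
        country=country,
        event_date=event_date,
    )


@pytest.fixture(scope="session")
def registry() -> ComponentRegistry:
    return builtin_registry()


@pytest.fixture
def mini_registry() -> ComponentRegistry:
    """Three-drug registry spanning both antibody classes and two payloads."""
    return ComponentRegistry(
        [
            ComponentMeta("alphamab vedotin", "IgG1", "cleavable", "microtubule_inhibitor", "3to5", 4.0),
            ComponentMeta("betamab ozogamicin", "IgG4", "cleavable", "dna_damaging", "lt3", 2.5),
            ComponentMeta("gammamab mafodotin", "IgG1", "non_cleavable", "microtubule_inhibitor", "3to5", 4.0),
        ]
    )


@pytest.fixture
def meddra4():
    return default_meddra_map(["PT_0001", "PT_0002", "PT_0003", "PT_0004"])
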