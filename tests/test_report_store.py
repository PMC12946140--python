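"""Ingestion, deduplication, normalization and component annotation."""

from __future__ import annotations

import random
from datetime import date

import pytest
from hypothesis import given, strategies as st

from adcvigil.report_store import (
    ComponentMeta,
    ConfigError,
    DarClass,
    FormatError,
    MeddraMap,
    UnmappedPTError,
    annotate_components,
    dar_class_for,
    deduplicate,
    default_meddra_map,
    normalize_drug_name,
    read_faers_ascii,
    read_simple_csv,
    write_faers_ascii,
    write_simple_csv,
)
from conftest import make_report


# ------------------------------------------------------------------ dialects


SIMPLE_HEADER = (
    "case_id,version_id,receipt_date,sex,age_years,reporter_type,serious,"
    "outcome,country,drug_name,drug_role,therapy_start_date,event_pt,event_date"
)


def test_simple_csv_groups_rows_into_cases(tmp_path):
    """6 rows over 2 case ids collapse into 2 reports with grouped drugs/events."""
    rows = [
        "C1,1,2022-01-01,female,60,healthcare_professional,true,hospitalization,US,drugA,primary_suspect,2021-12-01,PT_0001,2021-12-20",
        "C1,1,2022-01-01,female,60,healthcare_professional,true,hospitalization,US,drugA,primary_suspect,2021-12-01,PT_0002,2021-12-20",
        "C1,1,2022-01-01,female,60,healthcare_professional,true,hospitalization,US,drugB,concomitant,,PT_0001,2021-12-20",
        "C1,1,2022-01-01,female,60,healthcare_professional,true,hospitalization,US,drugB,concomitant,,PT_0002,2021-12-20",
        "C2,1,2022-02-01,male,41,consumer,false,,JP,drugC,primary_suspect,,PT_0003,",
        "C2,1,2022-02-01,male,41,consumer,false,,JP,drugC,primary_suspect,,PT_0004,",
    ]
    path = tmp_path / "six.csv"
    path.write_text(SIMPLE_HEADER + "\n" + "\n".join(rows) + "\n")
    reports, stats = read_simple_csv(path)
    assert stats.n_reports == 2 and stats.n_malformed == 0
    c1, c2 = reports
    assert {d.drug_name for d in c1.drugs} == {"drugA", "drugB"}
    assert c1.events == ["PT_0001", "PT_0002"]
    assert c1.event_date == date(2021, 12, 20)
    assert c2.events == ["PT_0003", "PT_0004"] and not c2.serious


def test_simple_csv_missing_column_names_it(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("case_id,version_id\nC1,1\n")
    with pytest.raises(FormatError, match="event_pt"):
        read_simple_csv(path)


def test_faers_join_and_orphan_accounting(tmp_path):
    """A DEMO+DRUG+REAC triple sharing primaryid becomes one report; a REAC
    row with no DEMO is counted as an orphan and excluded."""
    (tmp_path / "DEMO.txt").write_text(
        "primaryid$caseid$caseversion$fda_dt$event_dt$sex$age$age_cod$occp_cod$reporter_country\n"
        "P1$C1$1$20220101$20211220$F$60$YR$MD$US\n"
    )
    (tmp_path / "DRUG.txt").write_text(
        "primaryid$drug_seq$role_cod$drugname\nP1$1$PS$drugA\n"
    )
    (tmp_path / "REAC.txt").write_text("primaryid$pt\nP1$PT_0001\nP9$PT_0009\n")
    reports, stats = read_faers_ascii(
        [tmp_path / "DEMO.txt", tmp_path / "DRUG.txt", tmp_path / "REAC.txt"]
    )
    assert len(reports) == 1
    r = reports[0]
    assert r.case_id == "C1" and len(r.drugs) == 1 and r.events == ["PT_0001"]
    assert stats.n_orphans == 1


def test_faers_missing_mandatory_column(tmp_path):
    (tmp_path / "DEMO.txt").write_text("primaryid$caseid\nP1$C1\n")
    with pytest.raises(FormatError, match="caseversion"):
        read_faers_ascii([tmp_path / "DEMO.txt"])


def test_simple_round_trip_identity(tmp_path):
    reports = [
        make_report("A", drugs=[("drugA", "primary_suspect"), ("drugB", "concomitant")],
                    events=["PT_0002", "PT_0001"], therapy_start=date(2021, 5, 1),
                    event_date=date(2021, 6, 1)),
        make_report("B", serious=False, outcomes=(), age_years=None, country=None,
                    events=["PT_0003"]),
    ]
    path = tmp_path / "rt.csv"
    write_simple_csv(reports, path)
    back, stats = read_simple_csv(path)
    assert back == reports and stats.n_malformed == 0


def test_faers_round_trip_preserves_content(tmp_path):
    reports = [
        make_report("A", drugs=[("drugA", "primary_suspect")], events=["PT_0001", "PT_0002"],
                    therapy_start=date(2021, 5, 1), event_date=date(2021, 6, 1)),
        make_report("B", sex="male", serious=False, outcomes=(), events=["PT_0003"]),
    ]
    paths = write_faers_ascii(reports, tmp_path)
    back, _ = read_faers_ascii(list(paths.values()))
    assert [r.case_id for r in back] == ["A", "B"]
    for orig, rt in zip(reports, back):
        assert rt.events == orig.events
        assert rt.sex == orig.sex and rt.serious == orig.serious
        assert rt.drugs[0].therapy_start_date == orig.drugs[0].therapy_start_date if orig.drugs else True


# ------------------------------------------------------------------ dedup


def test_dedup_keeps_latest_version_and_date_tiebreak():
    v1 = make_report("C", version_id="1")
    v2 = make_report("C", version_id="2")
    kept, removed = deduplicate([v1, v2])
    assert kept == [v2] and removed == 1

    early = make_report("D", version_id="3", receipt_date=date(2020, 1, 1))
    late = make_report("D", version_id="3", receipt_date=date(2021, 1, 1))
    kept, _ = deduplicate([early, late])
    assert kept[0].receipt_date == date(2021, 1, 1)


def test_dedup_counts_on_mixed_fixture():
    """10 records over 7 cases -> 7 retained, 3 removed (group-by oracle)."""
    records = (
        [make_report(f"K{i}") for i in range(5)]
        + [make_report("K5", version_id=v) for v in ("1", "2", "3")]
        + [make_report("K6", version_id="1"), make_report("K6", version_id="9")]
    )
    kept, removed = deduplicate(records)
    assert len(kept) == 7 and removed == 3
    by_case = {r.case_id: r for r in kept}
    assert by_case["K5"].version_id == "3" and by_case["K6"].version_id == "9"


@given(st.randoms(use_true_random=False))
def test_dedup_idempotent_and_order_independent(rnd):
    records = (
        [make_report(f"C{i}", version_id=str(v)) for i in range(4) for v in (1, 2)]
        + [make_report("C9")]
    )
    shuffled = list(records)
    rnd.shuffle(shuffled)
    once, _ = deduplicate(shuffled)
    twice, removed_again = deduplicate(once)
    assert twice == once and removed_again == 0
    baseline, _ = deduplicate(records)
    assert once == baseline


# ------------------------------------------------------- normalization, meta


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("Belantamab Mafodotin-blmf", "belantamab mafodotin"),
        ("  ENHERTU ", "enhertu"),
        ("doxorubicin hydrochloride", "doxorubicin"),
        ("fam-trastuzumab deruxtecan-nxki", "fam-trastuzumab deruxtecan"),
        ("drug (100mg)", "drug"),
    ],
)
def test_normalize_drug_name(raw, expected):
    assert normalize_drug_name(raw) == expected


def test_dar_class_boundaries():
    assert dar_class_for(2.9) is DarClass.lt3
    assert dar_class_for(3.0) is DarClass.mid
    assert dar_class_for(5.0) is DarClass.mid
    assert dar_class_for(5.1) is DarClass.gt5


def test_component_meta_rejects_inconsistent_dar():
    with pytest.raises(ValueError, match="inconsistent"):
        ComponentMeta("x", "IgG1", "cleavable", "other", "lt3", dar_value=4.0)


def test_annotation_against_packaged_registry(registry):
    """Belantamab mafodotin carries IgG1 / non-cleavable / microtubule
    inhibitor / DAR 3-5; unknown drugs stay background."""
    r = make_report(
        "A",
        drugs=[
            ("Blenrep", "primary_suspect"),
            ("aspirin", "concomitant"),
            ("Enhertu", "secondary_suspect"),
        ],
    )
    n = annotate_components([r], registry)
    assert n == 2
    bel, asp, enh = r.drugs
    assert bel.component.drug_name == "belantamab mafodotin"
    assert (
        bel.component.antibody.value,
        bel.component.linker.value,
        bel.component.payload.value,
        bel.component.dar_class.value,
    ) == ("IgG1", "non_cleavable", "microtubule_inhibitor", "3to5")
    assert asp.component is None
    assert enh.component.drug_name == "fam-trastuzumab deruxtecan"


def test_annotation_unknown_study_drug_is_config_error(registry):
    with pytest.raises(ConfigError, match="not in registry"):
        annotate_components([make_report("A")], registry, study_drugs=["nosuchmab"])


def test_registry_excluded_drug_not_annotated(registry):
    r = make_report("A", drugs=[("datopotamab deruxtecan", "primary_suspect")])
    annotate_components([r], registry)
    assert r.drugs[0].component is None  # include=False drug stays background


# ------------------------------------------------------------------ MedDRA


def test_meddra_strict_vs_lenient_modes():
    strict = default_meddra_map(["PT_0001"], mode="strict")
    assert strict.soc("PT_0001") == "Blood and lymphatic system disorders"
    with pytest.raises(UnmappedPTError):
        strict.soc("PT_9999")
    lenient = MeddraMap(dict(strict.pt_to_soc), mode="lenient")
    assert lenient.soc("PT_9999") == MeddraMap.UNMAPPED


def test_meddra_csv_round_trip(tmp_path, meddra4):
    path = tmp_path / "map.csv"
    meddra4.to_csv(path)
    back = MeddraMap.from_csv(path)
    assert back.pt_to_soc == meddra4.pt_to_soc
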