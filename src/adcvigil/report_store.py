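"""Spontaneous-report ingestion, validation, deduplication and reference tables.

This module holds the in-memory model of a spontaneous adverse-event report
(one deduplicated case with demographics, outcomes, drugs and MedDRA
preferred-term events), readers/writers for two on-disk dialects, the
antibody-drug-conjugate (ADC) component registry and the PT->SOC map.

Two dialects are supported:

* the quarterly ASCII dialect of the FDA Adverse Event Reporting System
  (FAERS): dollar-delimited DEMO / DRUG / REAC / OUTC / THER files joined on
  ``primaryid``;
* a simplified tabular dialect: one CSV with one row per
  (case, drug, event) triple, convenient for fixtures and simulation output.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from datetime import date, datetime
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "ReporterType",
    "DrugRole",
    "OutcomeCode",
    "Antibody",
    "Linker",
    "Payload",
    "DarClass",
    "DrugEntry",
    "CaseReport",
    "ComponentMeta",
    "ComponentRegistry",
    "MeddraMap",
    "ParseStats",
    "FormatError",
    "ConfigError",
    "UnmappedPTError",
    "SUSPECT_ROLES",
    "normalize_drug_name",
    "dar_class_for",
    "builtin_registry",
    "default_meddra_map",
    "read_simple_csv",
    "write_simple_csv",
    "read_faers_ascii",
    "write_faers_ascii",
    "read_reports",
    "deduplicate",
    "annotate_components",
]


class FormatError(ValueError):
    """Input file does not conform to the declared dialect."""


class ConfigError(ValueError):
    """Run configuration is inconsistent or incomplete."""


class UnmappedPTError(KeyError):
    """A preferred term has no SOC in strict mapping mode."""


class Sex(str, Enum):
    male = "male"
    female = "female"
    unspecified = "unspecified"


class ReporterType(str, Enum):
    healthcare_professional = "healthcare_professional"
    consumer = "consumer"
    unspecified = "unspecified"


class DrugRole(str, Enum):
    primary_suspect = "primary_suspect"
    secondary_suspect = "secondary_suspect"
    concomitant = "concomitant"
    interacting = "interacting"


#: roles counted as exposure in contingency tables (suspect-only convention)
SUSPECT_ROLES = frozenset({DrugRole.primary_suspect, DrugRole.secondary_suspect})


class OutcomeCode(str, Enum):
    death = "death"
    disability = "disability"
    hospitalization = "hospitalization"
    life_threatening = "life_threatening"
    other_serious = "other_serious"


class Antibody(str, Enum):
    IgG1 = "IgG1"
    IgG4 = "IgG4"


class Linker(str, Enum):
    cleavable = "cleavable"
    non_cleavable = "non_cleavable"


class Payload(str, Enum):
    dna_damaging = "dna_damaging"
    microtubule_inhibitor = "microtubule_inhibitor"
    other = "other"


class DarClass(str, Enum):
    """Drug-to-antibody ratio class: mean payloads per antibody <3, 3-5, >5."""

    lt3 = "lt3"
    mid = "3to5"
    gt5 = "gt5"


def dar_class_for(dar_value: float) -> DarClass:
    """Class for a numeric DAR: <3 | closed interval [3, 5] | >5."""
    if dar_value < 3:
        return DarClass.lt3
    if dar_value <= 5:
        return DarClass.mid
    return DarClass.gt5


# --------------------------------------------------------------------------
# drug-name normalization

_SALT_WORDS = frozenset(
    {
        "hydrochloride",
        "hcl",
        "sodium",
        "sulfate",
        "sulphate",
        "acetate",
        "tartrate",
        "mesylate",
        "besylate",
        "citrate",
        "maleate",
        "phosphate",
        "injection",
        "tablets",
    }
)
# FDA nonproprietary-name distinguishing suffix, e.g. "-nxki", "-tdfk"
_FDA_SUFFIX_RE = re.compile(r"-[a-z]{4}$")


def normalize_drug_name(name: str) -> str:
    """Lowercase, trim, strip parentheticals, trailing salt/format words and
    the 4-letter FDA distinguishing suffix.  Purely deterministic; no fuzzy
    matching."""
    s = re.sub(r"\(.*?\)", " ", name.strip().lower())
    s = re.sub(r"\s+", " ", s).strip()
    tokens = s.split(" ")
    while len(tokens) > 1 and tokens[-1] in _SALT_WORDS:
        tokens.pop()
    s = " ".join(tokens)
    return _FDA_SUFFIX_RE.sub("", s)


# --------------------------------------------------------------------------
# domain records


@dataclass(slots=True)
class DrugEntry:
    """One drug listed on a report."""

    drug_name: str
    role: DrugRole
    therapy_start_date: date | None = None
    #: filled by :func:`annotate_components`; ``None`` means background drug
    component: "ComponentMeta | None" = None

    def is_suspect(self) -> bool:
        return self.role in SUSPECT_ROLES


@dataclass(slots=True)
class CaseReport:
    """One spontaneous report (a single version of a case)."""

    case_id: str
    version_id: str
    receipt_date: date | None
    sex: Sex
    age_years: float | None
    reporter_type: ReporterType
    serious: bool
    outcomes: frozenset[OutcomeCode]
    drugs: list[DrugEntry]
    events: list[str]
    country: str | None = None
    #: earliest adverse-event date recorded for the case (database logs the
    #: date the patient first experienced any AE, not a particular one)
    event_date: date | None = None

    def suspect_names(self) -> set[str]:
        """Normalized names of suspect-role drugs."""
        return {normalize_drug_name(d.drug_name) for d in self.drugs if d.is_suspect()}

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        issues = []
        if not self.case_id:
            issues.append("empty case_id")
        if not self.events:
            issues.append("no events")
        if self.age_years is not None and not (0 <= self.age_years <= 120):
            issues.append(f"age_years out of range: {self.age_years}")
        for d in self.drugs:
            if not d.drug_name:
                issues.append("empty drug_name")
        return issues


@dataclass(frozen=True, slots=True)
class ComponentMeta:
    """ADC component classes for one drug (antibody / linker / payload / DAR)."""

    drug_name: str
    antibody: Antibody
    linker: Linker
    payload: Payload
    dar_class: DarClass
    dar_value: float | None = None
    include: bool = True
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        # accept plain strings for the class fields
        for name, enum_cls in (
            ("antibody", Antibody), ("linker", Linker),
            ("payload", Payload), ("dar_class", DarClass),
        ):
            value = getattr(self, name)
            if not isinstance(value, enum_cls):
                object.__setattr__(self, name, enum_cls(value))
        if self.dar_value is not None:
            if self.dar_value <= 0:
                raise ValueError(f"{self.drug_name}: dar_value must be positive")
            expected = dar_class_for(self.dar_value)
            if expected is not self.dar_class:
                raise ValueError(
                    f"{self.drug_name}: dar_class {self.dar_class.value!r} "
                    f"inconsistent with dar_value {self.dar_value}"
                )


class ComponentRegistry:
    """Lookup table from normalized drug name (generic or brand) to
    :class:`ComponentMeta`."""

    def __init__(self, entries: Iterable[ComponentMeta]):
        self.entries: list[ComponentMeta] = list(entries)
        self._by_alias: dict[str, ComponentMeta] = {}
        for meta in self.entries:
            for name in (meta.drug_name, *meta.aliases):
                key = normalize_drug_name(name)
                prev = self._by_alias.get(key)
                if prev is not None and prev is not meta:
                    raise ConfigError(f"duplicate registry alias: {name!r}")
                self._by_alias[key] = meta

    def lookup(self, drug_name: str) -> ComponentMeta | None:
        return self._by_alias.get(normalize_drug_name(drug_name))

    def included(self) -> list[ComponentMeta]:
        return [m for m in self.entries if m.include]

    def included_names(self) -> list[str]:
        return [normalize_drug_name(m.drug_name) for m in self.included()]

    @classmethod
    def from_csv(cls, path: str | Path) -> "ComponentRegistry":
        entries = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            required = {"drug_name", "antibody", "linker", "payload", "dar_value", "dar_class"}
            missing = required - set(reader.fieldnames or [])
            if missing:
                raise FormatError(f"registry missing column(s): {sorted(missing)}")
            for row in reader:
                dar_value = float(row["dar_value"]) if row["dar_value"] else None
                entries.append(
                    ComponentMeta(
                        drug_name=row["drug_name"].strip(),
                        antibody=Antibody(row["antibody"]),
                        linker=Linker(row["linker"]),
                        payload=Payload(row["payload"]),
                        dar_class=DarClass(row["dar_class"]),
                        dar_value=dar_value,
                        include=row.get("include", "1").strip() not in ("0", "false", "False", ""),
                        aliases=tuple(
                            a.strip() for a in row.get("aliases", "").split(";") if a.strip()
                        ),
                    )
                )
        return cls(entries)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["drug_name", "antibody", "linker", "payload", "dar_value", "dar_class", "include", "aliases"]
            )
            for m in self.entries:
                w.writerow(
                    [
                        m.drug_name,
                        m.antibody.value,
                        m.linker.value,
                        m.payload.value,
                        "" if m.dar_value is None else m.dar_value,
                        m.dar_class.value,
                        int(m.include),
                        ";".join(m.aliases),
                    ]
                )


def builtin_registry() -> ComponentRegistry:
    """The packaged registry of the 14 FDA-approved ADCs (2000-2024) with
    component classes transcribed from product labels; 13 carry
    ``include=True``."""
    with resources.as_file(resources.files("adcvigil.data") / "adc_registry.csv") as p:
        return ComponentRegistry.from_csv(p)


# --------------------------------------------------------------------------
# MedDRA PT -> SOC map

#: the 27 MedDRA system organ classes
SOC_NAMES: tuple[str, ...] = (
    "Blood and lymphatic system disorders",
    "Cardiac disorders",
    "Congenital, familial and genetic disorders",
    "Ear and labyrinth disorders",
    "Endocrine disorders",
    "Eye disorders",
    "Gastrointestinal disorders",
    "General disorders and administration site conditions",
    "Hepatobiliary disorders",
    "Immune system disorders",
    "Infections and infestations",
    "Injury, poisoning and procedural complications",
    "Investigations",
    "Metabolism and nutrition disorders",
    "Musculoskeletal and connective tissue disorders",
    "Neoplasms benign, malignant and unspecified",
    "Nervous system disorders",
    "Pregnancy, puerperium and perinatal conditions",
    "Product issues",
    "Psychiatric disorders",
    "Renal and urinary disorders",
    "Reproductive system and breast disorders",
    "Respiratory, thoracic and mediastinal disorders",
    "Skin and subcutaneous tissue disorders",
    "Social circumstances",
    "Surgical and medical procedures",
    "Vascular disorders",
)


@dataclass
class MeddraMap:
    """Total map from preferred term to its single primary SOC.

    ``mode='strict'`` raises on an unknown PT; ``mode='lenient'`` routes it to
    the sentinel SOC ``'Unmapped'``.  Never both silently.
    """

    pt_to_soc: dict[str, str]
    mode: str = "strict"

    UNMAPPED = "Unmapped"

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "lenient"):
            raise ConfigError(f"unknown MeddraMap mode: {self.mode!r}")

    def soc(self, pt: str) -> str:
        try:
            return self.pt_to_soc[pt]
        except KeyError:
            if self.mode == "lenient":
                return self.UNMAPPED
            raise UnmappedPTError(pt) from None

    def socs(self) -> list[str]:
        return sorted(set(self.pt_to_soc.values()))

    @classmethod
    def from_csv(cls, path: str | Path, mode: str = "strict") -> "MeddraMap":
        mapping: dict[str, str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            missing = {"pt", "soc"} - set(reader.fieldnames or [])
            if missing:
                raise FormatError(f"MedDRA map missing column(s): {sorted(missing)}")
            for row in reader:
                pt, soc = row["pt"].strip(), row["soc"].strip()
                if pt in mapping and mapping[pt] != soc:
                    raise FormatError(f"PT {pt!r} mapped to two SOCs")
                mapping[pt] = soc
        return cls(mapping, mode=mode)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["pt", "soc"])
            for pt in sorted(self.pt_to_soc):
                w.writerow([pt, self.pt_to_soc[pt]])


def default_meddra_map(pts: Sequence[str], mode: str = "strict") -> MeddraMap:
    """Deterministic PT->SOC assignment (round-robin over the 27 SOCs) for
    simulated vocabularies."""
    return MeddraMap({pt: SOC_NAMES[i % len(SOC_NAMES)] for i, pt in enumerate(pts)}, mode=mode)


# --------------------------------------------------------------------------
# parsing helpers


@dataclass
class ParseStats:
    """Bookkeeping from a read: nothing is dropped silently."""

    n_rows: dict[str, int] = field(default_factory=dict)
    n_reports: int = 0
    n_malformed: int = 0
    n_orphans: int = 0
    n_no_event: int = 0
    issues: list[str] = field(default_factory=list)

    MAX_ISSUES = 200

    def note(self, msg: str) -> None:
        if len(self.issues) < self.MAX_ISSUES:
            self.issues.append(msg)
        log.debug("parse issue: %s", msg)


def _parse_iso_date(s: str) -> date | None:
    s = s.strip()
    if not s:
        return None
    return date.fromisoformat(s)


def _parse_faers_date(s: str) -> date | None:
    """FAERS YYYYMMDD (partial dates YYYYMM / YYYY are treated as missing)."""
    s = s.strip()
    if len(s) != 8 or not s.isdigit():
        return None
    return datetime.strptime(s, "%Y%m%d").date()


_SEX_CODES = {"M": Sex.male, "F": Sex.female}
_ROLE_CODES = {
    "PS": DrugRole.primary_suspect,
    "SS": DrugRole.secondary_suspect,
    "C": DrugRole.concomitant,
    "I": DrugRole.interacting,
}
_ROLE_TO_CODE = {v: k for k, v in _ROLE_CODES.items()}
_OUTC_CODES = {
    "DE": OutcomeCode.death,
    "DS": OutcomeCode.disability,
    "HO": OutcomeCode.hospitalization,
    "LT": OutcomeCode.life_threatening,
    "OT": OutcomeCode.other_serious,
}
_OUTC_TO_CODE = {v: k for k, v in _OUTC_CODES.items()}
_HCP_OCCP = {"MD", "PH", "RN", "HP"}


# --------------------------------------------------------------------------
# simplified dialect

SIMPLE_COLUMNS = (
    "case_id",
    "version_id",
    "receipt_date",
    "sex",
    "age_years",
    "reporter_type",
    "serious",
    "outcome",
    "country",
    "drug_name",
    "drug_role",
    "therapy_start_date",
    "event_pt",
    "event_date",
)


def read_simple_csv(path: str | Path) -> tuple[list[CaseReport], ParseStats]:
    """Read the one-row-per-(case, drug, event) CSV dialect.

    Rows are grouped on (case_id, version_id); drugs and events are
    de-duplicated within a case preserving first-seen order.
    """
    stats = ParseStats()
    groups: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(SIMPLE_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"simple dialect missing column(s): {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            stats.n_rows["simple"] = stats.n_rows.get("simple", 0) + 1
            try:
                case_id = row["case_id"].strip()
                if not case_id:
                    raise ValueError("empty case_id")
                key = (case_id, row["version_id"].strip())
                if key not in groups:
                    age = row["age_years"].strip()
                    age_years = float(age) if age else None
                    if age_years is not None and not (0 <= age_years <= 120):
                        raise ValueError(f"age out of range: {age_years}")
                    groups[key] = {
                        "receipt_date": _parse_iso_date(row["receipt_date"]),
                        "sex": Sex(row["sex"] or "unspecified"),
                        "age_years": age_years,
                        "reporter_type": ReporterType(row["reporter_type"] or "unspecified"),
                        "serious": row["serious"].strip().lower() in ("1", "true", "yes"),
                        "outcomes": frozenset(
                            OutcomeCode(o) for o in row["outcome"].split("|") if o
                        ),
                        "country": row["country"].strip() or None,
                        "drugs": {},
                        "events": {},
                        "event_dates": [],
                    }
                    order.append(key)
                g = groups[key]
                dname = row["drug_name"].strip()
                if dname:
                    dkey = (
                        dname,
                        row["drug_role"],
                        row["therapy_start_date"],
                    )
                    if dkey not in g["drugs"]:
                        g["drugs"][dkey] = DrugEntry(
                            drug_name=dname,
                            role=DrugRole(row["drug_role"]),
                            therapy_start_date=_parse_iso_date(row["therapy_start_date"]),
                        )
                pt = row["event_pt"].strip()
                if pt:
                    g["events"][pt] = None
                ed = _parse_iso_date(row["event_date"])
                if ed is not None:
                    g["event_dates"].append(ed)
            except (ValueError, KeyError) as exc:
                stats.n_malformed += 1
                stats.note(f"line {lineno}: {exc}")
    reports = []
    for key in order:
        g = groups[key]
        report = CaseReport(
            case_id=key[0],
            version_id=key[1],
            receipt_date=g["receipt_date"],
            sex=g["sex"],
            age_years=g["age_years"],
            reporter_type=g["reporter_type"],
            serious=g["serious"],
            outcomes=g["outcomes"],
            drugs=list(g["drugs"].values()),
            events=list(g["events"]),
            country=g["country"],
            event_date=min(g["event_dates"]) if g["event_dates"] else None,
        )
        if not report.events:
            stats.n_no_event += 1
            stats.note(f"case {key[0]} v{key[1]}: no events, excluded")
            continue
        reports.append(report)
    stats.n_reports = len(reports)
    return reports, stats


def write_simple_csv(reports: Iterable[CaseReport], path: str | Path) -> None:
    """Write the simplified dialect: one row per (case, drug, event);
    cases with no drugs still emit one row per event with blank drug fields."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(SIMPLE_COLUMNS)
        for r in reports:
            drugs = r.drugs or [None]
            for d in drugs:
                for pt in r.events:
                    w.writerow(
                        [
                            r.case_id,
                            r.version_id,
                            r.receipt_date.isoformat() if r.receipt_date else "",
                            r.sex.value,
                            "" if r.age_years is None else f"{r.age_years:g}",
                            r.reporter_type.value,
                            "true" if r.serious else "false",
                            "|".join(sorted(o.value for o in r.outcomes)),
                            r.country or "",
                            d.drug_name if d else "",
                            d.role.value if d else "",
                            d.therapy_start_date.isoformat() if d and d.therapy_start_date else "",
                            pt,
                            r.event_date.isoformat() if r.event_date else "",
                        ]
                    )


# --------------------------------------------------------------------------
# FAERS ASCII dialect

_FAERS_TABLES = {
    "DEMO": ("primaryid", "caseid", "caseversion", "fda_dt", "event_dt", "sex", "age", "age_cod", "occp_cod", "reporter_country"),
    "DRUG": ("primaryid", "drug_seq", "role_cod", "drugname"),
    "REAC": ("primaryid", "pt"),
    "OUTC": ("primaryid", "outc_cod"),
    "THER": ("primaryid", "dsg_drug_seq", "start_dt"),
}


def _classify_faers_file(path: Path) -> str:
    name = path.name.upper()
    for table in _FAERS_TABLES:
        if table in name:
            return table
    raise FormatError(f"cannot classify FAERS file (expected DEMO/DRUG/REAC/OUTC/THER in name): {path.name}")


def _read_dollar_file(path: Path, table: str, stats: ParseStats) -> list[dict[str, str]]:
    rows = []
    required = _FAERS_TABLES[table]
    with open(path, newline="", encoding="utf-8") as fh:
        # '$' delimiter, naive splitting (embedded '$' is not escaped)
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path.name}: empty file")
        header = [h.strip().lower() for h in header_line.rstrip("\n").split("$")]
        missing = set(required) - set(header)
        if missing:
            raise FormatError(f"{path.name}: missing mandatory column(s): {sorted(missing)}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("$")
            if len(fields) != len(header):
                stats.n_malformed += 1
                stats.note(f"{path.name} line {lineno}: {len(fields)} fields, expected {len(header)}")
                continue
            rows.append(dict(zip(header, fields)))
            stats.n_rows[table] = stats.n_rows.get(table, 0) + 1
    return rows


def _age_to_years(age: str, age_cod: str, stats: ParseStats, ctx: str) -> float | None:
    age = age.strip()
    if not age:
        return None
    try:
        value = float(age)
    except ValueError:
        stats.n_malformed += 1
        stats.note(f"{ctx}: unparseable age {age!r}")
        return None
    cod = age_cod.strip().upper() or "YR"
    factor = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12, "WK": 1 / 52.18, "DY": 1 / 365.25, "HR": 1 / 8766.0}.get(cod)
    if factor is None:
        stats.note(f"{ctx}: unknown age unit {cod!r}")
        return None
    years = value * factor
    if not (0 <= years <= 120):
        stats.n_malformed += 1
        stats.note(f"{ctx}: age out of range: {years:.2f}")
        return None
    return years


def read_faers_ascii(paths: Sequence[str | Path]) -> tuple[list[CaseReport], ParseStats]:
    """Read dollar-delimited FAERS quarterly files and join them on primaryid.

    DEMO is the spine.  DRUG/REAC/OUTC/THER rows whose primaryid has no DEMO
    row are counted as orphans and excluded; DEMO rows with no REAC events are
    counted and excluded (a report must carry at least one event).
    """
    stats = ParseStats()
    by_table: dict[str, list[dict[str, str]]] = {t: [] for t in _FAERS_TABLES}
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise OSError(f"no such file: {p}")
        table = _classify_faers_file(p)
        by_table[table].extend(_read_dollar_file(p, table, stats))
    if not by_table["DEMO"]:
        raise FormatError("no DEMO file among inputs")

    demo_ids = {row["primaryid"] for row in by_table["DEMO"]}
    drugs: dict[str, list[dict[str, str]]] = {}
    for row in by_table["DRUG"]:
        pid = row["primaryid"]
        if pid not in demo_ids:
            stats.n_orphans += 1
            stats.note(f"DRUG orphan primaryid {pid}")
            continue
        drugs.setdefault(pid, []).append(row)
    ther: dict[tuple[str, str], date | None] = {}
    for row in by_table["THER"]:
        pid = row["primaryid"]
        if pid not in demo_ids:
            stats.n_orphans += 1
            continue
        ther[(pid, row["dsg_drug_seq"])] = _parse_faers_date(row["start_dt"])
    events: dict[str, list[str]] = {}
    for row in by_table["REAC"]:
        pid = row["primaryid"]
        if pid not in demo_ids:
            stats.n_orphans += 1
            stats.note(f"REAC orphan primaryid {pid}")
            continue
        events.setdefault(pid, []).append(row["pt"].strip())
    outcomes: dict[str, set[OutcomeCode]] = {}
    for row in by_table["OUTC"]:
        pid = row["primaryid"]
        if pid not in demo_ids:
            stats.n_orphans += 1
            continue
        code = _OUTC_CODES.get(row["outc_cod"].strip().upper())
        if code is None:
            stats.n_malformed += 1
            stats.note(f"OUTC unknown code {row['outc_cod']!r}")
            continue
        outcomes.setdefault(pid, set()).add(code)

    reports = []
    for row in by_table["DEMO"]:
        pid = row["primaryid"]
        pid_events = [pt for pt in dict.fromkeys(events.get(pid, [])) if pt]
        if not pid_events:
            stats.n_no_event += 1
            stats.note(f"DEMO primaryid {pid}: no REAC events, excluded")
            continue
        entry_list = []
        for d in drugs.get(pid, []):
            role = _ROLE_CODES.get(d["role_cod"].strip().upper())
            if role is None or not d["drugname"].strip():
                stats.n_malformed += 1
                stats.note(f"DRUG primaryid {pid}: bad role/name")
                continue
            entry_list.append(
                DrugEntry(
                    drug_name=d["drugname"].strip(),
                    role=role,
                    therapy_start_date=ther.get((pid, d["drug_seq"])),
                )
            )
        outc = frozenset(outcomes.get(pid, set()))
        reports.append(
            CaseReport(
                case_id=row["caseid"].strip() or pid,
                version_id=row["caseversion"].strip() or "1",
                receipt_date=_parse_faers_date(row["fda_dt"]),
                sex=_SEX_CODES.get(row["sex"].strip().upper(), Sex.unspecified),
                age_years=_age_to_years(row["age"], row["age_cod"], stats, f"DEMO {pid}"),
                reporter_type=(
                    ReporterType.healthcare_professional
                    if row["occp_cod"].strip().upper() in _HCP_OCCP
                    else ReporterType.consumer
                    if row["occp_cod"].strip().upper() == "CN"
                    else ReporterType.unspecified
                ),
                serious=bool(outc),
                outcomes=outc,
                drugs=entry_list,
                events=pid_events,
                country=row["reporter_country"].strip() or None,
                event_date=_parse_faers_date(row["event_dt"]),
            )
        )
    stats.n_reports = len(reports)
    return reports, stats


def write_faers_ascii(reports: Iterable[CaseReport], outdir: str | Path) -> dict[str, Path]:
    """Write DEMO/DRUG/REAC/OUTC/THER dollar-delimited files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {t: outdir / f"{t}.txt" for t in _FAERS_TABLES}
    handles = {t: open(p, "w", encoding="utf-8") for t, p in paths.items()}
    try:
        for t, fh in handles.items():
            fh.write("$".join(_FAERS_TABLES[t]) + "\n")
        for r in reports:
            pid = f"{r.case_id}{r.version_id}"
            demo = [
                pid,
                r.case_id,
                r.version_id,
                r.receipt_date.strftime("%Y%m%d") if r.receipt_date else "",
                r.event_date.strftime("%Y%m%d") if r.event_date else "",
                {"male": "M", "female": "F"}.get(r.sex.value, ""),
                "" if r.age_years is None else f"{r.age_years:g}",
                "YR",
                "MD" if r.reporter_type is ReporterType.healthcare_professional
                else "CN" if r.reporter_type is ReporterType.consumer else "",
                r.country or "",
            ]
            handles["DEMO"].write("$".join(demo) + "\n")
            for seq, d in enumerate(r.drugs, start=1):
                handles["DRUG"].write(
                    "$".join([pid, str(seq), _ROLE_TO_CODE[d.role], d.drug_name]) + "\n"
                )
                if d.therapy_start_date is not None:
                    handles["THER"].write(
                        "$".join([pid, str(seq), d.therapy_start_date.strftime("%Y%m%d")]) + "\n"
                    )
            for pt in r.events:
                handles["REAC"].write("$".join([pid, pt]) + "\n")
            for o in sorted(r.outcomes, key=lambda x: x.value):
                handles["OUTC"].write("$".join([pid, _OUTC_TO_CODE[o]]) + "\n")
    finally:
        for fh in handles.values():
            fh.close()
    return paths


def read_reports(
    paths: Sequence[str | Path], dialect: str
) -> tuple[list[CaseReport], ParseStats]:
    """Dialect-dispatching facade: ``dialect`` is ``'simple'`` or ``'faers'``."""
    if dialect == "simple":
        if len(paths) != 1:
            raise ConfigError("simple dialect expects exactly one CSV path")
        return read_simple_csv(paths[0])
    if dialect == "faers":
        return read_faers_ascii(paths)
    raise ConfigError(f"unknown dialect: {dialect!r}")


# --------------------------------------------------------------------------
# deduplication


def _version_key(r: CaseReport):
    v = r.version_id.strip()
    numeric = v.isdigit()
    return (
        1 if numeric else 0,
        int(v) if numeric else 0,
        v,
        r.receipt_date or date.min,
    )


def _fingerprint(r: CaseReport):
    # full deterministic tie-break so dedup is order-independent even for
    # records with identical version and receipt date
    return (
        tuple(sorted(r.events)),
        tuple(sorted((d.drug_name, d.role.value) for d in r.drugs)),
        r.sex.value,
        r.age_years if r.age_years is not None else -1.0,
    )


def deduplicate(reports: Iterable[CaseReport]) -> tuple[list[CaseReport], int]:
    """Keep exactly one record per case_id: greatest version_id (numeric when
    both versions are numeric, else lexicographic), ties broken by latest
    receipt date.  Returns (retained, n_removed); output sorted by case_id."""
    by_case: dict[str, list[CaseReport]] = {}
    total = 0
    for r in reports:
        total += 1
        by_case.setdefault(r.case_id, []).append(r)
    retained = []
    for case_id in sorted(by_case):
        group = sorted(by_case[case_id], key=lambda r: (_version_key(r), _fingerprint(r)))
        retained.append(group[-1])
    return retained, total - len(retained)


# --------------------------------------------------------------------------
# component annotation


def annotate_components(
    reports: Iterable[CaseReport],
    registry: ComponentRegistry,
    study_drugs: Sequence[str] | None = None,
) -> int:
    """Attach :class:`ComponentMeta` to every drug entry matching the registry
    (included drugs only); all other drugs stay background (``component=None``).

    When ``study_drugs`` is given, each must resolve in the registry, else
    :class:`ConfigError`.  Returns the number of annotated drug entries.
    """
    if study_drugs is not None:
        unknown = [s for s in study_drugs if registry.lookup(s) is None]
        if unknown:
            raise ConfigError(f"study drug(s) not in registry: {unknown}")
    n = 0
    for r in reports:
        for d in r.drugs:
            meta = registry.lookup(d.drug_name)
            if meta is not None and meta.include:
                d.component = meta
                n += 1
            else:
                d.component = None
    return n
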