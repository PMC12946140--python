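"""Synthetic spontaneous-report generator with known ground truth.

Emulates the statistical structure that disproportionality analysis
assumes: independent reports, each naming one exposure drug (a study ADC
with configured probability, otherwise an anonymous background drug) and
one or more preferred-term events drawn from a background frequency law,
with planted multiplicative relative-reporting-rate (RRR) effects attached
to drugs or to ADC component classes.  Demographics, outcomes, reporter
qualification, countries, therapy-start/event dates (with configurable
missingness and a small implausible fraction), and duplicate case versions
are all generated so every downstream stage is exercisable without any
download.

Deliberately NOT modelled: reporting biases (notoriety, masking),
time-varying reporting rates, realistic country effects, multi-drug cases
(exercised by dedicated fixtures instead) — see the methods note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from adcvigil.report_store import (
    CaseReport,
    ComponentRegistry,
    ConfigError,
    DrugEntry,
    DrugRole,
    MeddraMap,
    OutcomeCode,
    ReporterType,
    Sex,
    builtin_registry,
    default_meddra_map,
    normalize_drug_name,
    write_faers_ascii,
    write_simple_csv,
)
from adcvigil.stratify_contingency import KINDS, build_strata

__all__ = ["PlantedEffect", "SimConfig", "GroundTruth", "pt_name", "generate", "write_dataset"]


def pt_name(index: int) -> str:
    """Canonical preferred-term name for event index ``index`` (0-based)."""
    return f"PT_{index + 1:04d}"


@dataclass(frozen=True)
class PlantedEffect:
    """One planted signal: reports exposed to ``target`` draw ``pt`` with
    ``rrr``-fold elevated sampling weight.

    ``kind='drug'`` targets one study drug by name; component kinds
    ('antibody', 'linker', 'payload', 'dar') expand to every member ADC.
    """

    kind: str
    target: str
    pt: str
    rrr: float

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigError(f"unknown planted-effect kind: {self.kind!r}")
        if self.rrr < 1:
            raise ConfigError(f"rrr must be >= 1, got {self.rrr}")


@dataclass
class SimConfig:
    """Generator configuration.  Defaults emulate the marginal structure of
    ADC spontaneous-report collections: ~55% female, ~80% serious, ~76%
    healthcare-professional reporters, ~47% missing age, heavily missing
    onset dates."""

    n_cases: int = 5000
    n_background_drugs: int = 20
    n_events: int = 50
    background_event_law: str = "zipf"   # 'uniform' | 'zipf'
    zipf_s: float = 1.1
    events_per_case_lambda: float = 2.0  # zero-truncated Poisson
    study_share: float = 0.3             # P(case is exposed to a study ADC)
    study_drugs: tuple[str, ...] = ()    # default: registry's included ADCs
    planted_effects: tuple[PlantedEffect, ...] = ()
    duplicate_fraction: float = 0.0
    missing_date_fraction: float = 0.3   # per date field
    implausible_date_fraction: float = 0.02
    onset_median_days: float = 26.0
    female_frac: float = 0.55
    male_frac: float = 0.27
    serious_frac: float = 0.80
    hcp_frac: float = 0.764
    consumer_frac: float = 0.15
    age_missing_frac: float = 0.47
    age_mean: float = 59.0
    age_sd: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_background_drugs <= 0 or self.n_events <= 0:
            raise ConfigError("n_cases, n_background_drugs, n_events must be positive")
        for name in ("duplicate_fraction", "missing_date_fraction", "implausible_date_fraction"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ConfigError(f"{name} must be in [0, 1), got {v}")
        for name in ("study_share", "female_frac", "male_frac", "serious_frac",
                     "hcp_frac", "consumer_frac", "age_missing_frac"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.female_frac + self.male_frac > 1 or self.hcp_frac + self.consumer_frac > 1:
            raise ConfigError("categorical fractions exceed 1")
        if self.background_event_law not in ("uniform", "zipf"):
            raise ConfigError(f"unknown background_event_law: {self.background_event_law!r}")
        if self.events_per_case_lambda <= 0 or self.zipf_s <= 0:
            raise ConfigError("events_per_case_lambda and zipf_s must be positive")
        if self.onset_median_days <= 0:
            raise ConfigError("onset_median_days must be positive")
        vocab = {pt_name(i) for i in range(self.n_events)}
        for eff in self.planted_effects:
            if eff.pt not in vocab:
                raise ConfigError(
                    f"planted PT {eff.pt!r} outside the event vocabulary "
                    f"(n_events={self.n_events})"
                )


@dataclass
class GroundTruth:
    """What was planted and who was exposed to what."""

    #: expanded planted set: (kind, stratum label, pt, rrr, member drugs)
    planted: list[dict]
    #: per original case (before duplication): exposure drug and study flag
    exposure: list[dict]
    meddra: dict[str, str] = field(default_factory=dict)

    def planted_pairs(self) -> set[tuple[str, str]]:
        """(stratum label, pt) pairs carrying a planted effect."""
        return {(p["label"], p["pt"]) for p in self.planted}

    def planted_drug_pairs(self) -> set[tuple[str, str]]:
        """(member drug, pt) pairs after class expansion."""
        return {(m, p["pt"]) for p in self.planted for m in p["member_drugs"]}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {"planted": self.planted, "exposure": self.exposure, "meddra": self.meddra},
                fh,
                indent=1,
            )


_OUTCOME_WEIGHTS = {
    OutcomeCode.death: 0.227,
    OutcomeCode.hospitalization: 0.217,
    OutcomeCode.life_threatening: 0.033,
    OutcomeCode.disability: 0.008,
    OutcomeCode.other_serious: 0.515,
}
_COUNTRIES = ("US", "JP", "FR", "CA", "CN", "OTHER")
_COUNTRY_WEIGHTS = (0.365, 0.14, 0.077, 0.063, 0.038, 0.317)
_EPOCH_START = date(2015, 1, 1)
_EPOCH_DAYS = (date(2024, 12, 31) - _EPOCH_START).days


def _base_weights(cfg: SimConfig) -> np.ndarray:
    if cfg.background_event_law == "uniform":
        w = np.ones(cfg.n_events)
    else:
        w = 1.0 / np.arange(1, cfg.n_events + 1, dtype=float) ** cfg.zipf_s
    return w / w.sum()


def _truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson via inverse CDF on uniforms above P(0)."""
    p0 = np.exp(-lam)
    u = p0 + rng.random(size) * (1 - p0)
    return stats.poisson.ppf(u, lam).astype(np.int64)


def _expand_effects(
    cfg: SimConfig, registry: ComponentRegistry, study: list[str]
) -> tuple[list[dict], dict[str, dict[int, float]]]:
    """Resolve planted effects to member drugs.

    Returns the expanded ground-truth list and, per affected drug, the
    mapping event-index -> rrr (max when several effects touch one pair).
    """
    strata = {k: {s.label: s for s in build_strata(registry, k)} for k in KINDS if k != "drug"}
    vocab = {pt_name(i): i for i in range(cfg.n_events)}
    planted: list[dict] = []
    per_drug: dict[str, dict[int, float]] = {}
    for eff in cfg.planted_effects:
        if eff.kind == "drug":
            members = [normalize_drug_name(eff.target)]
            if members[0] not in study:
                raise ConfigError(f"planted drug {eff.target!r} not among study drugs")
        else:
            stratum = strata[eff.kind].get(eff.target)
            if stratum is None:
                raise ConfigError(f"no {eff.kind} stratum labelled {eff.target!r}")
            members = sorted(stratum.member_drugs & set(study))
            if not members:
                raise ConfigError(f"planted class {eff.target!r} has no study member drugs")
        planted.append(
            {"kind": eff.kind, "label": eff.target, "pt": eff.pt, "rrr": eff.rrr,
             "member_drugs": members}
        )
        for m in members:
            idx = vocab[eff.pt]
            per_drug.setdefault(m, {})
            per_drug[m][idx] = max(per_drug[m].get(idx, 1.0), eff.rrr)
    return planted, per_drug


def generate(
    config: SimConfig, registry: ComponentRegistry | None = None
) -> tuple[list[CaseReport], GroundTruth]:
    """Generate a report collection plus its ground truth.

    Deterministic given ``config`` (all randomness flows from one generator
    seeded with ``config.seed``).  Each case carries exactly one exposure
    drug with primary-suspect role; events are sampled with replacement and
    de-duplicated within the case.
    """
    cfg = config
    registry = registry if registry is not None else builtin_registry()
    study = (
        [normalize_drug_name(s) for s in cfg.study_drugs]
        if cfg.study_drugs
        else registry.included_names()
    )
    for s in study:
        if registry.lookup(s) is None:
            raise ConfigError(f"study drug {s!r} not in registry")
    planted, per_drug_rrr = _expand_effects(cfg, registry, study)

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cases

    # exposure: one drug per case
    is_study = rng.random(n) < cfg.study_share
    study_idx = rng.integers(0, len(study), size=n)
    bg_idx = rng.integers(0, cfg.n_background_drugs, size=n)
    drug_names = np.where(
        is_study,
        np.array(study, dtype=object)[study_idx],
        np.array([f"backgrounddrug{j:03d}" for j in range(cfg.n_background_drugs)], dtype=object)[bg_idx],
    )

    # event sampling, grouped by weight profile (base, or per planted drug)
    base_w = _base_weights(cfg)
    profiles: dict[str, np.ndarray] = {}
    for drug, boosts in per_drug_rrr.items():
        w = base_w.copy()
        for idx, rrr in boosts.items():
            w[idx] *= rrr
        profiles[drug] = w / w.sum()
    k = _truncated_poisson(rng, cfg.events_per_case_lambda, n)
    profile_of = np.array([d if d in profiles else "" for d in drug_names], dtype=object)
    case_events: list[list[str]] = [[] for _ in range(n)]
    for key in [""] + sorted(profiles):
        w = base_w if key == "" else profiles[key]
        sel = np.flatnonzero(profile_of == key)
        if sel.size == 0:
            continue
        draws = rng.choice(cfg.n_events, size=int(k[sel].sum()), p=w)
        offsets = np.concatenate([[0], np.cumsum(k[sel])])
        for j, case in enumerate(sel):
            uniq = list(dict.fromkeys(draws[offsets[j]:offsets[j + 1]]))
            case_events[case] = [pt_name(i) for i in uniq]

    # demographics
    u_sex = rng.random(n)
    sexes = np.where(
        u_sex < cfg.female_frac, "female", np.where(u_sex < cfg.female_frac + cfg.male_frac, "male", "unspecified")
    )
    ages = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 0.2, 110.0).round(1)
    age_missing = rng.random(n) < cfg.age_missing_frac
    u_rep = rng.random(n)
    reporters = np.where(
        u_rep < cfg.hcp_frac,
        "healthcare_professional",
        np.where(u_rep < cfg.hcp_frac + cfg.consumer_frac, "consumer", "unspecified"),
    )
    serious = rng.random(n) < cfg.serious_frac
    outc_codes = list(_OUTCOME_WEIGHTS)
    outc_draw = rng.choice(len(outc_codes), size=n, p=np.array(list(_OUTCOME_WEIGHTS.values())))
    countries = np.array(_COUNTRIES, dtype=object)[
        rng.choice(len(_COUNTRIES), size=n, p=np.array(_COUNTRY_WEIGHTS))
    ]

    # dates
    receipt_off = rng.integers(0, _EPOCH_DAYS + 1, size=n)
    start_off = receipt_off - rng.integers(30, 400, size=n)
    onset = np.maximum(np.rint(rng.exponential(cfg.onset_median_days / np.log(2), n)), 0).astype(np.int64)
    implausible = rng.random(n) < cfg.implausible_date_fraction
    onset = np.where(implausible, -(onset + 1), onset)
    start_missing = rng.random(n) < cfg.missing_date_fraction
    event_missing = rng.random(n) < cfg.missing_date_fraction

    reports: list[CaseReport] = []
    for i in range(n):
        start = _EPOCH_START + timedelta(days=int(start_off[i]))
        reports.append(
            CaseReport(
                case_id=f"SIM{i:07d}",
                version_id="1",
                receipt_date=_EPOCH_START + timedelta(days=int(receipt_off[i])),
                sex=Sex(str(sexes[i])),
                age_years=None if age_missing[i] else float(ages[i]),
                reporter_type=ReporterType(str(reporters[i])),
                serious=bool(serious[i]),
                outcomes=frozenset({outc_codes[outc_draw[i]]}) if serious[i] else frozenset(),
                drugs=[
                    DrugEntry(
                        drug_name=str(drug_names[i]),
                        role=DrugRole.primary_suspect,
                        therapy_start_date=None if start_missing[i] else start,
                    )
                ],
                events=case_events[i],
                country=str(countries[i]),
                event_date=None if event_missing[i] else start + timedelta(days=int(onset[i])),
            )
        )

    # duplicate case versions
    n_dup = int(round(cfg.duplicate_fraction * n))
    if n_dup:
        dup_idx = np.sort(rng.choice(n, size=n_dup, replace=False))
        for i in dup_idx:
            orig = reports[i]
            reports.append(
                CaseReport(
                    case_id=orig.case_id,
                    version_id="2",
                    receipt_date=(orig.receipt_date + timedelta(days=30)) if orig.receipt_date else None,
                    sex=orig.sex,
                    age_years=orig.age_years,
                    reporter_type=orig.reporter_type,
                    serious=orig.serious,
                    outcomes=orig.outcomes,
                    drugs=[DrugEntry(d.drug_name, d.role, d.therapy_start_date) for d in orig.drugs],
                    events=list(orig.events),
                    country=orig.country,
                    event_date=orig.event_date,
                )
            )

    meddra = default_meddra_map([pt_name(i) for i in range(cfg.n_events)])
    truth = GroundTruth(
        planted=planted,
        exposure=[
            {"case_id": f"SIM{i:07d}", "drug": str(drug_names[i]), "is_study": bool(is_study[i])}
            for i in range(n)
        ],
        meddra=dict(meddra.pt_to_soc),
    )
    return reports, truth


def write_dataset(
    reports: Sequence[CaseReport],
    truth: GroundTruth,
    outdir: str | Path,
    dialect: str = "simple",
) -> dict[str, Path]:
    """Write the collection in the requested dialect plus ground-truth JSON
    and the PT->SOC map CSV.  Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if dialect == "simple":
        paths["reports"] = outdir / "reports.csv"
        write_simple_csv(reports, paths["reports"])
    elif dialect == "faers":
        paths.update(write_faers_ascii(reports, outdir))
    else:
        raise ConfigError(f"unknown dialect: {dialect!r}")
    paths["ground_truth"] = outdir / "ground_truth.json"
    truth.to_json(paths["ground_truth"])
    paths["meddra"] = outdir / "pt_soc_map.csv"
    MeddraMap(dict(truth.meddra)).to_csv(paths["meddra"])
    return paths
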