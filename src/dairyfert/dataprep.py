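"""Fertility-record editing and trait derivation.

Raw inputs are one event record per cow x parity: calving dates, the
insemination sequence of that breeding episode, conception, calf sex, farm
and region.  From these the interval traits are derived in integer days —
calving interval (CI), days open (DO), calving to first insemination
(CTFS), first insemination to conception (FSTC), gestation length (GL),
age at first service (AFS), age at first calving (AFC) — plus the number
of services (NS) and the binary 56-day non-return rate (NRR).

Editing follows the usual dairy-recording rules: duplicate cow x parity
records collapsed, inconsistent duplicates removed entirely, animals absent
from the pedigree dropped, and per-trait values beyond 4 standard
deviations discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

__all__ = [
    "EventRecord",
    "TraitDataset",
    "ModelSpec",
    "DEFAULT_SPECS",
    "INTERVAL_TRAITS",
    "merge_dedup",
    "derive_traits",
    "code_nrr",
    "filter_outliers",
    "filter_dataset",
    "match_pedigree",
    "build_effect_classes",
    "descriptive_stats",
    "prepare_trait",
    "read_events",
    "write_events",
    "load_config",
]

INTERVAL_TRAITS = ("CI", "DO", "CTFS", "FSTC", "GL", "AFS", "AFC")
ALL_TRAITS = INTERVAL_TRAITS + ("NS", "NRR")


@dataclass(frozen=True)
class EventRecord:
    """One breeding episode of one cow (parity 0 = heifer episode)."""

    cow_id: str
    parity: int
    birth_date: date | None = None
    previous_calving_date: date | None = None  # calving opening the episode
    calving_date: date | None = None           # calving closing the episode
    insemination_dates: tuple[date, ...] = ()
    conception_date: date | None = None
    service_sire_ids: tuple[str, ...] = ()
    calf_sex: str | None = None                # sex of the calf born at calving_date
    farm_id: str | None = None
    region: str | None = None

    def first_insemination(self) -> date | None:
        return self.insemination_dates[0] if self.insemination_dates else None

    @property
    def stage(self) -> str:
        return "heifer" if self.parity == 0 else "cow"


@dataclass(frozen=True)
class ModelSpec:
    """Fixed/random effect layout of one trait x stage analysis.

    Effect names: RYM (region x birth year x birth month), Mf (month of
    first insemination), MfX (Mf x calf sex), AcMcX (current-calving age
    class x calving month x calf sex x parity), ApMf / ApMp / ApMpX
    (previous-calving age class analogues), stage (for merged analyses);
    random effects: HY (herd x birth year), SS (service sire), a (animal).
    """

    trait: str
    stage: str
    fixed_effects: tuple[str, ...]
    random_effects: tuple[str, ...]

    def __post_init__(self):
        if "a" not in self.random_effects:
            raise ValueError("the additive animal effect 'a' is always fitted")

    @property
    def has_ss(self) -> bool:
        return "SS" in self.random_effects

    @property
    def has_hy(self) -> bool:
        return "HY" in self.random_effects


def _spec(trait, stage, fixed, random=("HY", "a")) -> ModelSpec:
    return ModelSpec(trait, stage, tuple(fixed), tuple(random))


#: per trait x stage effect layout used for the published analyses
DEFAULT_SPECS: dict[tuple[str, str], ModelSpec] = {
    ("AFS", "heifer"): _spec("AFS", "heifer", ("RYM",)),
    ("AFC", "heifer"): _spec("AFC", "heifer", ("RYM",)),
    ("NRR", "heifer"): _spec("NRR", "heifer", ("RYM", "Mf"), ("HY", "SS", "a")),
    ("NRR", "cow"): _spec("NRR", "cow", ("RYM", "ApMf"), ("HY", "SS", "a")),
    ("NS", "heifer"): _spec("NS", "heifer", ("RYM", "Mf")),
    ("NS", "cow"): _spec("NS", "cow", ("RYM", "ApMf")),
    ("FSTC", "heifer"): _spec("FSTC", "heifer", ("RYM", "Mf")),
    ("FSTC", "cow"): _spec("FSTC", "cow", ("RYM", "ApMf")),
    ("GL", "heifer"): _spec("GL", "heifer", ("RYM", "MfX"), ("HY", "SS", "a")),
    ("GL", "cow"): _spec("GL", "cow", ("RYM", "ApMpX"), ("HY", "SS", "a")),
    ("DO", "cow"): _spec("DO", "cow", ("RYM", "AcMcX")),
    ("CTFS", "cow"): _spec("CTFS", "cow", ("RYM", "ApMp")),
    ("CI", "cow"): _spec("CI", "cow", ("RYM", "ApMp")),
}


@dataclass
class TraitDataset:
    """One trait's response vector plus effect-label vectors.

    ``records`` keeps the per-row context (dates, farm, sire ids) needed to
    build composite effect classes; ``fixed``/``hy_labels``/``ss_ids`` are
    filled by :func:`build_effect_classes`.
    """

    trait: str
    stage: str
    animal_ids: np.ndarray
    y: np.ndarray
    records: pd.DataFrame
    fixed: dict[str, np.ndarray] = field(default_factory=dict)
    hy_labels: np.ndarray | None = None
    ss_ids: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.y)

    def subset(self, mask: np.ndarray) -> "TraitDataset":
        mask = np.asarray(mask, dtype=bool)
        return TraitDataset(
            trait=self.trait,
            stage=self.stage,
            animal_ids=self.animal_ids[mask],
            y=self.y[mask],
            records=self.records.loc[mask].reset_index(drop=True),
            fixed={k: v[mask] for k, v in self.fixed.items()},
            hy_labels=None if self.hy_labels is None else self.hy_labels[mask],
            ss_ids=None if self.ss_ids is None else self.ss_ids[mask],
        )

    def concatenate(self, other: "TraitDataset", stage: str = "all") -> "TraitDataset":
        """Stack two stage datasets of the same trait (for merged analyses)."""
        if other.trait != self.trait:
            raise ValueError("can only concatenate datasets of the same trait")
        fixed = {
            k: np.concatenate([self.fixed[k], other.fixed[k]])
            for k in self.fixed
            if k in other.fixed
        }
        cat = lambda a, b: None if a is None or b is None else np.concatenate([a, b])
        return TraitDataset(
            trait=self.trait,
            stage=stage,
            animal_ids=np.concatenate([self.animal_ids, other.animal_ids]),
            y=np.concatenate([self.y, other.y]),
            records=pd.concat([self.records, other.records], ignore_index=True),
            fixed=fixed,
            hy_labels=cat(self.hy_labels, other.hy_labels),
            ss_ids=cat(self.ss_ids, other.ss_ids),
        )


# ---------------------------------------------------------------------------
# record editing


def merge_dedup(records: list[EventRecord]) -> list[EventRecord]:
    """One record per (cow, parity); conflicting duplicates dropped entirely.

    Exact duplicates collapse to one row.  Records sharing a key but
    disagreeing in any field are treated as recording errors (the same cow
    number attached to inconsistent information) and all copies are removed.
    """
    groups: dict[tuple[str, int], list[EventRecord]] = {}
    order: list[tuple[str, int]] = []
    for r in records:
        key = (r.cow_id, r.parity)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)
    out: list[EventRecord] = []
    n_conflict = 0
    for key in order:
        uniq = set(groups[key])
        if len(uniq) == 1:
            out.append(groups[key][0])
        else:
            n_conflict += 1
    if n_conflict:
        log.info("merge_dedup: dropped %d cow x parity keys with conflicting duplicates", n_conflict)
    return out


def _days(later: date | None, earlier: date | None) -> float | None:
    if later is None or earlier is None:
        return None
    return float((later - earlier).days)


def _trait_value(r: EventRecord, trait: str) -> float | None:
    fi = r.first_insemination()
    if trait == "CI":
        return _days(r.calving_date, r.previous_calving_date) if r.parity > 0 else None
    if trait == "DO":
        return _days(r.conception_date, r.previous_calving_date) if r.parity > 0 else None
    if trait == "CTFS":
        return _days(fi, r.previous_calving_date) if r.parity > 0 else None
    if trait == "FSTC":
        return _days(r.conception_date, fi)
    if trait == "GL":
        return _days(r.calving_date, r.conception_date)
    if trait == "AFS":
        return _days(fi, r.birth_date) if r.parity == 0 else None
    if trait == "AFC":
        return _days(r.calving_date, r.birth_date) if r.parity == 0 else None
    if trait == "NS":
        if r.conception_date is None or not r.insemination_dates:
            return None
        return float(sum(1 for d in r.insemination_dates if d <= r.conception_date))
    raise ValueError(f"unknown trait {trait!r}")


def _context_frame(records: list[EventRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": [r.cow_id for r in records],
            "parity": [r.parity for r in records],
            "stage": [r.stage for r in records],
            "region": [r.region for r in records],
            "farm": [r.farm_id for r in records],
            "birth_date": [r.birth_date for r in records],
            "previous_calving": [r.previous_calving_date for r in records],
            "calving": [r.calving_date for r in records],
            "first_insem": [r.first_insemination() for r in records],
            "conception": [r.conception_date for r in records],
            "calf_sex": [r.calf_sex for r in records],
            "ss_first": [
                r.service_sire_ids[0] if r.service_sire_ids else None for r in records
            ],
            "ss_conception": [_conceiving_sire(r) for r in records],
        }
    )


def _conceiving_sire(r: EventRecord) -> str | None:
    if r.conception_date is None:
        return r.service_sire_ids[0] if r.service_sire_ids else None
    for d, s in zip(r.insemination_dates, r.service_sire_ids):
        if d == r.conception_date:
            return s
    return r.service_sire_ids[-1] if r.service_sire_ids else None


def derive_traits(
    records: list[EventRecord],
    traits: tuple[str, ...] = INTERVAL_TRAITS + ("NS",),
) -> dict[tuple[str, str], TraitDataset]:
    """Interval and count traits per (trait, stage); NRR has its own coder.

    Interval traits must be strictly positive (FSTC may be 0: conception at
    first service); rows with missing required dates are skipped and logged.
    """
    out: dict[tuple[str, str], TraitDataset] = {}
    for trait in traits:
        rows, vals = [], []
        n_skip = 0
        for r in records:
            v = _trait_value(r, trait)
            if v is None:
                n_skip += 1
                continue
            low = 0.0 if trait in ("FSTC", "NS") else 1.0
            if v < low or (trait == "NS" and v < 1):
                n_skip += 1
                continue
            rows.append(r)
            vals.append(v)
        if n_skip:
            log.debug("derive_traits: %s skipped %d records", trait, n_skip)
        if not rows:
            continue
        for stage in ("heifer", "cow"):
            sel = [i for i, r in enumerate(rows) if r.stage == stage]
            if not sel:
                continue
            sub = [rows[i] for i in sel]
            out[(trait, stage)] = TraitDataset(
                trait=trait,
                stage=stage,
                animal_ids=np.array([r.cow_id for r in sub], dtype=object),
                y=np.array([vals[i] for i in sel], dtype=float),
                records=_context_frame(sub),
            )
    return out


def code_nrr(
    records: list[EventRecord],
    window_days: int = 56,
    anchor: str = "insemination",
    success_value: int = 1,
) -> dict[tuple[str, str], TraitDataset]:
    """Binary 56-day non-return rate per stage.

    ``success_value`` (default 1) is assigned when **no** further
    insemination occurs within ``window_days`` of the anchor — the cow did
    not return to estrus, i.e. presumably conceived.  ``anchor`` is
    ``"insemination"`` (first insemination of the episode, the conventional
    definition) or ``"calving"`` (the calving opening the episode).
    """
    if anchor not in ("insemination", "calving"):
        raise ValueError("anchor must be 'insemination' or 'calving'")
    out: dict[tuple[str, str], TraitDataset] = {}
    for stage in ("heifer", "cow"):
        sub, vals = [], []
        for r in records:
            if r.stage != stage:
                continue
            fi = r.first_insemination()
            if fi is None:
                continue
            anchor_date = fi
            if anchor == "calving":
                if r.previous_calving_date is None:
                    continue
                anchor_date = r.previous_calving_date
            returned = any(
                0 < (d - anchor_date).days <= window_days
                for d in r.insemination_dates
                if d > fi
            )
            sub.append(r)
            vals.append(1 - success_value if returned else success_value)
        if not sub:
            continue
        out[("NRR", stage)] = TraitDataset(
            trait="NRR",
            stage=stage,
            animal_ids=np.array([r.cow_id for r in sub], dtype=object),
            y=np.array(vals, dtype=float),
            records=_context_frame(sub),
        )
    return out


def filter_outliers(y: np.ndarray, k: float = 4.0, two_sided: bool = True) -> np.ndarray:
    """Keep mask for the k-standard-deviation edit (single pass, n-1 SD)."""
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        return np.ones(len(y), dtype=bool)
    sd = float(np.std(y, ddof=1))
    if sd == 0.0:
        return np.ones(len(y), dtype=bool)
    dev = y - float(np.mean(y))
    if two_sided:
        return np.abs(dev) <= k * sd
    return dev <= k * sd


def filter_dataset(ds: TraitDataset, k: float = 4.0, two_sided: bool = True) -> TraitDataset:
    return ds.subset(filter_outliers(ds.y, k=k, two_sided=two_sided))


def match_pedigree(ds: TraitDataset, ped) -> TraitDataset:
    """Drop rows whose animal is absent from the pedigree (count logged)."""
    mask = np.array([a in ped for a in ds.animal_ids], dtype=bool)
    n_drop = int((~mask).sum())
    if n_drop:
        log.info("match_pedigree: dropped %d of %d records (%s %s)",
                 n_drop, ds.n, ds.trait, ds.stage)
    return ds.subset(mask)


# ---------------------------------------------------------------------------
# effect classes


def _month(d) -> str:
    return "NA" if d is None else f"{d.month:02d}"


def _year(d) -> str:
    return "NA" if d is None else str(d.year)


def _age_months(later, earlier) -> str:
    if later is None or earlier is None:
        return "NA"
    return str(int((later - earlier).days / 30.4375))


def _effect_components(row: pd.Series, effect: str) -> list[str]:
    # each composite is a string join of its components
    if effect == "RYM":
        return [str(row["region"]), _year(row["birth_date"]), _month(row["birth_date"])]
    if effect == "Mf":
        return [_month(row["first_insem"])]
    if effect == "MfX":
        return [_month(row["first_insem"]), str(row["calf_sex"])]
    if effect == "AcMcX":
        return [
            _age_months(row["calving"], row["birth_date"]),
            _month(row["calving"]),
            str(row["calf_sex"]),
            str(row["parity"]),
        ]
    if effect == "ApMf":
        return [
            _age_months(row["previous_calving"], row["birth_date"]),
            _month(row["first_insem"]),
            str(row["parity"]),
        ]
    if effect == "ApMp":
        return [
            _age_months(row["previous_calving"], row["birth_date"]),
            _month(row["previous_calving"]),
            str(row["parity"]),
        ]
    if effect == "ApMpX":
        return _effect_components(row, "ApMp") + [str(row["calf_sex"])]
    if effect == "stage":
        return [str(row["stage"])]
    raise ValueError(f"unknown fixed effect {effect!r}")


_EFFECT_FIELDS = {
    "RYM": ("region", "birth_date"),
    "Mf": ("first_insem",),
    "MfX": ("first_insem", "calf_sex"),
    "AcMcX": ("calving", "birth_date", "calf_sex"),
    "ApMf": ("previous_calving", "birth_date", "first_insem"),
    "ApMp": ("previous_calving", "birth_date"),
    "ApMpX": ("previous_calving", "birth_date", "calf_sex"),
    "stage": ("stage",),
}


def build_effect_classes(
    ds: TraitDataset, spec: ModelSpec, min_count: int = 3
) -> TraitDataset:
    """Attach composite fixed-effect labels and random-effect labels.

    Fixed-effect classes with fewer than ``min_count`` observations are
    merged into a per-effect ``OTHER`` level so the mixed-model equations
    stay well conditioned.  HY = farm x birth year.  The service sire is
    the first-service bull for NRR and the conceiving bull otherwise.
    """
    rec = ds.records
    fixed: dict[str, np.ndarray] = {}
    for effect in spec.fixed_effects:
        for fld in _EFFECT_FIELDS[effect]:
            if rec[fld].isna().all():
                raise ValueError(f"effect {effect!r} needs field {fld!r}, all missing")
        labels = np.array(
            ["/".join(_effect_components(row, effect)) for _, row in rec.iterrows()],
            dtype=object,
        )
        if min_count > 1:
            counts = pd.Series(labels).value_counts()
            rare = set(counts[counts < min_count].index)
            if rare:
                labels = np.array(
                    [lab if lab not in rare else "OTHER" for lab in labels],
                    dtype=object,
                )
        fixed[effect] = labels
    hy = None
    if spec.has_hy:
        hy = np.array(
            [f"{f}/{_year(b)}" for f, b in zip(rec["farm"], rec["birth_date"])],
            dtype=object,
        )
    ss = None
    if spec.has_ss:
        col = "ss_first" if spec.trait == "NRR" else "ss_conception"
        ss = rec[col].to_numpy(dtype=object)
    return TraitDataset(
        trait=ds.trait,
        stage=ds.stage,
        animal_ids=ds.animal_ids,
        y=ds.y,
        records=rec,
        fixed=fixed,
        hy_labels=hy,
        ss_ids=ss,
    )


def descriptive_stats(ds: TraitDataset | np.ndarray) -> pd.Series:
    """N, mean, SD (n-1), min, max — the usual descriptive summary row."""
    y = ds.y if isinstance(ds, TraitDataset) else np.asarray(ds, dtype=float)
    return pd.Series(
        {
            "N": int(len(y)),
            "mean": float(np.mean(y)),
            "SD": float(np.std(y, ddof=1)) if len(y) > 1 else 0.0,
            "min": float(np.min(y)),
            "max": float(np.max(y)),
        }
    )


def prepare_trait(
    records: list[EventRecord],
    trait: str,
    stage: str,
    ped,
    spec: ModelSpec | None = None,
    k: float = 4.0,
    min_count: int = 3,
    window_days: int = 56,
) -> TraitDataset:
    """Full editing pipeline for one trait x stage.

    Order: merge/dedup -> derive -> pedigree match -> 4-SD filter -> effect
    classes.  Binary NRR skips the SD edit (it cannot exceed 4 SD).
    """
    spec = spec or DEFAULT_SPECS[(trait, stage)]
    merged = merge_dedup(records)
    if trait == "NRR":
        derived = code_nrr(merged, window_days=window_days)
    else:
        derived = derive_traits(merged, traits=(trait,))
    if (trait, stage) not in derived:
        raise ValueError(f"no usable records for {trait} ({stage})")
    ds = match_pedigree(derived[(trait, stage)], ped)
    if trait != "NRR":
        ds = filter_dataset(ds, k=k)
    return build_effect_classes(ds, spec, min_count=min_count)


# ---------------------------------------------------------------------------
# external interfaces

_DATE_COLS = ("birth_date", "previous_calving_date", "calving_date", "conception_date")


def _parse_date(tok) -> date | None:
    if tok is None or (isinstance(tok, float) and np.isnan(tok)) or str(tok) == "":
        return None
    return date.fromisoformat(str(tok))


def read_events(path, column_map: dict[str, str] | None = None) -> list[EventRecord]:
    """Read events CSV; list fields are ';'-joined, dates ISO-8601.

    ``column_map`` maps our field names to the file's column names.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cm = {f: f for f in (
        "cow_id", "parity", *_DATE_COLS, "insemination_dates",
        "service_sire_ids", "calf_sex", "farm_id", "region",
    )}
    if column_map:
        cm.update(column_map)
    out = []
    for _, row in df.iterrows():
        get = lambda f: row[cm[f]] if cm[f] in row and row[cm[f]] != "" else None
        insems = get("insemination_dates")
        sires = get("service_sire_ids")
        out.append(
            EventRecord(
                cow_id=str(row[cm["cow_id"]]),
                parity=int(row[cm["parity"]]),
                birth_date=_parse_date(get("birth_date")),
                previous_calving_date=_parse_date(get("previous_calving_date")),
                calving_date=_parse_date(get("calving_date")),
                insemination_dates=tuple(
                    date.fromisoformat(t) for t in insems.split(";")
                ) if insems else (),
                conception_date=_parse_date(get("conception_date")),
                service_sire_ids=tuple(sires.split(";")) if sires else (),
                calf_sex=get("calf_sex"),
                farm_id=get("farm_id"),
                region=get("region"),
            )
        )
    return out


def write_events(records: list[EventRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "cow_id": r.cow_id,
                "parity": r.parity,
                "birth_date": r.birth_date or "",
                "previous_calving_date": r.previous_calving_date or "",
                "calving_date": r.calving_date or "",
                "insemination_dates": ";".join(d.isoformat() for d in r.insemination_dates),
                "conception_date": r.conception_date or "",
                "service_sire_ids": ";".join(r.service_sire_ids),
                "calf_sex": r.calf_sex or "",
                "farm_id": r.farm_id or "",
                "region": r.region or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_config(path) -> dict:
    """YAML run configuration: traits, window_days, k, min class size, etc."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    cfg.setdefault("traits", list(ALL_TRAITS))
    cfg.setdefault("window_days", 56)
    cfg.setdefault("k", 4.0)
    cfg.setdefault("min_class_size", 3)
    return cfg
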