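"""Synthetic pedigrees and fertility records with known true parameters.

Nothing here depends on proprietary herd data: multi-generation pedigrees
are simulated with heavy sire reuse (AI half-sib families), breeding
values by the Mendelian-sampling recursion (exact under the numerator
relationship matrix, linear time), and phenotypes either directly from the
linear model (for estimator-recovery studies) or as full event timelines
(calvings, insemination sequences, conceptions) whose date arithmetic
reconstructs the generating interval values exactly.

Default variance magnitudes sit in the neighbourhood of published
estimates for Holstein fertility traits: e.g. AFC-like
h2 ~ 0.19, CI-like h2 ~ 0.012, NRR analyzed linearly with h2 of a few
per mille.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .dataprep import EventRecord, TraitDataset
from .pedigree import Pedigree

__all__ = [
    "TraitTruth",
    "BivariateTruth",
    "SimTruth",
    "TRAIT_TRUTH_DEFAULTS",
    "simulate_pedigree",
    "random_pedigree",
    "simulate_breeding_values",
    "simulate_trait_dataset",
    "simulate_bivariate_dataset",
    "simulate_events",
    "fixture_small",
    "truth_to_yaml",
]

ORIGIN = date(2008, 1, 1)


@dataclass(frozen=True)
class TraitTruth:
    """Generating parameters of one trait x stage."""

    trait: str
    stage: str
    mu: float
    sigma2_a: float
    sigma2_e: float
    sigma2_hy: float | None = None
    sigma2_ss: float | None = None

    @property
    def total(self) -> float:
        return (
            self.sigma2_a
            + self.sigma2_e
            + (self.sigma2_hy or 0.0)
            + (self.sigma2_ss or 0.0)
        )

    @property
    def h2(self) -> float:
        return self.sigma2_a / self.total


@dataclass(frozen=True)
class BivariateTruth:
    """Generating 2x2 covariance blocks of a heifer/cow trait pair."""

    trait: str
    mu: tuple[float, float]
    G: np.ndarray
    HY: np.ndarray
    R: np.ndarray
    SS: np.ndarray | None = None

    @property
    def rg(self) -> float:
        return float(self.G[0, 1] / np.sqrt(self.G[0, 0] * self.G[1, 1]))

    def h2(self, t: int) -> float:
        tot = self.G[t, t] + self.HY[t, t] + self.R[t, t]
        if self.SS is not None:
            tot += self.SS[t, t]
        return float(self.G[t, t] / tot)


#: generating parameters in the neighbourhood of published Holstein values
TRAIT_TRUTH_DEFAULTS: dict[tuple[str, str], TraitTruth] = {
    ("CI", "cow"): TraitTruth("CI", "cow", 429.19, 109.14, 8690.96, 446.55),
    ("DO", "cow"): TraitTruth("DO", "cow", 156.75, 155.28, 8894.42, 208.06),
    ("AFS", "heifer"): TraitTruth("AFS", "heifer", 467.48, 215.09, 1172.98, 2149.04),
    ("AFC", "heifer"): TraitTruth("AFC", "heifer", 781.87, 1137.22, 3462.47, 1300.42),
    ("CTFS", "cow"): TraitTruth("CTFS", "cow", 80.22, 0.71, 860.05, 30.06),
    ("FSTC", "cow"): TraitTruth("FSTC", "cow", 61.83, 43.13, 6130.55, 179.42),
    ("FSTC", "heifer"): TraitTruth("FSTC", "heifer", 20.31, 115.14, 1105.28, 245.44),
    ("GL", "cow"): TraitTruth("GL", "cow", 276.68, 8.52, 57.46, 1.19, 1.00),
    ("GL", "heifer"): TraitTruth("GL", "heifer", 278.42, 2.31, 39.24, 4.59, 0.66),
    ("NRR", "cow"): TraitTruth("NRR", "cow", 0.4576, 0.34e-3, 0.22, 0.94e-2, 0.19e-1),
    ("NRR", "heifer"): TraitTruth("NRR", "heifer", 0.2969, 0.40e-4, 0.17, 0.23e-1, 0.41e-1),
    ("NS", "cow"): TraitTruth("NS", "cow", 2.25, 0.76e-7, 2.14, 0.12),
    ("NS", "heifer"): TraitTruth("NS", "heifer", 1.58, 0.50e-1, 0.74, 0.17),
}


@dataclass(frozen=True)
class SimTruth:
    """Pedigree/herd structure plus per-trait generating parameters."""

    n_founder_sires: int = 25
    n_founder_dams: int = 300
    n_generations: int = 3          # generations bred after the founders
    n_per_generation: int = 300
    sires_per_generation: int = 12  # heavy reuse -> half-sib families
    prop_female: float = 0.85
    n_herds: int = 8
    n_regions: int = 2
    n_parities: int = 2             # cow episodes per female in event sim
    conception_p: tuple[float, float] = (0.55, 0.45)   # heifer, cow
    ns_cap: tuple[int, int] = (6, 9)
    dup_rate: float = 0.0
    corrupt_rate: float = 0.0
    traits: dict = field(default_factory=lambda: dict(TRAIT_TRUTH_DEFAULTS))

    def nrr_expected(self, stage: str) -> float:
        """Non-return probability implied by the liability threshold."""
        from scipy.stats import norm

        return float(norm.cdf(norm.ppf(self.traits[("NRR", stage)].mu)))


# ---------------------------------------------------------------------------


def simulate_pedigree(truth: SimTruth, rng: np.random.Generator
                      ) -> tuple[Pedigree, pd.DataFrame]:
    """Discrete-generation pedigree with reused sires.

    Returns the sorted pedigree plus a frame (id, sex, generation) aligned
    to pedigree order.  Seed-reproducible: same truth + generator state
    gives an identical pedigree.
    """
    rows: list[tuple[str, str | None, str | None]] = []
    info: dict[str, tuple[str, int]] = {}
    males = [f"G0M{i:05d}" for i in range(truth.n_founder_sires)]
    females = [f"G0F{i:05d}" for i in range(truth.n_founder_dams)]
    for a in males:
        rows.append((a, None, None)); info[a] = ("M", 0)
    for a in females:
        rows.append((a, None, None)); info[a] = ("F", 0)
    for g in range(1, truth.n_generations + 1):
        k = min(truth.sires_per_generation, len(males))
        sires = list(rng.choice(males, size=k, replace=False))
        new_m, new_f = [], []
        for i in range(truth.n_per_generation):
            s = sires[int(rng.integers(len(sires)))]
            d = females[int(rng.integers(len(females)))]
            female = rng.random() < truth.prop_female
            a = f"G{g}{'F' if female else 'M'}{i:05d}"
            rows.append((a, s, d))
            info[a] = ("F" if female else "M", g)
            (new_f if female else new_m).append(a)
        males, females = new_m or males, new_f or females
    ped = Pedigree.from_triples(rows)
    meta = pd.DataFrame(
        {
            "id": ped.ids,
            "sex": [info[a][0] for a in ped.ids],
            "generation": [info[a][1] for a in ped.ids],
        }
    )
    return ped, meta


def random_pedigree(rng: np.random.Generator, n: int, n_founders: int = 10) -> Pedigree:
    """Unstructured random sex-consistent pedigree (for algebra checks).

    Unlike :func:`simulate_pedigree` there are no discrete generations:
    any earlier animal can be a parent, parents may be missing, and sexes
    are random — a stress shape for relationship-matrix code.
    """
    males: list[str] = []
    females: list[str] = []
    triples = []
    for i in range(n):
        name = f"A{i:04d}"
        if i < n_founders or (not males and not females):
            triples.append((name, None, None))
        else:
            s = males[int(rng.integers(len(males)))] if males and rng.random() < 0.9 else None
            d = females[int(rng.integers(len(females)))] if females and rng.random() < 0.9 else None
            triples.append((name, s, d))
        (males if rng.random() < 0.5 else females).append(name)
    return Pedigree.from_triples(triples)


def simulate_breeding_values(
    ped: Pedigree,
    sigma2_a: float | None = None,
    rng: np.random.Generator | None = None,
    G: np.ndarray | None = None,
) -> np.ndarray:
    """Additive values with covariance ``A sigma_a^2`` (or ``G (x) A``).

    Mendelian-sampling recursion: ``a_i = (a_s + a_d)/2 + m_i`` with
    ``Var(m_i) = d_i sigma_a^2`` and the pedigree's within-family
    coefficient ``d_i`` (1 for founders, 0.5 - 0.25(F_s + F_d) with both
    parents known).  Exact under A, linear time — no dense Cholesky.
    """
    if rng is None:
        raise ValueError("pass a numpy Generator")
    n = len(ped)
    d = ped.mendelian_d
    if G is not None:
        G = np.asarray(G, dtype=float)
        k = G.shape[0]
        L = np.linalg.cholesky(G + 1e-12 * np.eye(k) * max(G.diagonal().max(), 1.0))
        a = np.zeros((n, k))
        z = rng.standard_normal((n, k))
        for i in range(n):
            m = np.sqrt(d[i]) * (L @ z[i])
            parent = np.zeros(k)
            if ped.sire[i] >= 0:
                parent += 0.5 * a[ped.sire[i]]
            if ped.dam[i] >= 0:
                parent += 0.5 * a[ped.dam[i]]
            a[i] = parent + m
        return a
    if sigma2_a == 0.0:
        return np.zeros(n)
    sd = np.sqrt(sigma2_a * d)
    z = rng.standard_normal(n) * sd
    a = np.zeros(n)
    for i in range(n):
        val = z[i]
        if ped.sire[i] >= 0:
            val += 0.5 * a[ped.sire[i]]
        if ped.dam[i] >= 0:
            val += 0.5 * a[ped.dam[i]]
        a[i] = val
    return a


def _minimal_records(animal_ids: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"animal_id": animal_ids})


def simulate_trait_dataset(
    ped: Pedigree,
    truth: TraitTruth,
    rng: np.random.Generator,
    phenotyped: np.ndarray | None = None,
    n_herd_years: int = 200,
    n_fixed_levels: int = 12,
    fixed_sd_frac: float = 0.25,
    service_sires: list | None = None,
    round_y: bool = False,
    design_rng: np.random.Generator | None = None,
) -> tuple[TraitDataset, dict]:
    """Phenotypes straight from the linear model (for recovery studies).

    One record per phenotyped animal (default: all non-founders);
    herd-year and fixed ("RYM") classes assigned uniformly at random;
    service sires, when the trait has a sire variance, drawn from
    ``service_sires`` (default: founder-coded sires in the pedigree) with
    effects simulated with covariance ``A_ss sigma_ss^2`` through the full
    pedigree.
    """
    if phenotyped is None:
        phenotyped = np.array(
            [a for i, a in enumerate(ped.ids) if not ped.is_founder[i]], dtype=object
        )
    drng = design_rng or rng
    idx = ped.indices(phenotyped)
    n = len(idx)
    bv = simulate_breeding_values(ped, truth.sigma2_a, rng)
    y = truth.mu + bv[idx]
    fixed_labels = drng.integers(0, n_fixed_levels, size=n)
    fixed_eff = rng.normal(0.0, fixed_sd_frac * np.sqrt(truth.total), n_fixed_levels)
    y = y + fixed_eff[fixed_labels]
    comp = {"a": bv[idx]}
    hy_labels = None
    if truth.sigma2_hy is not None:
        hy_codes = drng.integers(0, n_herd_years, size=n)
        hy_eff = rng.normal(0.0, np.sqrt(truth.sigma2_hy), n_herd_years)
        y = y + hy_eff[hy_codes]
        hy_labels = np.array([f"HY{c:04d}" for c in hy_codes], dtype=object)
        comp["hy"] = hy_eff[hy_codes]
    ss_ids = None
    if truth.sigma2_ss is not None:
        if service_sires is None:
            service_sires = [a for a in ped.ids if "M" in a][:50] or list(ped.ids[:10])
        ss_bv = simulate_breeding_values(ped, truth.sigma2_ss, rng)
        ss_pick = drng.integers(0, len(service_sires), size=n)
        ss_ids = np.array([service_sires[i] for i in ss_pick], dtype=object)
        y = y + ss_bv[ped.indices(ss_ids)]
        comp["ss"] = ss_bv[ped.indices(ss_ids)]
    e = rng.normal(0.0, np.sqrt(truth.sigma2_e), n)
    y = y + e
    comp["e"] = e
    if round_y:
        y = np.round(y)
    ds = TraitDataset(
        trait=truth.trait,
        stage=truth.stage,
        animal_ids=np.asarray(phenotyped, dtype=object),
        y=np.asarray(y, dtype=float),
        records=_minimal_records(np.asarray(phenotyped, dtype=object)),
        fixed={"RYM": np.array([f"L{c:02d}" for c in fixed_labels], dtype=object)},
        hy_labels=hy_labels,
        ss_ids=ss_ids,
    )
    return ds, comp


def simulate_bivariate_dataset(
    ped: Pedigree,
    truth: BivariateTruth,
    rng: np.random.Generator,
    phenotyped: np.ndarray | None = None,
    both_frac: float = 1.0,
    n_herd_years: int = 150,
    n_fixed_levels: int = 8,
    service_sires: list | None = None,
    record_mask: tuple[np.ndarray, np.ndarray] | None = None,
    design_rng: np.random.Generator | None = None,
) -> tuple[TraitDataset, TraitDataset, dict]:
    """Heifer/cow record pair per animal under 2x2 covariance blocks.

    ``both_frac`` of the phenotyped animals carry records at both stages
    (residuals correlated per ``truth.R``); the remainder split evenly
    between heifer-only and cow-only.  Pass ``record_mask`` (heifer, cow
    boolean arrays over the phenotyped animals) to hold the record layout
    fixed across replicates.
    """
    if phenotyped is None:
        phenotyped = np.array(
            [a for i, a in enumerate(ped.ids) if not ped.is_founder[i]], dtype=object
        )
    drng = design_rng or rng
    idx = ped.indices(phenotyped)
    n = len(idx)
    bv = simulate_breeding_values(ped, rng=rng, G=truth.G)
    hy_codes = drng.integers(0, n_herd_years, size=n)
    hy_eff = rng.multivariate_normal([0, 0], truth.HY, size=n_herd_years)
    fixed_codes = drng.integers(0, n_fixed_levels, size=n)
    scale = np.sqrt(np.trace(truth.G + truth.HY + truth.R) / 2.0)
    fixed_eff = rng.normal(0.0, 0.25 * scale, (n_fixed_levels, 2))
    e = rng.multivariate_normal([0, 0], truth.R, size=n)
    y = np.array(truth.mu) + bv[idx] + hy_eff[hy_codes] + fixed_eff[fixed_codes] + e
    ss_ids = None
    if truth.SS is not None:
        if service_sires is None:
            service_sires = [a for a in ped.ids if "M" in a][:50] or list(ped.ids[:10])
        ss_bv = simulate_breeding_values(ped, rng=rng, G=truth.SS)
        ss_pick = drng.integers(0, len(service_sires), size=n)
        ss_ids = np.array([service_sires[i] for i in ss_pick], dtype=object)
        y = y + ss_bv[ped.indices(ss_ids)]

    if record_mask is not None:
        has1, has2 = record_mask
    else:
        u = drng.random(n)
        has1 = u < both_frac + (1 - both_frac) / 2
        has2 = (u < both_frac) | (u >= both_frac + (1 - both_frac) / 2)
    hy_labels = np.array([f"HY{c:04d}" for c in hy_codes], dtype=object)
    fx = np.array([f"L{c:02d}" for c in fixed_codes], dtype=object)

    def make(stage_i: int, mask: np.ndarray, stage: str) -> TraitDataset:
        ids = np.asarray(phenotyped, dtype=object)[mask]
        return TraitDataset(
            trait=truth.trait,
            stage=stage,
            animal_ids=ids,
            y=y[mask, stage_i],
            records=_minimal_records(ids),
            fixed={"RYM": fx[mask]},
            hy_labels=hy_labels[mask],
            ss_ids=None if ss_ids is None else ss_ids[mask],
        )

    ds1 = make(0, has1, "heifer")
    ds2 = make(1, has2, "cow")
    return ds1, ds2, {"a": bv, "both": has1 & has2}


# ---------------------------------------------------------------------------
# event-level simulation


@dataclass
class EventSim:
    """Simulated event records plus the generating interval values."""

    records: list[EventRecord]
    values: pd.DataFrame      # cow_id, parity, trait, value


def _draw_interval(t: TraitTruth, a: float, hy: float, ss: float,
                   rng: np.random.Generator, lo: float) -> int:
    y = t.mu + a + hy + ss + rng.normal(0.0, np.sqrt(t.sigma2_e))
    return int(max(round(y), lo))


def simulate_events(
    ped: Pedigree,
    meta: pd.DataFrame,
    truth: SimTruth,
    rng: np.random.Generator,
) -> EventSim:
    """Full event timelines for every non-founder female.

    Interval traits (AFS, CTFS, GL) are drawn from their linear models and
    the calving/insemination dates are placed so date arithmetic returns
    exactly those values; FSTC, CI, DO, AFC emerge as sums.  NS comes from
    a per-service conception draw (geometric-like, capped); the 56-day
    non-return outcome is decided on a standardized liability whose
    variance shares follow the trait's components, then made deterministic
    in the dates (an early return at 18-45 d, a late one at 57-90 d).
    Duplicate and corrupted-duplicate records are injected at the
    configured rates to exercise deduplication.
    """
    females = meta[(meta.sex == "F") & (meta.generation > 0)]
    sire_pool = list(meta[meta.sex == "M"].id)
    tt = truth.traits
    # per-trait breeding values through the pedigree
    bv = {
        key: simulate_breeding_values(ped, tt[key].sigma2_a, rng)
        for key in tt
        if key[0] in ("AFS", "CTFS", "GL")
    }
    ss_bv = {
        key: simulate_breeding_values(ped, tt[key].sigma2_ss, rng)
        for key in tt
        if key[0] == "GL"
    }
    # standardized NRR liability shares
    nrr_bv = {
        st: simulate_breeding_values(ped, 1.0, rng) for st in ("heifer", "cow")
    }
    nrr_ss = {st: simulate_breeding_values(ped, 1.0, rng) for st in ("heifer", "cow")}

    herd_of = {}
    hy_eff: dict[tuple, float] = {}

    def hy_effect(key, farm, year) -> float:
        t = tt[key]
        if t.sigma2_hy is None:
            return 0.0
        k = (key, farm, year)
        if k not in hy_eff:
            hy_eff[k] = rng.normal(0.0, np.sqrt(t.sigma2_hy))
        return hy_eff[k]

    from scipy.stats import norm

    records: list[EventRecord] = []
    values: list[tuple] = []

    for _, row in females.iterrows():
        cow = row.id
        i = ped.index(cow)
        farm = herd_of.setdefault(cow, f"H{int(rng.integers(truth.n_herds)):02d}")
        region = f"R{int(farm[1:]) % truth.n_regions}"
        birth = ORIGIN + timedelta(days=int(row.generation) * 420 + int(rng.integers(365)))
        byear = birth.year

        def episode(parity: int, open_date: date, first_insem: date,
                    afs_val: int | None):
            stage = "heifer" if parity == 0 else "cow"
            pcap = truth.conception_p[0 if stage == "heifer" else 1]
            cap = truth.ns_cap[0 if stage == "heifer" else 1]
            ns = 1
            while ns < cap and rng.random() > pcap:
                ns += 1
            # liability for the 56-day non-return outcome
            t_nrr = tt[("NRR", stage)]
            shares = np.array([
                t_nrr.sigma2_a, t_nrr.sigma2_hy or 0.0, t_nrr.sigma2_ss or 0.0,
                t_nrr.sigma2_e,
            ])
            w = np.sqrt(shares / shares.sum())
            ss_id = sire_pool[int(rng.integers(len(sire_pool)))]
            liab = (
                w[0] * nrr_bv[stage][i]
                + w[1] * rng.normal()
                + w[2] * nrr_ss[stage][ped.index(ss_id)]
                + w[3] * rng.normal()
            )
            no_return = liab < norm.ppf(t_nrr.mu)
            if not no_return:
                ns = max(ns, 2)
            gaps = []
            for j in range(ns - 1):
                if j == 0:
                    gaps.append(int(rng.integers(57, 91)) if no_return
                                else int(rng.integers(18, 46)))
                else:
                    gaps.append(int(rng.integers(18, 46)))
            insems = [first_insem]
            for g in gaps:
                insems.append(insems[-1] + timedelta(days=g))
            sires = [ss_id] + [
                sire_pool[int(rng.integers(len(sire_pool)))] for _ in gaps
            ]
            conception = insems[-1]
            key_gl = ("GL", stage)
            gl = _draw_interval(
                tt[key_gl], bv[key_gl][i], hy_effect(key_gl, farm, byear),
                ss_bv[key_gl][ped.index(sires[-1])], rng, 240,
            )
            calving = conception + timedelta(days=gl)
            calf_sex = "M" if rng.random() < 0.5 else "F"
            rec = EventRecord(
                cow_id=cow,
                parity=parity,
                birth_date=birth,
                previous_calving_date=None if parity == 0 else open_date,
                calving_date=calving,
                insemination_dates=tuple(insems),
                conception_date=conception,
                service_sire_ids=tuple(sires),
                calf_sex=calf_sex,
                farm_id=farm,
                region=region,
            )
            records.append(rec)
            values.append((cow, parity, "GL", gl))
            values.append((cow, parity, "NS", ns))
            values.append((cow, parity, "NRR", 1 if no_return else 0))
            if afs_val is not None:
                values.append((cow, parity, "AFS", afs_val))
            return calving

        key_afs = ("AFS", "heifer")
        afs = _draw_interval(
            tt[key_afs], bv[key_afs][i], hy_effect(key_afs, farm, byear), 0.0, rng, 300
        )
        calving = episode(0, birth, birth + timedelta(days=afs), afs)
        for parity in range(1, truth.n_parities + 1):
            key_ctfs = ("CTFS", "cow")
            ctfs = _draw_interval(
                tt[key_ctfs], bv[key_ctfs][i], hy_effect(key_ctfs, farm, byear),
                0.0, rng, 21,
            )
            values.append((cow, parity, "CTFS", ctfs))
            calving = episode(parity, calving, calving + timedelta(days=ctfs), None)

    # duplicate / corrupted-record injection
    clean = list(records)
    for r in clean:
        if truth.dup_rate and rng.random() < truth.dup_rate:
            records.append(r)
        if truth.corrupt_rate and rng.random() < truth.corrupt_rate:
            records.append(replace(r, birth_date=r.birth_date + timedelta(days=1000)))
    vals = pd.DataFrame(values, columns=["cow_id", "parity", "trait", "value"])
    return EventSim(records=records, values=vals)


def fixture_small(seed: int = 20240103) -> tuple[Pedigree, EventSim, SimTruth]:
    """Deterministic miniature pedigree + events (<= 50 animals)."""
    truth = SimTruth(
        n_founder_sires=4,
        n_founder_dams=12,
        n_generations=2,
        n_per_generation=16,
        sires_per_generation=3,
        n_herds=2,
        n_parities=1,
    )
    rng = np.random.default_rng(seed)
    ped, meta = simulate_pedigree(truth, rng)
    sim = simulate_events(ped, meta, truth, rng)
    return ped, sim, truth


def truth_to_yaml(truth: SimTruth, path) -> None:
    """Serialize the generating parameters for provenance."""
    import yaml
    from dataclasses import asdict

    payload = asdict(truth)
    payload["traits"] = {
        f"{t}/{s}": asdict(v) for (t, s), v in truth.traits.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
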