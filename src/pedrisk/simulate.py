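"""Synthetic national-registry population generator.

Emulates the statistical structure the downstream analysis assumes: a
multigenerational pedigree; per-person additive-genetic values for ten
psychiatric/substance-use disorder liabilities and for educational attainment
(EA), drawn from a multivariate normal with configurable genetic correlations
and transmitted as midparent mean plus Mendelian-segregation noise; disorder
affection by the liability-threshold rule; age-at-first-registration events
from age 17 truncated at censoring; male conscript mediators (IQ, resilience)
loading on the EA genetic factor; and co-residence years used by the
cohabitation adjustment.

The final simulated generation is the study cohort (birth years inside
``birth_year_range``); earlier generations exist as phenotyped relatives.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

MONTHS_AT_ENTRY = 17 * 12  # follow-up starts at the 17th birthday

DISORDER_CODES = ("MD", "AD", "OCD", "AN", "BN", "DUD", "AUD", "ADHD", "BD", "SZ")

# lifetime prevalence (proportion) of each disorder in the study cohort
DEFAULT_PREVALENCE = {
    "MD": 0.1766,
    "AD": 0.1975,
    "OCD": 0.0130,
    "AN": 0.0050,
    "BN": 0.0032,
    "DUD": 0.0562,
    "AUD": 0.0379,
    "ADHD": 0.0332,
    "BD": 0.0146,
    "SZ": 0.0020,
}

# genetic correlation between each disorder liability and the EA genetic factor
DEFAULT_GENETIC_CORR = {
    "MD": -0.10,
    "AD": -0.15,
    "OCD": 0.00,
    "AN": -0.03,
    "BN": 0.01,
    "DUD": -0.29,
    "AUD": -0.28,
    "ADHD": -0.27,
    "BD": -0.04,
    "SZ": -0.01,
}

# liability heritabilities: literature-range values (twin-study scale)
DEFAULT_HERITABILITY = {
    "MD": 0.35,
    "AD": 0.30,
    "OCD": 0.45,
    "AN": 0.50,
    "BN": 0.50,
    "DUD": 0.55,
    "AUD": 0.50,
    "ADHD": 0.70,
    "BD": 0.70,
    "SZ": 0.75,
}

# female:male lifetime prevalence ratios
DEFAULT_SEX_RATIO = {
    "MD": 1.8,
    "AD": 1.8,
    "OCD": 1.2,
    "AN": 8.0,
    "BN": 8.0,
    "DUD": 0.5,
    "AUD": 0.45,
    "ADHD": 0.5,
    "BD": 1.2,
    "SZ": 0.6,
}

# liability-scale moderation of disorder genetics by EA genetics (product term),
# emulating the qualitative interaction pattern: negative for externalizing and
# internalizing disorders, weakly positive for eating disorders
DEFAULT_INTERACTION = {
    "MD": -0.05,
    "AD": -0.05,
    "OCD": 0.0,
    "AN": 0.03,
    "BN": 0.03,
    "DUD": -0.10,
    "AUD": -0.10,
    "ADHD": -0.10,
    "BD": 0.0,
    "SZ": 0.0,
}

PERSONS_COLUMNS = [
    "id", "sex", "yob", "county",
    "death_month", "emig_month", "ea_z", "iq_z", "res_z",
]
PEDIGREE_COLUMNS = ["id", "father_id", "mother_id"]
EVENTS_COLUMNS = ["id", "disorder", "age_months"]
COHAB_COLUMNS = ["id_a", "id_b", "years"]


class SchemaError(ValueError):
    """A registry CSV does not match the documented column schema."""


@dataclass(frozen=True)
class DisorderSpec:
    """Generative parameters for one disorder."""

    code: str
    prevalence: float
    heritability: float
    sex_ratio: float = 1.0  # female:male prevalence ratio
    onset_mean_months: float = 120.0  # mean exponential waiting time from age 17
    interaction_gamma: float = 0.0  # liability product-term with the EA factor

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError(f"{self.code}: prevalence must be in (0,1)")
        if not 0 <= self.heritability < 1:
            raise ValueError(f"{self.code}: heritability must be in [0,1)")
        if self.sex_ratio <= 0:
            raise ValueError(f"{self.code}: sex_ratio must be positive")


@dataclass(frozen=True)
class GaeaSpec:
    """EA genetic factor: heritability and correlations with disorder liabilities."""

    h2_ea: float = 0.40
    genetic_corr: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENETIC_CORR)
    )


@dataclass(frozen=True)
class MediatorSpec:
    """Loadings of male conscript IQ and resilience on the EA genetic factor."""

    iq_loading: float = 0.50
    resilience_loading: float = 0.35


@dataclass(frozen=True)
class CensoringSpec:
    """Death/emigration hazards (per person-year) and administrative end."""

    death_hazard: float = 0.0005
    emig_hazard: float = 0.002
    admin_end_year: int = 2018


@dataclass(frozen=True)
class CohabModel:
    """Mean/SD of recorded co-residence years by relative degree.

    Only 1st-degree pairs are recorded in the cohabitation table; all other
    pairs default to ``other_mean`` years at scoring time, which the generator
    represents implicitly by omission (years 0).
    """

    first_degree_mean: float = 15.0
    first_degree_sd: float = 3.0
    other_mean: float = 0.5
    other_sd: float = 1.0


def default_disorders() -> list[DisorderSpec]:
    return [
        DisorderSpec(
            code=c,
            prevalence=DEFAULT_PREVALENCE[c],
            heritability=DEFAULT_HERITABILITY[c],
            sex_ratio=DEFAULT_SEX_RATIO[c],
            interaction_gamma=DEFAULT_INTERACTION[c],
        )
        for c in DISORDER_CODES
    ]


@dataclass
class SimulationConfig:
    n_founder_couples: int = 1000
    n_generations: int = 4
    birth_year_range: tuple[int, int] = (1973, 1995)
    disorders: list[DisorderSpec] = field(default_factory=default_disorders)
    gaea: GaeaSpec = field(default_factory=GaeaSpec)
    mediators: MediatorSpec = field(default_factory=MediatorSpec)
    censoring: CensoringSpec = field(default_factory=CensoringSpec)
    cohab: CohabModel = field(default_factory=CohabModel)
    mean_children: float = 2.4
    generation_gap_years: int = 28
    n_counties: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_generations < 3:
            raise ValueError("n_generations must be >= 3")
        if self.n_founder_couples < 1:
            raise ValueError("need at least one founder couple")
        codes = [d.code for d in self.disorders]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate disorder codes")

    def genetic_covariance(self) -> np.ndarray:
        """Additive-genetic covariance of (disorder liabilities..., EA), checked PSD."""
        codes = [d.code for d in self.disorders]
        k = len(codes) + 1
        h2 = np.array([d.heritability for d in self.disorders] + [self.gaea.h2_ea])
        r = np.zeros((k, k))
        np.fill_diagonal(r, 1.0)
        for idx, c in enumerate(codes):
            rg = self.gaea.genetic_corr.get(c, 0.0)
            if abs(rg) > 1:
                raise ValueError(
                    f"genetic correlation between {c} and EA is {rg}, outside [-1, 1]"
                )
            r[idx, -1] = r[-1, idx] = rg
        eig = np.linalg.eigvalsh(r)
        if eig.min() < -1e-10:
            worst = max(codes, key=lambda c: abs(self.gaea.genetic_corr.get(c, 0.0)))
            raise ValueError(
                "genetic correlation matrix is not positive semi-definite; "
                f"largest off-diagonal involves pair ({worst}, EA)"
            )
        s = np.sqrt(h2)
        return r * np.outer(s, s)


@dataclass
class RegistryBundle:
    """The four registry-style tables the pipeline consumes."""

    persons: pd.DataFrame
    pedigree: pd.DataFrame
    events: pd.DataFrame
    cohab: pd.DataFrame

    def validate(self) -> None:
        for name, df, cols in (
            ("persons", self.persons, PERSONS_COLUMNS),
            ("pedigree", self.pedigree, PEDIGREE_COLUMNS),
            ("events", self.events, EVENTS_COLUMNS),
            ("cohab", self.cohab, COHAB_COLUMNS),
        ):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise SchemaError(f"{name} table missing columns: {missing}")
        ids = set(self.persons["id"])
        ped = self.pedigree
        known_parents = ped[["father_id", "mother_id"]].stack().dropna()
        if not set(known_parents.astype(int)).issubset(ids):
            raise SchemaError("pedigree refers to parents absent from persons table")
        non_founder = ped["father_id"].notna() | ped["mother_id"].notna()
        both = ped["father_id"].notna() & ped["mother_id"].notna()
        if (non_founder & ~both).any():
            raise SchemaError("every non-founder must have both parents recorded")
        if not self.events.empty:
            if not set(self.events["id"]).issubset(ids):
                raise SchemaError("events refer to ids absent from persons table")
            if (self.events["age_months"] < MONTHS_AT_ENTRY).any():
                raise SchemaError("event before the age-17 start of follow-up")
            if self.events.duplicated(subset=["id", "disorder"]).any():
                raise SchemaError("duplicate (id, disorder) event")

    def cohort_mask(self, birth_year_range: tuple[int, int]) -> pd.Series:
        lo, hi = birth_year_range
        return (self.persons["yob"] >= lo) & (self.persons["yob"] <= hi)


def simulate_population(
    config: SimulationConfig, return_truth: bool = False
) -> RegistryBundle | tuple[RegistryBundle, pd.DataFrame]:
    """Simulate the registry bundle (and optionally the latent genetic truth).

    All randomness comes from one generator seeded with ``config.seed``; the
    same seed reproduces the bundle exactly.

    When ``return_truth`` is True, also returns a frame with each person's
    additive-genetic values (``g_<code>``, ``g_EA``) and total liabilities
    (``liab_<code>``), for estimator-validation use only — the truth is never
    part of the registry files.
    """
    rng = np.random.default_rng(config.seed)
    codes = [d.code for d in config.disorders]
    sigma_a = config.genetic_covariance()
    chol_a = np.linalg.cholesky(sigma_a + 1e-12 * np.eye(sigma_a.shape[0]))
    k = len(codes) + 1

    lo, hi = config.birth_year_range
    gap = config.generation_gap_years

    ids: list[np.ndarray] = []
    sexes: list[np.ndarray] = []
    yobs: list[np.ndarray] = []
    fathers: list[np.ndarray] = []
    mothers: list[np.ndarray] = []
    genetics: list[np.ndarray] = []
    founder_sets: list[frozenset[int] | None] = []  # per person, founder ancestors

    next_id = 0

    def draw_founders(n: int, yob_lo: int, yob_hi: int):
        nonlocal next_id
        pid = np.arange(next_id, next_id + n, dtype=np.int64)
        next_id += n
        sex = rng.integers(0, 2, size=n)  # 0 female, 1 male
        yob = rng.integers(yob_lo, yob_hi + 1, size=n)
        g = rng.standard_normal((n, k)) @ chol_a.T
        return pid, sex, yob, g

    # generation 0: founders
    n0 = 2 * config.n_founder_couples
    offset = (config.n_generations - 1) * gap
    pid, sex, yob, g = draw_founders(n0, lo - offset, hi - offset)
    sex[: config.n_founder_couples] = 1  # guarantee enough of each sex for pairing
    sex[config.n_founder_couples:] = 0
    ids.append(pid); sexes.append(sex); yobs.append(yob)
    fathers.append(np.full(n0, -1, dtype=np.int64))
    mothers.append(np.full(n0, -1, dtype=np.int64))
    genetics.append(g)
    founder_sets.extend(frozenset((int(i),)) for i in pid)

    prev_pid, prev_sex, prev_g = pid, sex, g
    prev_founder_sets = founder_sets[:]

    for gen in range(1, config.n_generations):
        # pair males and females of the previous generation, avoiding couples
        # that share any founder ancestor (keeps the pedigree outbred)
        males = np.flatnonzero(prev_sex == 1)
        females = np.flatnonzero(prev_sex == 0)
        rng.shuffle(males)
        rng.shuffle(females)
        n_pairs = min(len(males), len(females))
        males, females = males[:n_pairs], females[:n_pairs]
        ok = np.array(
            [
                prev_founder_sets[m].isdisjoint(prev_founder_sets[f])
                for m, f in zip(males, females)
            ]
        )
        for _ in range(8):  # reshuffle clashing partners among themselves
            if ok.all():
                break
            bad = np.flatnonzero(~ok)
            if len(bad) < 2:
                break
            perm = rng.permutation(bad)
            females[bad] = females[perm]
            ok[bad] = [
                prev_founder_sets[males[b]].isdisjoint(prev_founder_sets[females[b]])
                for b in bad
            ]
        males, females = males[ok], females[ok]

        n_children = rng.poisson(config.mean_children, size=len(males))
        fa = np.repeat(prev_pid[males], n_children)
        mo = np.repeat(prev_pid[females], n_children)
        couple_idx = np.repeat(np.arange(len(males)), n_children)
        n = len(fa)
        pid = np.arange(next_id, next_id + n, dtype=np.int64)
        next_id += n
        sex = rng.integers(0, 2, size=n)
        off = (config.n_generations - 1 - gen) * gap
        yob = rng.integers(lo - off, hi - off + 1, size=n)
        midparent = 0.5 * (prev_g[males][couple_idx] + prev_g[females][couple_idx])
        segregation = rng.standard_normal((n, k)) @ (chol_a.T / np.sqrt(2.0))
        g = midparent + segregation

        child_founders = [
            prev_founder_sets[m] | prev_founder_sets[f]
            for m, f in zip(males[couple_idx], females[couple_idx])
        ]
        ids.append(pid); sexes.append(sex); yobs.append(yob)
        fathers.append(fa); mothers.append(mo); genetics.append(g)
        founder_sets.extend(child_founders)
        prev_pid, prev_sex, prev_g = pid, sex, g
        prev_founder_sets = child_founders

    person_id = np.concatenate(ids)
    sex_all = np.concatenate(sexes)
    yob_all = np.concatenate(yobs)
    father_all = np.concatenate(fathers)
    mother_all = np.concatenate(mothers)
    g_all = np.vstack(genetics)
    n_total = len(person_id)

    # environmental deviations and total liabilities (with optional EA moderation)
    h2 = np.array([d.heritability for d in config.disorders])
    g_ea = g_all[:, -1]
    g_ea_std = g_ea / np.sqrt(config.gaea.h2_ea)
    liab = np.empty((n_total, len(codes)))
    for j, d in enumerate(config.disorders):
        gamma = d.interaction_gamma
        if d.heritability > 0:
            g_d_std = g_all[:, j] / np.sqrt(d.heritability)
        else:
            g_d_std = np.zeros(n_total)
        inter = gamma * g_d_std * g_ea_std
        rg = config.gaea.genetic_corr.get(d.code, 0.0)
        var_inter = gamma ** 2 * (1.0 + rg ** 2)
        env_var = max(1.0 - d.heritability - var_inter, 0.05)
        liab[:, j] = g_all[:, j] + inter + rng.standard_normal(n_total) * np.sqrt(env_var)

    # censoring: months from birth; admin end = December of admin_end_year
    admin_months = (config.censoring.admin_end_year - yob_all + 1) * 12.0
    death = rng.exponential(12.0 / max(config.censoring.death_hazard, 1e-12), n_total)
    emig = rng.exponential(12.0 / max(config.censoring.emig_hazard, 1e-12), n_total)
    death_month = np.where(death < admin_months, np.round(death, 1), np.nan)
    emig_month = np.where(emig < admin_months, np.round(emig, 1), np.nan)
    censor = np.nanmin(
        np.column_stack([death_month, emig_month, admin_months]), axis=1
    )

    # affection by sex-specific liability thresholds; onset truncated-exponential
    ev_ids, ev_dis, ev_age = [], [], []
    for j, d in enumerate(config.disorders):
        r = d.sex_ratio
        k_f = min(d.prevalence * 2 * r / (r + 1), 0.999)
        k_m = min(d.prevalence * 2 / (r + 1), 0.999)
        tau = np.where(sex_all == 1, stats.norm.isf(k_m), stats.norm.isf(k_f))
        affected = liab[:, j] > tau
        can_onset = affected & (censor > MONTHS_AT_ENTRY + 1)
        idx = np.flatnonzero(can_onset)
        if len(idx) == 0:
            continue
        span = censor[idx] - MONTHS_AT_ENTRY
        u = rng.random(len(idx))
        mean_w = d.onset_mean_months
        wait = -mean_w * np.log1p(-u * (1.0 - np.exp(-span / mean_w)))
        wait = np.minimum(wait, span - 1e-6)
        ev_ids.append(person_id[idx])
        ev_dis.append(np.full(len(idx), d.code, dtype=object))
        ev_age.append(np.round(MONTHS_AT_ENTRY + wait, 1))

    events = pd.DataFrame(
        {
            "id": np.concatenate(ev_ids) if ev_ids else np.array([], dtype=np.int64),
            "disorder": np.concatenate(ev_dis) if ev_dis else np.array([], dtype=object),
            "age_months": np.concatenate(ev_age) if ev_age else np.array([], dtype=float),
        }
    )

    # EA phenotype, standardized within birth year
    ea_raw = g_ea + rng.standard_normal(n_total) * np.sqrt(1.0 - config.gaea.h2_ea)
    ea_z = _zscore_by(ea_raw, yob_all)

    # male conscript mediators, cohort members only, standardized within birth year
    cohort = (yob_all >= lo) & (yob_all <= hi)
    iq_z = np.full(n_total, np.nan)
    res_z = np.full(n_total, np.nan)
    m_idx = np.flatnonzero(cohort & (sex_all == 1))
    if len(m_idx):
        lam_iq = config.mediators.iq_loading
        lam_res = config.mediators.resilience_loading
        iq_raw = lam_iq * g_ea_std[m_idx] + rng.standard_normal(len(m_idx)) * np.sqrt(
            max(1 - lam_iq ** 2, 0.05)
        )
        res_raw = lam_res * g_ea_std[m_idx] + rng.standard_normal(len(m_idx)) * np.sqrt(
            max(1 - lam_res ** 2, 0.05)
        )
        iq_z[m_idx] = _zscore_by(iq_raw, yob_all[m_idx])
        res_z[m_idx] = _zscore_by(res_raw, yob_all[m_idx])

    county = rng.integers(0, config.n_counties, size=n_total)

    persons = pd.DataFrame(
        {
            "id": person_id,
            "sex": np.where(sex_all == 1, "M", "F"),
            "yob": yob_all,
            "county": county,
            "death_month": death_month,
            "emig_month": emig_month,
            "ea_z": np.round(ea_z, 6),
            "iq_z": np.round(iq_z, 6),
            "res_z": np.round(res_z, 6),
        }
    )
    pedigree = pd.DataFrame(
        {
            "id": person_id,
            "father_id": np.where(father_all < 0, np.nan, father_all),
            "mother_id": np.where(mother_all < 0, np.nan, mother_all),
        }
    )

    cohab = _simulate_cohab(pedigree, config, rng)

    bundle = RegistryBundle(persons=persons, pedigree=pedigree, events=events, cohab=cohab)
    bundle.validate()
    if not return_truth:
        return bundle
    truth = pd.DataFrame({"id": person_id})
    for j, c in enumerate(codes):
        truth[f"g_{c}"] = g_all[:, j]
        truth[f"liab_{c}"] = liab[:, j]
    truth["g_EA"] = g_ea
    return bundle, truth


def _zscore_by(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    s = pd.Series(values)
    grouped = s.groupby(pd.Series(groups))
    mean = grouped.transform("mean")
    sd = grouped.transform("std").replace(0.0, np.nan)
    z = (s - mean) / sd
    return z.fillna(0.0).to_numpy()


def _simulate_cohab(
    pedigree: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Record co-residence years for 1st-degree pairs (parent–child and full sibs)."""
    ped = pedigree.dropna(subset=["father_id"])
    child = ped["id"].to_numpy(np.int64)
    fa = ped["father_id"].to_numpy(np.int64)
    mo = ped["mother_id"].to_numpy(np.int64)
    pairs_a = np.concatenate([child, child])
    pairs_b = np.concatenate([fa, mo])
    # full-sib pairs within each sibship
    sib = pd.DataFrame({"id": child, "fa": fa, "mo": mo}).sort_values(["fa", "mo", "id"])
    sib_pairs_a, sib_pairs_b = [], []
    for _, grp in sib.groupby(["fa", "mo"], sort=False):
        kids = grp["id"].to_numpy()
        if len(kids) > 1:
            ia, ib = np.triu_indices(len(kids), k=1)
            sib_pairs_a.append(kids[ia])
            sib_pairs_b.append(kids[ib])
    if sib_pairs_a:
        pairs_a = np.concatenate([pairs_a] + sib_pairs_a)
        pairs_b = np.concatenate([pairs_b] + sib_pairs_b)
    years = rng.normal(config.cohab.first_degree_mean, config.cohab.first_degree_sd, len(pairs_a))
    years = np.clip(years, 0.0, None)
    return pd.DataFrame({"id_a": pairs_a, "id_b": pairs_b, "years": np.round(years, 2)})


def write_bundle(bundle: RegistryBundle, directory: str | Path) -> dict[str, Path]:
    """Write the four registry CSVs; missing values as empty fields."""
    bundle.validate()
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("persons", bundle.persons),
        ("pedigree", bundle.pedigree),
        ("events", bundle.events),
        ("cohab", bundle.cohab),
    ):
        p = d / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.6g")
        paths[name] = p
    return paths


def read_bundle(directory: str | Path) -> RegistryBundle:
    """Read a bundle written by :func:`write_bundle`, checking the schema."""
    d = Path(directory)
    frames = {}
    dtypes = {
        "persons": {"id": np.int64, "sex": str, "yob": np.int64, "county": np.int64},
        "pedigree": {"id": np.int64},
        "events": {"id": np.int64, "disorder": str},
        "cohab": {"id_a": np.int64, "id_b": np.int64},
    }
    expected = {
        "persons": PERSONS_COLUMNS,
        "pedigree": PEDIGREE_COLUMNS,
        "events": EVENTS_COLUMNS,
        "cohab": COHAB_COLUMNS,
    }
    for name in ("persons", "pedigree", "events", "cohab"):
        p = d / f"{name}.csv"
        if not p.exists():
            raise SchemaError(f"missing registry file {p}")
        df = pd.read_csv(p)
        missing = [c for c in expected[name] if c not in df.columns]
        if missing:
            raise SchemaError(f"{name}.csv missing columns: {missing}")
        if not df.empty:
            df = df.astype({k: v for k, v in dtypes[name].items() if k in df.columns})
        else:
            df = pd.DataFrame({c: pd.Series(dtype=float) for c in expected[name]})
        frames[name] = df
    bundle = RegistryBundle(**frames)
    bundle.validate()
    return bundle


def founder_couples_for_cohort(target_cohort: int, config: SimulationConfig | None = None) -> int:
    """Founder-couple count whose expected final generation is ~``target_cohort``."""
    cfg = config or SimulationConfig()
    c = cfg.mean_children
    couples_growth = c / 2.0  # ~half the children form next-generation couples
    expected_per_founder_couple = c * couples_growth ** (cfg.n_generations - 2)
    return max(int(np.ceil(target_cohort / expected_per_founder_couple)), 1)


def config_to_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)
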