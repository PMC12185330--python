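"""Family genetic risk scores from relatives' phenotypes.

A proband's score for a disorder aggregates liability-threshold contributions
from their 1st–5th-degree relatives: an affected relative contributes the mean
liability of the affected tail of a standard normal, an unaffected relative
the mean of the unaffected portion. Contributions are weighted by relatedness
(2*phi), optionally residualized on co-residence years within degree class,
shrunk toward zero when the pedigree is uninformative, and finally
z-standardized within birth-year-by-county strata. The educational-attainment
analogue (GAEA) uses relatives' continuous EA z-scores in place of the
threshold contributions; higher GAEA means higher familial attainment.

The proband's own phenotype never enters their score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import MONTHS_AT_ENTRY, RegistryBundle

GAEA_TRAIT = "GAEA"


@dataclass(frozen=True)
class LiabilityModel:
    """Liability-threshold quantities for a disorder of lifetime prevalence K.

    threshold      tau = Phi^-1(1 - K)
    z_affected     mean liability above tau  = pdf(tau) / K
    z_unaffected   mean liability below tau  = -pdf(tau) / (1 - K)

    so that K * z_affected + (1 - K) * z_unaffected = 0.
    """

    prevalence: float

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError(f"prevalence must be in (0,1), got {self.prevalence}")

    @property
    def threshold(self) -> float:
        return float(stats.norm.isf(self.prevalence))

    @property
    def z_affected(self) -> float:
        return float(stats.norm.pdf(self.threshold) / self.prevalence)

    @property
    def z_unaffected(self) -> float:
        return float(-stats.norm.pdf(self.threshold) / (1.0 - self.prevalence))


@dataclass(frozen=True)
class ScoringConfig:
    """Tuning constants for score aggregation.

    shrinkage_lambda:
        lambda in the shrinkage factor s = W / (W + lambda), W the summed
        relatedness weights; 0 disables shrinkage.
    cohab_adjust:
        residualize relative contributions on co-residence years per degree
        class before aggregation.
    min_relatives_for_adjust:
        smallest degree-class size on which the cohabitation regression is fit.
    """

    shrinkage_lambda: float = 1.0
    cohab_adjust: bool = True
    min_relatives_for_adjust: int = 10

    def __post_init__(self) -> None:
        if not np.isfinite(self.shrinkage_lambda) or self.shrinkage_lambda < 0:
            raise ValueError("shrinkage_lambda must be finite and >= 0")


def relative_contribution(model: LiabilityModel, affected: bool) -> float:
    """Liability contribution of one relative: the truncated-normal tail mean."""
    return model.z_affected if affected else model.z_unaffected


def prevalence_by_year(
    bundle: RegistryBundle, disorder: str, min_cases: int = 10
) -> pd.Series:
    """Per-birth-year prevalence of ``disorder``, pooled to the overall rate
    for years contributing fewer than ``min_cases`` cases."""
    persons = bundle.persons
    cases = bundle.events.loc[bundle.events["disorder"] == disorder, "id"].unique()
    is_case = persons["id"].isin(cases)
    by_year = persons.assign(case=is_case).groupby("yob")["case"].agg(["sum", "size"])
    overall = max(is_case.sum(), 1) / len(persons)
    prev = by_year["sum"] / by_year["size"]
    prev[by_year["sum"] < min_cases] = overall
    return prev.clip(1e-6, 1 - 1e-6)


def cohabitation_adjust(
    contributions: pd.DataFrame, min_n: int = 10
) -> pd.DataFrame:
    """Residualize contributions on co-residence years within each degree class.

    ``contributions`` needs columns ``z`` (relative contribution), ``degree``
    and ``cohab_years``. Within each degree class with at least ``min_n`` rows
    and non-degenerate cohab variance, ``z`` is replaced by the least-squares
    residual re-centred at the class mean (so the class-level mean contribution
    is preserved); degenerate classes pass through unchanged.
    """
    out = contributions.copy()
    out["z"] = _adjust_arrays(
        out["z"].to_numpy(float),
        out["degree"].to_numpy(),
        out["cohab_years"].to_numpy(float),
        min_n,
    )
    return out


def _adjust_arrays(
    z: np.ndarray, degree: np.ndarray, cohab_years: np.ndarray, min_n: int
) -> np.ndarray:
    z = z.copy()
    for d in np.unique(degree):
        mask = degree == d
        if mask.sum() < min_n:
            continue
        x = cohab_years[mask]
        vx = np.var(x)
        if vx <= 1e-12:
            continue
        y = z[mask]
        slope = np.cov(x, y, bias=True)[0, 1] / vx
        z[mask] = y - slope * (x - x.mean())
    return z


def fit_cohab_slope(contributions: pd.DataFrame, degree: int) -> float:
    """OLS slope of contribution on cohab years within one degree class."""
    sub = contributions[contributions["degree"] == degree]
    x = sub["cohab_years"].to_numpy(float)
    y = sub["z"].to_numpy(float)
    if np.var(x) <= 1e-12:
        return 0.0
    return float(np.cov(x, y, bias=True)[0, 1] / np.var(x))


def compute_fgrs(
    bundle: RegistryBundle,
    links: pd.DataFrame,
    trait: str,
    model: LiabilityModel | None = None,
    config: ScoringConfig | None = None,
    probands: np.ndarray | None = None,
) -> pd.DataFrame:
    """Compute standardized genetic scores for a trait.

    Parameters
    ----------
    bundle:
        Registry bundle supplying relative phenotypes and proband strata.
    links:
        Proband–relative table with columns proband, relative, phi, degree and
        (optionally) cohab_years.
    trait:
        A disorder code, or ``"GAEA"`` for the educational-attainment score.
    model:
        Liability model for a disorder trait. When None, prevalence is
        estimated per relative birth-year stratum from the bundle itself
        (strata with fewer than 10 cases pooled to the overall rate).
    probands:
        Ids to score; defaults to every distinct proband in ``links``. Probands
        without a single phenotyped relative get raw score 0.

    Returns
    -------
    DataFrame with columns id, trait, raw, z, weight_sum.
    """
    if bundle.persons.empty:
        raise ValueError("empty cohort: persons table has no rows")
    cfg = config or ScoringConfig()
    persons = bundle.persons
    pid_index = pd.Index(persons["id"])

    rel_pos = pid_index.get_indexer(links["relative"])  # -1 = unknown relative
    known = rel_pos >= 0
    if trait == GAEA_TRAIT:
        pheno = persons["ea_z"].to_numpy(float)
        z = np.where(known, pheno[np.clip(rel_pos, 0, None)], np.nan)
    else:
        case_ids = bundle.events.loc[bundle.events["disorder"] == trait, "id"].unique()
        is_case = np.zeros(len(persons), dtype=bool)
        is_case[pid_index.get_indexer(case_ids)] = True
        affected = np.where(known, is_case[np.clip(rel_pos, 0, None)], False)
        if model is not None:
            z = np.where(affected, model.z_affected, model.z_unaffected)
        else:
            prev = prevalence_by_year(bundle, trait)
            yob = persons["yob"].to_numpy()[np.clip(rel_pos, 0, None)]
            k = prev.reindex(yob).fillna(prev.mean()).to_numpy(float)
            tau = stats.norm.isf(k)
            pdf = stats.norm.pdf(tau)
            z = np.where(affected, pdf / k, -pdf / (1.0 - k))
        z = np.where(known, z, np.nan)  # unknown-status relatives drop out

    valid = np.isfinite(z)
    z = z[valid]
    phi = links["phi"].to_numpy(float)[valid]
    degree = links["degree"].to_numpy()[valid]
    cohab = (
        links["cohab_years"].to_numpy(float)[valid]
        if "cohab_years" in links.columns
        else np.zeros(len(z))
    )
    proband = links["proband"].to_numpy(np.int64)[valid]

    if cfg.cohab_adjust and len(z):
        z = _adjust_arrays(z, degree, cohab, cfg.min_relatives_for_adjust)

    w = 2.0 * phi
    codes, uniq = pd.factorize(proband, sort=True)
    w_sum_u = np.bincount(codes, weights=w, minlength=len(uniq))
    wz_sum_u = np.bincount(codes, weights=w * z, minlength=len(uniq))

    if probands is None:
        index = pd.Index(uniq, name="proband")
        w_sum = pd.Series(w_sum_u, index=index)
        wz_sum = pd.Series(wz_sum_u, index=index)
    else:
        index = pd.Index(np.asarray(probands, dtype=np.int64), name="proband")
        if len(uniq) == 0:
            w_sum = pd.Series(0.0, index=index)
            wz_sum = pd.Series(0.0, index=index)
        else:
            pos = pd.Index(uniq).get_indexer(index)
            w_sum = pd.Series(np.where(pos >= 0, w_sum_u[np.clip(pos, 0, None)], 0.0), index=index)
            wz_sum = pd.Series(np.where(pos >= 0, wz_sum_u[np.clip(pos, 0, None)], 0.0), index=index)
    lam = cfg.shrinkage_lambda
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_contrib = np.where(w_sum > 0, wz_sum / w_sum, 0.0)
    shrink = np.where(w_sum > 0, w_sum / (w_sum + lam), 0.0) if lam > 0 else (w_sum > 0).astype(float)
    raw = mean_contrib * shrink

    scores = pd.DataFrame({"id": index.to_numpy(), "trait": trait, "raw": raw})
    scores["weight_sum"] = w_sum.to_numpy()
    persons = persons.set_index("id")
    strata = persons.loc[scores["id"], ["yob", "county"]].reset_index(drop=True)
    scores["z"] = standardize_within_strata(
        scores["raw"].to_numpy(), strata["yob"].to_numpy(), strata["county"].to_numpy()
    )
    return scores[["id", "trait", "raw", "z", "weight_sum"]]


def standardize_within_strata(
    values: np.ndarray, *strata: np.ndarray
) -> np.ndarray:
    """Z-standardize within the cross-classification of the given strata.

    Singleton or zero-variance strata get score 0 (with a warning for
    singletons), matching the registry convention that a score carries no
    information when its stratum cannot define a scale.
    """
    df = pd.DataFrame({"v": values})
    key = pd.Series(list(zip(*strata))) if strata else pd.Series(0, index=df.index)
    grouped = df["v"].groupby(key)
    mean = grouped.transform("mean")
    sd = grouped.transform("std")  # ddof=1; NaN for singletons
    n = grouped.transform("size")
    if (n == 1).any():
        warnings.warn(
            f"{int((n == 1).sum())} singleton strata; scores set to 0",
            stacklevel=2,
        )
    z = (df["v"] - mean) / sd.replace(0.0, np.nan)
    return z.fillna(0.0).to_numpy()


def compute_all_scores(
    bundle: RegistryBundle,
    links: pd.DataFrame,
    disorders: list[str],
    config: ScoringConfig | None = None,
    probands: np.ndarray | None = None,
) -> pd.DataFrame:
    """Scores for every disorder plus GAEA, one wide frame indexed by id.

    Columns are ``FGRS_<code>`` and ``GAEA`` (standardized z-scores).
    """
    frames = {}
    for code in disorders:
        s = compute_fgrs(bundle, links, code, config=config, probands=probands)
        frames[f"FGRS_{code}"] = s.set_index("id")["z"]
    s = compute_fgrs(bundle, links, GAEA_TRAIT, config=config, probands=probands)
    frames[GAEA_TRAIT] = s.set_index("id")["z"]
    return pd.DataFrame(frames)
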