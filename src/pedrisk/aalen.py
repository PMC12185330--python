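"""Aalen's linear (additive) hazards model with a score-by-score interaction.

The hazard is modelled as lambda(t | x) = beta_0(t) + sum_j beta_j(t) x_j and
estimated through the cumulative coefficients B_j(t) = int_0^t beta_j(s) ds.
At each event time t_k the increment is the least-squares solution

    dB(t_k) = (X_k' X_k)^{-1} X_k' e_k

with X_k the covariate matrix of the risk set at t_k and e_k the indicator of
the subjects whose event occurs at t_k (tied events are handled jointly in one
increment). With no covariates this reduces exactly to the Nelson–Aalen
cumulative-hazard estimator.

Time is measured in months since the 17th birthday; effect summaries are the
cumulative coefficients at T* = 408 months (34 years, the reference mean
follow-up), scaled by 100 to read as percentage-unit increases in cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import MONTHS_AT_ENTRY, RegistryBundle

logger = logging.getLogger(__name__)

T_STAR_MONTHS = 408.0  # 34 years of follow-up
MODEL_COVARIATES = {
    "A1": ("yob_c", "sex", "FGRS"),
    "A2": ("yob_c", "sex", "GAEA"),
    "B": ("yob_c", "sex", "FGRS", "GAEA"),
    "C": ("yob_c", "sex", "FGRS", "GAEA", "FGRSxGAEA"),
}
_COND_MAX = 1e10


@dataclass
class SurvivalDesign:
    """Follow-up data and covariates for one disorder/model combination."""

    time: np.ndarray  # months since age 17 at exit
    event: np.ndarray  # 1 if exit is the first registration of the disorder
    X: np.ndarray  # n x p covariate matrix, first column the intercept
    columns: list[str]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if np.any(self.time <= 0):
            raise ValueError("exit must be after entry; drop zero-length follow-up")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("covariates must be finite")


@dataclass
class AalenFit:
    """Cumulative coefficient paths B_j at the ordered event times."""

    times: np.ndarray  # m ordered distinct event times
    B: np.ndarray  # m x p cumulative coefficients
    increments: np.ndarray  # m x p
    n_at_risk: np.ndarray  # m
    n_events: np.ndarray  # m
    columns: list[str]
    n_skipped: int = 0  # event times with rank-deficient risk sets (pinv increments)

    def cumulative_at(self, t: float) -> np.ndarray:
        """B at the last event time <= t (B(0) = 0 before the first event)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return np.zeros(self.B.shape[1])
        return self.B[idx]


@dataclass
class RiskSummary:
    """Per-covariate 100 * B_j(T*) with a bootstrap confidence interval."""

    columns: list[str]
    estimate: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    t_star: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.columns,
                "estimate": self.estimate,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def build_design(
    bundle: RegistryBundle,
    scores: pd.DataFrame,
    disorder: str,
    model: str = "C",
    sex_filter: str | None = None,
    cohort_years: tuple[int, int] | None = None,
) -> SurvivalDesign:
    """Assemble the survival design for one disorder and model.

    ``scores`` is the wide frame from :func:`pedrisk.scoring.compute_all_scores`
    (columns ``FGRS_<code>`` and ``GAEA``, indexed by person id); only persons
    present in it enter the design. Follow-up runs from age 17 (month 0) to
    first registration of ``disorder``, death, emigration or the administrative
    end implied by the recorded censoring columns. Subjects with missing scores
    or no positive follow-up are dropped (counted in ``n_dropped``).
    """
    if model not in MODEL_COVARIATES:
        raise ValueError(f"unknown model {model!r}; expected one of {sorted(MODEL_COVARIATES)}")
    persons = bundle.persons
    if sex_filter in ("F", "M"):
        persons = persons[persons["sex"] == sex_filter]
    elif sex_filter not in (None, "all"):
        raise ValueError("sex_filter must be None, 'all', 'F' or 'M'")
    if cohort_years is not None:
        persons = persons[(persons["yob"] >= cohort_years[0]) & (persons["yob"] <= cohort_years[1])]
    persons = persons[persons["id"].isin(scores.index)]
    n_request = len(persons)

    ev = bundle.events
    ev = ev[ev["disorder"] == disorder].set_index("id")["age_months"]
    admin_months = (2018 - persons["yob"].to_numpy() + 1) * 12.0
    death = persons["death_month"].to_numpy(float)
    emig = persons["emig_month"].to_numpy(float)
    censor = np.nanmin(np.column_stack([death, emig, admin_months]), axis=1)
    event_age = persons["id"].map(ev).to_numpy(float)
    has_event = np.isfinite(event_age) & (event_age <= censor)
    exit_age = np.where(has_event, event_age, censor)
    time = exit_age - MONTHS_AT_ENTRY

    fgrs = persons["id"].map(scores[f"FGRS_{disorder}"]).to_numpy(float)
    gaea = persons["id"].map(scores["GAEA"]).to_numpy(float)
    yob_c = persons["yob"].to_numpy(float)
    yob_c = yob_c - yob_c.mean() if len(yob_c) else yob_c
    sex = (persons["sex"] == "M").to_numpy(float)

    cols = {"yob_c": yob_c, "sex": sex, "FGRS": fgrs, "GAEA": gaea, "FGRSxGAEA": fgrs * gaea}
    names = ["intercept"] + list(MODEL_COVARIATES[model])
    X = np.column_stack([np.ones(len(persons))] + [cols[c] for c in MODEL_COVARIATES[model]])

    keep = (time > 0) & np.all(np.isfinite(X), axis=1)
    n_dropped = int(n_request - keep.sum())
    if n_dropped:
        logger.info("build_design(%s, %s): dropped %d subjects", disorder, model, n_dropped)
    return SurvivalDesign(
        time=time[keep],
        event=has_event[keep].astype(np.int8),
        X=X[keep],
        columns=names,
        n_dropped=n_dropped,
    )


def fit_aalen(design: SurvivalDesign) -> AalenFit:
    """Least-squares increment fit of the additive hazards model.

    All subjects enter at time 0, so the risk set at an event time t is
    everyone with exit time >= t; the Gram matrix is accumulated by scanning
    exit times in decreasing order, giving an O(n p^2 + m p^3) fit.
    """
    t = np.asarray(design.time, float)
    d = np.asarray(design.event, int)
    X = np.asarray(design.X, float)
    if d.sum() == 0:
        raise ValueError("no events in the design; cannot fit")
    n, p = X.shape

    order = np.argsort(-t, kind="stable")
    t_s, d_s, X_s = t[order], d[order], X[order]
    # group boundaries of distinct exit times (descending)
    change = np.flatnonzero(np.diff(t_s) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])

    outer = np.einsum("ij,ik->ijk", X_s, X_s)
    grp_gram = np.add.reduceat(outer, starts, axis=0)  # per distinct time
    gram = np.cumsum(grp_gram, axis=0)  # risk-set Gram at each distinct time
    dX = X_s * d_s[:, None]
    grp_ev = np.add.reduceat(dX, starts, axis=0)
    grp_nev = np.add.reduceat(d_s.astype(float), starts)
    counts = ends - starts
    n_at_risk = np.cumsum(counts)

    has_event = grp_nev > 0
    G = gram[has_event]
    E = grp_ev[has_event]
    ev_times = t_s[starts][has_event]
    ev_risk = n_at_risk[has_event]
    ev_count = grp_nev[has_event]

    m = G.shape[0]
    inc = np.zeros((m, p))
    with np.errstate(all="ignore"):
        cond = np.linalg.cond(G)
    ok = np.isfinite(cond) & (cond < _COND_MAX)
    n_skipped = int(m - ok.sum())
    if n_skipped == m:
        raise np.linalg.LinAlgError("risk-set design rank-deficient at every event time")
    if ok.any():
        inc[ok] = np.linalg.solve(G[ok], E[ok][..., None])[..., 0]
    if n_skipped:
        # rank-deficient risk sets (e.g. a covariate constant among those still
        # at risk): minimum-norm least squares keeps the identifiable part of
        # the increment, so covariate-free sub-models reduce to Nelson-Aalen
        for i in np.flatnonzero(~ok):
            inc[i] = np.linalg.pinv(G[i], rcond=1e-10) @ E[i]
        logger.info(
            "fit_aalen: %d rank-deficient event times solved by pseudoinverse",
            n_skipped,
        )

    # re-order ascending in time
    rev = slice(None, None, -1)
    times = ev_times[rev]
    inc = inc[rev]
    B = np.cumsum(inc, axis=0)
    return AalenFit(
        times=times,
        B=B,
        increments=inc,
        n_at_risk=ev_risk[rev],
        n_events=ev_count[rev].astype(int),
        columns=list(design.columns),
        n_skipped=n_skipped,
    )


def summarize_34y(
    design: SurvivalDesign,
    fit: AalenFit | None = None,
    t_star: float = T_STAR_MONTHS,
    n_boot: int = 200,
    seed: int = 0,
    ci_level: float = 0.95,
) -> RiskSummary:
    """100 * B_j at the last event time <= ``t_star`` with a subject bootstrap CI."""
    if fit is None:
        fit = fit_aalen(design)
    if fit.times[0] > t_star:
        raise ValueError(f"no event before {t_star} months; summary undefined")
    est = 100.0 * fit.cumulative_at(t_star)
    rng = np.random.default_rng(seed)
    n = len(design.time)
    boots = np.empty((n_boot, len(est)))
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        bd = SurvivalDesign(
            time=design.time[idx],
            event=design.event[idx],
            X=design.X[idx],
            columns=design.columns,
        )
        try:
            bf = fit_aalen(bd)
            boots[b] = 100.0 * bf.cumulative_at(t_star)
        except (ValueError, np.linalg.LinAlgError):
            boots[b] = np.nan
    alpha = 1.0 - ci_level
    lo = np.nanpercentile(boots, 100 * alpha / 2, axis=0)
    hi = np.nanpercentile(boots, 100 * (1 - alpha / 2), axis=0)
    lo = np.minimum(lo, est)
    hi = np.maximum(hi, est)
    return RiskSummary(
        columns=list(fit.columns), estimate=est, ci_low=lo, ci_high=hi, t_star=t_star
    )


def prediction_grid(
    fit: AalenFit,
    fgrs_grid: np.ndarray | None = None,
    gaea_levels: np.ndarray | None = None,
    t_star: float = T_STAR_MONTHS,
    sex_ref: float = 0.5,
    yob_ref: float = 0.0,
) -> pd.DataFrame:
    """Predicted 34-year rates over an FGRS grid at fixed GAEA levels.

    Each prediction is x' B(T*) with sex and (centred) birth year held at
    reference values, clamped to [0, 1] since a linear hazard model can stray
    outside the probability scale.
    """
    if fgrs_grid is None:
        fgrs_grid = np.arange(-3.0, 3.0 + 1e-9, 0.25)
    if gaea_levels is None:
        gaea_levels = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    B = fit.cumulative_at(t_star)
    pos = {c: i for i, c in enumerate(fit.columns)}
    rows = []
    n_clamped = 0
    for g in gaea_levels:
        for f in fgrs_grid:
            x = np.zeros(len(fit.columns))
            x[pos["intercept"]] = 1.0
            if "yob_c" in pos:
                x[pos["yob_c"]] = yob_ref
            if "sex" in pos:
                x[pos["sex"]] = sex_ref
            if "FGRS" in pos:
                x[pos["FGRS"]] = f
            if "GAEA" in pos:
                x[pos["GAEA"]] = g
            if "FGRSxGAEA" in pos:
                x[pos["FGRSxGAEA"]] = f * g
            rate = float(x @ B)
            clamped = min(max(rate, 0.0), 1.0)
            if clamped != rate:
                n_clamped += 1
            rows.append({"gaea_level": g, "fgrs": f, "predicted_rate": clamped})
    if n_clamped:
        logger.info("prediction_grid: clamped %d grid points to [0, 1]", n_clamped)
    return pd.DataFrame(rows)


def nelson_aalen(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nelson–Aalen cumulative hazard (distinct event times, H(t))."""
    t = np.asarray(time, float)
    d = np.asarray(event, int)
    ev_times = np.unique(t[d == 1])
    H = np.empty(len(ev_times))
    acc = 0.0
    for i, s in enumerate(ev_times):
        at_risk = np.sum(t >= s)
        acc += np.sum(d[t == s]) / at_risk
        H[i] = acc
    return ev_times, H
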