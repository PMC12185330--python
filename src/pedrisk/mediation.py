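"""Three-path mediation of the GAEA effect on disorder risk (males only).

The path model has one exogenous predictor g (the GAEA score), two mediators
m1 (IQ) and m2 (resilience), and a binary outcome y (first registration at or
after age 19; earlier cases are excluded):

    m1 = a1 g + e1            (least squares)
    m2 = a2 g + e2            (least squares)
    y* = c' g + b1 m1 + b2 m2 + e,   y = 1{y* > tau}   (probit)

All predictors are z-standardized on the analysis sample, and the outcome
coefficients are expressed on the standardized latent-response scale by
dividing by the model-implied SD of y* (sqrt of the linear predictor variance
plus the unit probit residual). The decomposition is the product of
coefficients: indirect via IQ = a1*b1, via resilience = a2*b2, and the total
effect is direct + indirect exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

AGE19_MONTHS = 19 * 12


@dataclass
class MediationInput:
    """Standardized per-subject arrays for the path model."""

    g: np.ndarray
    m_iq: np.ndarray
    m_res: np.ndarray
    y: np.ndarray

    @classmethod
    def from_arrays(
        cls,
        g: np.ndarray,
        m_iq: np.ndarray,
        m_res: np.ndarray,
        y: np.ndarray,
        standardize: bool = True,
    ) -> "MediationInput":
        g, m1, m2 = (np.asarray(v, float) for v in (g, m_iq, m_res))
        y = np.asarray(y, int)
        ok = np.isfinite(g) & np.isfinite(m1) & np.isfinite(m2)
        g, m1, m2, y = g[ok], m1[ok], m2[ok], y[ok]
        if standardize:
            g, m1, m2 = (_z(v) for v in (g, m1, m2))
        return cls(g=g, m_iq=m1, m_res=m2, y=y)

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class MediationDecomposition:
    """Standardized effects and the proportion-mediated summaries."""

    total: float
    direct: float
    indirect_iq: float
    indirect_res: float

    @property
    def indirect(self) -> float:
        return self.indirect_iq + self.indirect_res

    @property
    def prop_mediated_pct(self) -> float:
        """Total proportion mediated: indirect / total, as a percentage."""
        return 100.0 * self.indirect / self.total

    @property
    def prop_via_iq_pct(self) -> float:
        """Share of the indirect effect through IQ, as a percentage."""
        if self.indirect == 0:
            return float("nan")
        return 100.0 * self.indirect_iq / self.indirect

    @property
    def prop_via_res_pct(self) -> float:
        if self.indirect == 0:
            return float("nan")
        return 100.0 * self.indirect_res / self.indirect


def _z(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("zero-variance predictor cannot be standardized")
    return (v - v.mean()) / sd


def _paths(inp: MediationInput) -> tuple[float, float, float, float]:
    """Raw path coefficients (a1, a2, c'_std, b1_std, b2_std collapsed).

    Returns (a1*b1_std, a2*b2_std, c'_std, sd_star) pieces via a single tuple:
    (c_std, a1b1, a2b2, sd_star).
    """
    g, m1, m2, y = inp.g, inp.m_iq, inp.m_res, inp.y
    a1 = float(np.dot(g, m1) / np.dot(g, g))
    a2 = float(np.dot(g, m2) / np.dot(g, g))
    X = sm.add_constant(np.column_stack([g, m1, m2]))
    model = sm.Probit(y, X)
    res = model.fit(disp=0, maxiter=100)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(f"probit did not converge: {res.mle_retvals}")
    _, c_raw, b1_raw, b2_raw = res.params
    eta = X[:, 1:] @ np.array([c_raw, b1_raw, b2_raw])
    sd_star = float(np.sqrt(eta.var() + 1.0))
    c_std = c_raw / sd_star
    b1_std = b1_raw / sd_star
    b2_std = b2_raw / sd_star
    return c_std, a1 * b1_std, a2 * b2_std, sd_star


def fit_paths(inp: MediationInput, min_n: int = 500, min_cases: int = 20) -> MediationDecomposition:
    """Fit the three-path model and assemble the effect decomposition."""
    if inp.n < min_n:
        raise ValueError(f"need at least {min_n} subjects, got {inp.n}")
    n_cases = int(inp.y.sum())
    if n_cases < min_cases or n_cases > inp.n - 1:
        raise ValueError(
            f"outcome needs >= {min_cases} cases and at least one non-case "
            f"(got {n_cases}/{inp.n})"
        )
    c_std, a1b1, a2b2, _ = _paths(inp)
    return MediationDecomposition(
        total=c_std + a1b1 + a2b2,
        direct=c_std,
        indirect_iq=a1b1,
        indirect_res=a2b2,
    )


def decomposition_from_effects(
    total: float, direct: float, indirect_iq: float, indirect_res: float
) -> MediationDecomposition:
    """Decomposition from externally reported effects (reporting arithmetic only).

    ``total`` is retained as given; proportions use the reported indirect
    components, mirroring how reported effect tables are summarised.
    """
    d = MediationDecomposition(
        total=total, direct=direct, indirect_iq=indirect_iq, indirect_res=indirect_res
    )
    return d


def proportion_table(decompositions: dict[str, MediationDecomposition]) -> pd.DataFrame:
    """Mediation summary, one disorder per row, percentages to one decimal.

    When the indirect effect is exactly 0 the via-IQ/via-resilience split is
    undefined and reported blank with a note.
    """
    rows = []
    for code, d in decompositions.items():
        undef = d.indirect == 0
        rows.append(
            {
                "disorder": code,
                "total": d.total,
                "direct": d.direct,
                "indirect": d.indirect,
                "indirect_iq": d.indirect_iq,
                "indirect_res": d.indirect_res,
                "prop_mediated_pct": round(d.prop_mediated_pct, 1) if d.total != 0 else np.nan,
                "prop_via_iq_pct": np.nan if undef else round(d.prop_via_iq_pct, 1),
                "prop_via_res_pct": np.nan if undef else round(d.prop_via_res_pct, 1),
                "note": "indirect effect 0; via-mediator split undefined" if undef else "",
            }
        )
    return pd.DataFrame(rows)


def iq_vs_resilience_test(
    inp: MediationInput, n_boot: int = 1000, seed: int = 0
) -> float:
    """Two-sided percentile-bootstrap p for a1*b1 = a2*b2 (IQ vs resilience).

    Resamples subjects, refits the full path model, and evaluates the sign
    distribution of delta = indirect_via_IQ - indirect_via_resilience.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for a stable percentile p-value")
    rng = np.random.default_rng(seed)
    n = inp.n
    deltas = np.empty(n_boot)
    start = None
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        bi = MediationInput.from_arrays(
            inp.g[idx], inp.m_iq[idx], inp.m_res[idx], inp.y[idx]
        )
        try:
            _, a1b1, a2b2, _ = _paths(bi)
            deltas[b] = a1b1 - a2b2
        except Exception:
            deltas[b] = np.nan
    deltas = deltas[np.isfinite(deltas)]
    if len(deltas) < 100:
        raise RuntimeError("too many failed bootstrap refits")
    p_pos = np.mean(deltas > 0)
    p_neg = np.mean(deltas < 0)
    p = 2.0 * min(p_pos, p_neg)
    return float(min(max(p, 0.0), 1.0))


def mediation_input_from_bundle(
    bundle, scores: pd.DataFrame, disorder: str
) -> MediationInput:
    """Males with conscript mediators; outcome = first registration at/after 19.

    Subjects registered for the disorder before age 19 are excluded, matching
    the design in which mediators are measured at conscription (~18).
    """
    persons = bundle.persons
    males = persons[(persons["sex"] == "M") & persons["iq_z"].notna() & persons["res_z"].notna()]
    males = males[males["id"].isin(scores.index)]
    ev = bundle.events
    ev = ev[ev["disorder"] == disorder].set_index("id")["age_months"]
    age = males["id"].map(ev)
    pre19 = age < AGE19_MONTHS
    males = males[~pre19.fillna(False)]
    age = males["id"].map(ev)
    y = age.notna().to_numpy(int)
    g = males["id"].map(scores["GAEA"]).to_numpy(float)
    return MediationInput.from_arrays(
        g, males["iq_z"].to_numpy(float), males["res_z"].to_numpy(float), y
    )
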