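"""Tetrachoric and product-moment correlation between genetic scores.

The tetrachoric estimator assumes a latent bivariate normal dichotomized at
thresholds implied by the table margins and finds the latent correlation rho
maximizing the multinomial likelihood of the four cell counts; the standard
error comes from the observed information at the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

_RHO_BOUND = 0.9999


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts for a dichotomized pair: n11 both high, n10 row-high only, etc."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total == 0:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def transpose(self) -> "TwoByTwoTable":
        return TwoByTwoTable(self.n11, self.n01, self.n10, self.n00)

    def with_continuity_correction(self) -> "TwoByTwoTable":
        # 0.5 is added to every cell via a float-carrying shim table
        return _CorrectedTable(self.n11 + 0.5, self.n10 + 0.5, self.n01 + 0.5, self.n00 + 0.5)


@dataclass(frozen=True)
class _CorrectedTable(TwoByTwoTable):
    n11: float
    n10: float
    n01: float
    n00: float


@dataclass(frozen=True)
class CorrelationEstimate:
    rho: float
    se: float
    method: str
    n: int

    def __post_init__(self) -> None:
        if abs(self.rho) > 1 + 1e-12:
            raise ValueError("correlation outside [-1, 1]")


def _cell_probs(h: float, k: float, rho: float) -> tuple[float, float, float, float]:
    """Bivariate-normal quadrant probabilities at thresholds (h, k)."""
    cov = [[1.0, rho], [rho, 1.0]]
    # P(X > h, Y > k) = P(-X < -h? ...) use symmetry: survival = cdf at (-h, -k) with same rho
    p11 = float(stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([-h, -k]))
    p_row = float(stats.norm.sf(h))  # P(X > h)
    p_col = float(stats.norm.sf(k))
    p10 = p_row - p11
    p01 = p_col - p11
    p00 = 1.0 - p_row - p_col + p11
    eps = 1e-12
    return (max(p11, eps), max(p10, eps), max(p01, eps), max(p00, eps))


def tetrachoric_loglik(table: TwoByTwoTable, rho: float) -> float:
    """Multinomial log-likelihood at ``rho`` with margin-implied thresholds."""
    n = np.array([table.n11, table.n10, table.n01, table.n00], dtype=float)
    total = n.sum()
    h = stats.norm.isf((table.n11 + table.n10) / total)
    k = stats.norm.isf((table.n11 + table.n01) / total)
    p = np.array(_cell_probs(h, k, rho))
    return float(n @ np.log(p))


def tetrachoric_mle(
    table: TwoByTwoTable, continuity_correction: bool = False
) -> CorrelationEstimate:
    """Maximum-likelihood tetrachoric correlation from a 2x2 table.

    Thresholds are fixed at the normal quantiles of the margins; rho is found
    by bounded scalar optimization of the cell-probability likelihood. Zero
    margins are an error unless ``continuity_correction`` adds 0.5 per cell.
    """
    if continuity_correction:
        table = table.with_continuity_correction()
    margins = (
        table.n11 + table.n10,
        table.n01 + table.n00,
        table.n11 + table.n01,
        table.n10 + table.n00,
    )
    if min(margins) <= 0:
        raise ValueError(
            "zero margin in 2x2 table; rerun with continuity_correction=True "
            "to add 0.5 to every cell"
        )
    res = optimize.minimize_scalar(
        lambda r: -tetrachoric_loglik(table, r),
        bounds=(-_RHO_BOUND, _RHO_BOUND),
        method="bounded",
        options={"xatol": 1e-8},
    )
    rho = float(res.x)
    se = _se_from_information(table, rho)
    return CorrelationEstimate(rho=rho, se=se, method="tetrachoric", n=int(round(table.total)))


def _se_from_information(table: TwoByTwoTable, rho: float, step: float = 1e-4) -> float:
    hi = min(rho + step, _RHO_BOUND)
    lo = max(rho - step, -_RHO_BOUND)
    f = lambda r: tetrachoric_loglik(table, r)
    d2 = (f(hi) - 2.0 * f(rho) + f(lo)) / ((0.5 * (hi - lo)) ** 2)
    if d2 >= 0:
        return float("nan")
    return float(1.0 / np.sqrt(-d2))


def median_split_table(a: np.ndarray, b: np.ndarray) -> TwoByTwoTable:
    """Dichotomize two paired continuous vectors at their medians."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ha = a > np.median(a)
    hb = b > np.median(b)
    return TwoByTwoTable(
        n11=int(np.sum(ha & hb)),
        n10=int(np.sum(ha & ~hb)),
        n01=int(np.sum(~ha & hb)),
        n00=int(np.sum(~ha & ~hb)),
    )


def score_correlation(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    method: str = "product-moment",
) -> CorrelationEstimate:
    """Correlation between two paired score vectors.

    method="product-moment" gives the Pearson correlation of the continuous
    scores; method="tetrachoric" median-splits both vectors and applies the
    latent-normal MLE.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape:
        raise ValueError("score vectors must be paired (same length)")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 paired scores")
    if method == "product-moment":
        rho = float(np.corrcoef(a, b)[0, 1])
        rho = float(np.clip(rho, -1.0, 1.0))
        if abs(rho) >= 1.0 - 1e-15:
            se = 0.0
        else:
            se = float(np.sqrt((1.0 - rho**2) / (n - 2)))
        return CorrelationEstimate(rho=rho, se=se, method="product-moment", n=n)
    if method == "tetrachoric":
        return tetrachoric_mle(median_split_table(a, b))
    raise ValueError(f"unknown method {method!r}")
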