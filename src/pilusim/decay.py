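"""Exponential-decay fitting and log-space tail extrapolation.

For every terminating growth model the correct-pilus probability P(C,n)
decays geometrically in n, with asymptotic per-subunit decay
ln max(p[E][E], p[A][A]).  Fitting ln P(C,n) = intercept + slope * n over a
window of lengths and summing the fitted geometric series analytically gives
tail probabilities P* far below anything Monte Carlo can count directly —
this is the simulate-fit-extrapolate route, with the closed form in
:mod:`pilusim.chain` as its exact counterpart.

Empirical bins are fitted by weighted least squares in log space: the
variance of ln(count / n_pili) is approximately 1/count for rare bins, so
weights equal the counts.  Exactly log-linear input is recovered to
floating precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .chain import DistributionTable, PStarResult

__all__ = ["DecayFit", "fit_decay", "extrapolate_p_star"]

LOG10 = math.log(10.0)

#: Lengths below this are excluded by default: the number of (i, j)
#: compositions still grows there and the decay is not yet geometric.
DEFAULT_N_LO = 10

#: Minimum count for an empirical bin to enter the fit.
DEFAULT_MIN_COUNT = 10


@dataclass(frozen=True)
class DecayFit:
    """Weighted least-squares fit of ln P(C,n) = intercept + slope * n."""

    slope: float
    intercept: float
    n_lo: int
    n_hi: int
    n_points: int
    residual_sd: float
    slope_se: float
    cov: np.ndarray  # 2x2 covariance of (intercept, slope)

    def predict_log(self, n) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(n, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slope": [self.slope],
                "intercept": [self.intercept],
                "n_lo": [self.n_lo],
                "n_hi": [self.n_hi],
                "n_points": [self.n_points],
                "residual_sd": [self.residual_sd],
                "slope_se": [self.slope_se],
            }
        )


def _extract_series(
    data, min_count: int, n_range: tuple[int, int] | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n, ln P(C,n), weights) of qualifying bins from either input kind.

    ``data`` may be an analytic :class:`DistributionTable` (unit weights) or
    an empirical frame from :func:`pilusim.growth.empirical_pmf` with
    ``correct_count`` (weights = counts, bins with count < min_count drop).
    """
    if isinstance(data, DistributionTable):
        if data.log_P_Cn is None:
            raise ValueError("DistributionTable has no P(C,n) column to fit")
        n = np.asarray(data.n, dtype=float)
        y = np.asarray(data.log_P_Cn, dtype=float)
        w = np.ones_like(y)
        keep = np.isfinite(y)
    elif isinstance(data, pd.DataFrame):
        if "correct_count" not in data or "P_Cn" not in data:
            raise ValueError("empirical frame needs 'correct_count' and 'P_Cn' columns")
        n = data["n"].to_numpy(dtype=float)
        counts = data["correct_count"].to_numpy(dtype=float)
        keep = counts >= max(min_count, 1)
        with np.errstate(divide="ignore"):
            y = np.log(data["P_Cn"].to_numpy(dtype=float))
        w = counts
    else:
        raise TypeError(f"cannot fit decay on {type(data).__name__}")
    lo, hi = n_range if n_range is not None else (DEFAULT_N_LO, np.inf)
    keep = keep & (n >= lo) & (n <= hi)
    return n[keep], y[keep], w[keep]


def fit_decay(
    data,
    min_count: int = DEFAULT_MIN_COUNT,
    n_range: tuple[int, int] | None = None,
) -> DecayFit:
    """Fit the exponential decay of P(C,n) over qualifying length bins.

    Parameters
    ----------
    data
        Analytic :class:`DistributionTable` or empirical-pmf ``DataFrame``.
    min_count
        Empirical bins with fewer correct counts are dropped (their
        log-estimates are too noisy and biased).
    n_range
        Inclusive fit window; defaults to ``[10, inf)`` to skip the
        pre-asymptotic composition regime.
    """
    n, y, w = _extract_series(data, min_count, n_range)
    if len(n) < 2:
        raise ValueError(
            f"insufficient support for fit: {len(n)} qualifying bin(s), need >= 2"
        )
    X = sm.add_constant(n)
    res = sm.WLS(y, X, weights=w).fit()
    resid = y - res.fittedvalues
    return DecayFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        n_lo=int(n.min()),
        n_hi=int(n.max()),
        n_points=len(n),
        residual_sd=float(np.sqrt(np.mean(resid**2))),
        slope_se=float(res.bse[1]),
        cov=np.asarray(res.cov_params()),
    )


def extrapolate_p_star(fit: DecayFit, n_min: int) -> PStarResult:
    """Tail probability P* = sum_{n >= n_min} exp(intercept + slope n).

    Evaluates the geometric tail exp(intercept + slope n_min) / (1 - e^slope)
    in log space and propagates a standard-error band from the fit
    covariance (delta method); far extrapolations are meaningful only to
    order of magnitude and the band says how far.
    """
    if not fit.slope < 0:
        raise ValueError("non-decaying fit cannot be extrapolated")
    log_p = fit.intercept + fit.slope * n_min - math.log1p(-math.exp(fit.slope))
    # d log_p / d(intercept, slope); the tail factor contributes to the slope
    g = np.array([1.0, n_min + math.exp(fit.slope) / -math.expm1(fit.slope)])
    var = float(g @ fit.cov @ g)
    return PStarResult(
        log10_p_star=log_p / LOG10,
        n_min=n_min,
        method="fit_extrapolation",
        log10_se=math.sqrt(max(var, 0.0)) / LOG10,
    )


def write_fit_report(
    fit: DecayFit, p_stars: list[PStarResult], path
) -> None:
    """Fit report TSV: one fit row, then one row per requested n_min."""
    frame = fit.to_frame()
    rows = pd.DataFrame(
        {
            "n_min": [p.n_min for p in p_stars],
            "log10_p_star": [p.log10_p_star for p in p_stars],
            "log10_se": [p.log10_se for p in p_stars],
        }
    )
    with open(path, "w") as fh:
        frame.to_csv(fh, sep="\t", index=False)
        rows.to_csv(fh, sep="\t", index=False)
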