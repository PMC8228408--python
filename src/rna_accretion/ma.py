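"""Menzerath-Altmann law fitting for accretion series.

The law states that the larger the whole, the smaller its parts. For a
growing RNA molecule, let x be the number of substructures accumulated at
some point in its history and y(x) the mean length of the part added. The
general form is

    y(x) = A * x**b * exp(-c * x)

with the two classical special cases b = 0 (pure exponential shrinkage,
``y = A exp(-cx)``, the form used for accretion series) and c = 0 (pure
power law, the form used for protein domains). Fitting is done in log space
(``ln y = ln A + b ln x - c x``) by ordinary least squares, matching the
straight-line fitting procedure the field uses; an optional nonlinear
least-squares refit is available as a cross-check.

Because substructure count x grows roughly linearly with relative age t,
the special form doubles as an evolutionary decay law
``N(t) = N0 exp(-lambda t)`` with N0 = A and lambda = c * k, where k is the
number of substructures added per unit relative time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats as sps
import statsmodels.api as sm

from .stats import AccretionSeries

__all__ = ["MAFit", "DecayParams", "fit_ma_special", "fit_ma_general", "to_decay", "fit_report"]

#: condition number above which ln x and x are flagged as collinear
COLLINEARITY_THRESHOLD = 1e4


@dataclass
class MAFit:
    """Fitted MA-law parameters with standard errors and fit diagnostics.

    ``b`` is fixed at 0 for the special (exponential) form. ``F`` carries
    degrees of freedom ``df = (k, n - k - 1)`` where k is the number of
    regressors, and ``p`` is the right-tailed F p-value. ``R`` is the
    multiple correlation coefficient sqrt(R2). Standard errors for A come
    from the delta method (SE of the log-space intercept times A).
    """

    A: float
    b: float
    c: float
    SE_A: float
    SE_b: float
    SE_c: float
    R2: float
    R: float
    F: float
    df: tuple[int, int]
    p: float
    n: int
    form: str  # "special" | "general"
    collinear: bool = False
    #: (A, c) or (A, b, c) from the nonlinear refit, when requested and
    #: disagreeing with the log-space fit by more than 1%
    nls_params: tuple[float, ...] | None = None

    def ci(self, param: str, level: float = 0.95) -> tuple[float, float]:
        """Wald confidence interval for A, b, or c."""
        est = getattr(self, param)
        se = getattr(self, f"SE_{param}")
        z = sps.t.ppf(0.5 + level / 2, self.df[1])
        return est - z * se, est + z * se


@dataclass
class DecayParams:
    """Evolutionary decay parameterization N(t) = N0 exp(-lambda t)."""

    N0: float
    lam: float
    k: float


def _check_series(series: AccretionSeries, n_min: int) -> tuple[np.ndarray, np.ndarray]:
    x = series.x.astype(float)
    y = series.mean_length
    if len(x) < n_min:
        raise ValueError(f"need >= {n_min} points, got {len(x)}")
    if np.any(y <= 0):
        raise ValueError("all mean lengths must be positive to fit in log space")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in substructure count x")
    return x, y


def _f_stat(resid: np.ndarray, lny: np.ndarray, k: int) -> tuple[float, float, tuple[int, int]]:
    n = len(lny)
    df = (k, n - k - 1)
    sse = float((resid**2).sum())
    sst = float(((lny - lny.mean()) ** 2).sum())
    ssr = sst - sse
    if sst == 0 or ssr <= 0:
        return 0.0, 1.0, df
    if sse == 0:
        return float("inf"), 0.0, df
    F = (ssr / df[0]) / (sse / df[1])
    return F, float(sps.f.sf(F, *df)), df


def fit_ma_special(
    series: AccretionSeries, nonlinear_check: bool = False
) -> MAFit:
    """Fit the special MA form y = A exp(-c x) by log-linear OLS.

    Regresses ln y on x: A = exp(intercept), c = -slope. SE_A is propagated
    to A's scale by the delta method. A perfectly flat series returns c = 0
    with F = 0 and p = 1. With ``nonlinear_check``, a nonlinear
    least-squares refit is run and recorded when it moves A or c by > 1%.
    """
    x, y = _check_series(series, 3)
    lny = np.log(y)
    n = len(x)
    if np.allclose(lny, lny[0]):
        A = float(np.exp(lny.mean()))
        return MAFit(A, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, (1, n - 2), 1.0, n, "special")
    X = sm.add_constant(x)
    fit = sm.OLS(lny, X).fit()
    intercept, slope = fit.params
    A = float(np.exp(intercept))
    c = float(-slope)
    SE_A = float(fit.bse[0] * A)  # delta method on exp(intercept)
    SE_c = float(fit.bse[1])
    F, p, df = _f_stat(fit.resid, lny, 1)
    R2 = float(fit.rsquared)
    out = MAFit(A, 0.0, c, SE_A, 0.0, SE_c, R2, math.sqrt(max(R2, 0.0)), F, df, p, n, "special")
    if nonlinear_check:
        out.nls_params = _nls_refit(x, y, (A, c), lambda x, A, c: A * np.exp(-c * x))
    return out


def fit_ma_general(series: AccretionSeries, nonlinear_check: bool = False) -> MAFit:
    """Fit the general MA form y = A x^b exp(-c x) by log-linear OLS.

    Regresses ln y on ln x and x. Collinearity between ln x and x (common
    for short series) is flagged via the design-matrix condition number.
    """
    x, y = _check_series(series, 4)
    if np.any(x < 1):
        raise ValueError("general form needs x >= 1 (ln x regressor)")
    lny = np.log(y)
    n = len(x)
    X = sm.add_constant(np.column_stack([np.log(x), x]))
    fit = sm.OLS(lny, X).fit()
    collinear = bool(fit.condition_number > COLLINEARITY_THRESHOLD)
    if collinear:
        warnings.warn(
            f"ln x and x nearly collinear (cond={fit.condition_number:.3g}); "
            "b and c are poorly separated",
            stacklevel=2,
        )
    intercept, b, negc = fit.params
    A = float(np.exp(intercept))
    c = float(-negc)
    F, p, df = _f_stat(fit.resid, lny, 2)
    R2 = float(fit.rsquared)
    out = MAFit(
        A, float(b), c,
        float(fit.bse[0] * A), float(fit.bse[1]), float(fit.bse[2]),
        R2, math.sqrt(max(R2, 0.0)), F, df, p, n, "general", collinear,
    )
    if nonlinear_check:
        out.nls_params = _nls_refit(
            x, y, (A, b, c), lambda x, A, b, c: A * x**b * np.exp(-c * x)
        )
    return out


def _nls_refit(x, y, p0, model) -> tuple[float, ...] | None:
    """Nonlinear least-squares refit; returned only if it moves any
    parameter by more than 1% relative to the log-space estimate."""
    try:
        popt, _ = optimize.curve_fit(model, x, y, p0=p0, maxfev=10_000)
    except (RuntimeError, ValueError):
        return None
    moved = any(
        abs(a - b) > 0.01 * max(abs(b), 1e-12) for a, b in zip(popt, p0)
    )
    return tuple(float(v) for v in popt) if moved else None


def to_decay(fit: MAFit, k: float = 1.0) -> DecayParams:
    """Map an MA fit to decay parameters: N0 = A, lambda = c * k.

    ``k`` is the number of substructures accreted per unit relative time
    (x is approximately linear in age t on the 0-1 nd scale).
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    return DecayParams(N0=fit.A, lam=fit.c * k, k=k)


def fit_report(fits: dict[str, MAFit]) -> str:
    """Human-readable fit table: A +- SE, c +- SE, R2, R, F(df), p."""
    lines = [
        f"{'series':<16}{'A':>16}{'c':>16}{'R2':>8}{'R':>8}{'F(df1,df2)':>18}{'p':>10}"
    ]
    for name, f in fits.items():
        lines.append(
            f"{name:<16}"
            f"{f.A:>9.2f} (±{f.SE_A:.2f})"
            f"{f.c:>9.3f} (±{f.SE_c:.2f})"
            f"{f.R2:>8.3f}{f.R:>8.3f}"
            f"{f.F:>10.2f} ({f.df[0]},{f.df[1]})"
            f"{f.p:>10.2g}"
        )
    return "\n".join(lines) + "\n"
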