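"""Box–Cox power transformation of indicator distributions.

Cross-country indicator distributions are mostly non-normal (skewed,
sometimes multimodal even after a log transform), so each indicator is
passed through a Box–Cox transformation before T-score standardization:

    y = ((x + shift)^lambda - 1) / lambda     (lambda != 0)
    y = ln(x + shift)                          (lambda == 0)

``lambda`` is estimated per indicator by maximizing the profile
log-likelihood over all countries with data (never per income group —
grouping happens after scoring).  Because many indicators (mortality
rates, prevalences) can be exactly zero, a data-driven positive shift
is applied first; Box–Cox requires strictly positive inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .exceptions import DegenerateIndicatorError
from .indicators import CountryTable, MIN_NONMISSING

__all__ = [
    "BoxCoxFit",
    "choose_shift",
    "estimate_lambda",
    "boxcox_apply",
    "fit_table",
    "export_fits",
    "LAMBDA_GRID",
]

#: Default lambda search grid: [-3, 3] in steps of 0.05, then refined.
LAMBDA_GRID: tuple[float, float, float] = (-3.0, 3.0, 0.05)


@dataclass(frozen=True)
class BoxCoxFit:
    """Estimated Box–Cox parameters for one indicator.

    Attributes
    ----------
    lmbda : float
        Power parameter (dimensionless).
    shift : float
        Additive offset applied before transforming, in the indicator's
        own units; guarantees positivity.
    loglik : float
        Profile log-likelihood at ``lmbda``.
    n : int
        Number of non-missing values used in the fit.
    """

    lmbda: float
    shift: float
    loglik: float
    n: int


def _clean(values) -> np.ndarray:
    x = np.asarray(pd.Series(values, dtype=float).dropna(), dtype=float)
    return x


def choose_shift(values) -> float:
    """Shift making all non-missing values strictly positive.

    Zero if the minimum is already positive; otherwise ``-min + eps``
    with ``eps`` = 1% of the non-missing range (0.5 if the range is
    degenerate).  Mortality and prevalence variables are legitimately 0
    for some countries, so this comes up routinely.
    """
    x = _clean(values)
    if x.size == 0:
        return 0.0
    lo, hi = float(x.min()), float(x.max())
    if lo > 0:
        return 0.0
    rng = hi - lo
    eps = 0.01 * rng if rng > 0 else 0.5
    return -lo + eps


def estimate_lambda(
    values,
    grid: tuple[float, float, float] = LAMBDA_GRID,
    shift: float | None = None,
) -> BoxCoxFit:
    """Profile-maximum-likelihood Box–Cox lambda for one indicator.

    Scans ``grid`` (lower, upper, step), then refines the best grid
    point by golden-section search between its neighbours.  Missing
    values are ignored.

    Raises
    ------
    DegenerateIndicatorError
        If fewer than 3 non-missing values remain or the vector is
        constant.
    """
    x = _clean(values)
    if x.size < MIN_NONMISSING:
        raise DegenerateIndicatorError(
            f"need >= {MIN_NONMISSING} non-missing values, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise DegenerateIndicatorError("degenerate indicator: constant values")
    if shift is None:
        shift = choose_shift(x)
    xs = x + shift
    if xs.min() <= 0:
        raise DegenerateIndicatorError(
            f"shift {shift} leaves non-positive values (min {xs.min()})"
        )

    lo, hi, step = grid
    lambdas = np.arange(lo, hi + step / 2, step)
    llf = np.array([stats.boxcox_llf(l, xs) for l in lambdas])
    best = int(np.argmax(llf))

    def neg_llf(l: float) -> float:
        return -float(stats.boxcox_llf(l, xs))

    if 0 < best < len(lambdas) - 1:
        a, b, c = lambdas[best - 1], lambdas[best], lambdas[best + 1]
        try:
            lmbda = float(optimize.golden(neg_llf, brack=(a, b, c)))
        except ValueError:  # flat triple; keep the grid point
            lmbda = float(b)
    else:
        # maximum at a grid edge: refine within the edge cell only
        a = lambdas[max(best - 1, 0)]
        c = lambdas[min(best + 1, len(lambdas) - 1)]
        res = optimize.minimize_scalar(neg_llf, bounds=(a, c), method="bounded")
        lmbda = float(res.x)
    return BoxCoxFit(
        lmbda=lmbda,
        shift=float(shift),
        loglik=float(stats.boxcox_llf(lmbda, xs)),
        n=int(x.size),
    )


def boxcox_apply(values, fit: BoxCoxFit):
    """Apply a fitted Box–Cox transformation, preserving missingness.

    Accepts an array or Series; returns the same container type with
    non-missing entries transformed and NaN left in place.

    Raises
    ------
    DegenerateIndicatorError
        If any non-missing value is <= -shift (names the offending
        country when the input is an indexed Series).
    """
    series = isinstance(values, pd.Series)
    s = pd.Series(values, dtype=float) if not series else values.astype(float)
    mask = s.notna()
    xs = s[mask] + fit.shift
    if (xs <= 0).any():
        bad = xs.index[xs <= 0][0]
        raise DegenerateIndicatorError(
            f"value at {bad!r} is <= -shift ({-fit.shift}); cannot Box-Cox transform"
        )
    out = s.copy()
    out[mask] = special.boxcox(xs.to_numpy(), fit.lmbda)
    return out if series else out.to_numpy()


def fit_table(
    table: CountryTable,
    grid: tuple[float, float, float] = LAMBDA_GRID,
) -> dict[str, BoxCoxFit]:
    """Estimate a Box–Cox fit for every non-ceiling indicator in a table.

    Ceiling-flagged indicators are skipped (they are scored by the
    percentile method, not Box–Cox).  Degenerate indicators are skipped
    silently here; :func:`devgraph.deviation.score_table` reports them.
    """
    fits: dict[str, BoxCoxFit] = {}
    for spec in table.registry:
        if spec.ceiling:
            continue
        try:
            fits[spec.id] = estimate_lambda(table.data[spec.id], grid=grid)
        except DegenerateIndicatorError:
            continue
    return fits


def export_fits(fits: Mapping[str, BoxCoxFit], path: str | Path) -> None:
    """Write fitted lambdas/shifts to CSV so a run is auditable and repeatable."""
    frame = pd.DataFrame(
        [
            {
                "indicator": k,
                "lambda": f.lmbda,
                "shift": f.shift,
                "n": f.n,
                "loglik": f.loglik,
            }
            for k, f in fits.items()
        ]
    )
    frame.to_csv(path, index=False)
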