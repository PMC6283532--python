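"""Deviation values (T-scores), polarity orientation and table scoring.

The deviation value of a country on an indicator is the T-score of its
(Box–Cox transformed) value against all countries with data:

    T = 50 + 10 * (x - mean) / SD        (sample SD, n-1 denominator)

so the cross-country mean is 50 and one SD is worth 10 points.  For
ceiling indicators — variables piled up against an upper bound, where
mean/SD are uninformative — the score is instead derived from the rank:
percentile p = (rank - 0.5)/n (midranks for ties), mapped through the
standard normal quantile, T = 50 + 10 * Phi^-1(p).

Indicators for which a *lower* raw value is desirable (stunting,
smoking, blood pressure) are reflected about 50 after scoring so that a
higher deviation value always reads as "better"; reflection is its own
inverse and preserves the mean-50 / SD-10 calibration.

Scores are relative positions: a country missing an indicator does not
influence others on that indicator, but adding or removing a country
*with* data shifts everyone else's scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateIndicatorError
from .indicators import MIN_NONMISSING, CountryTable
from .transform import LAMBDA_GRID, BoxCoxFit, boxcox_apply, estimate_lambda

__all__ = [
    "METHOD_BOXCOX",
    "METHOD_PERCENTILE",
    "DeviationMatrix",
    "tscore",
    "percentile_tscore",
    "orient",
    "score_table",
    "ceiling_fraction",
]

METHOD_BOXCOX = "boxcox_tscore"
METHOD_PERCENTILE = "percentile"

#: Heuristic: warn (never auto-switch) when at least this fraction of a
#: non-ceiling indicator's values sit within 1% of the attainable
#: maximum — the indicator probably deserves the percentile method.
CEILING_WARN_FRACTION = 0.25


@dataclass
class DeviationMatrix:
    """Oriented deviation values for a scored table.

    Attributes
    ----------
    values : pandas.DataFrame
        Countries × indicators T-scores; NaN where the input was
        missing.  Indicators that could not be scored are absent.
    method : pandas.Series
        Per-indicator scoring method, ``boxcox_tscore`` or ``percentile``.
    oriented : pandas.Series
        Per-indicator bool: True where the raw polarity was
        lower-desirable and the scores were reflected about 50.
    fits : dict
        Box–Cox fit per boxcox_tscore indicator (audit trail).
    errors : dict
        indicator id → message for indicators that failed to score
        (degenerate / too sparse); the rest of the table is unaffected.
    """

    values: pd.DataFrame
    method: pd.Series
    oriented: pd.Series
    fits: dict[str, BoxCoxFit] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        """Export countries × indicators with method and orientation rows.

        The first two data rows are labelled ``#method`` and
        ``#oriented`` so the numeric backbone of every figure carries
        its own provenance.
        """
        header = pd.DataFrame(
            [self.method.reindex(self.values.columns),
             self.oriented.reindex(self.values.columns).astype(str)],
            index=["#method", "#oriented"],
        )
        out = pd.concat([header, self.values])
        out.index.name = "country"
        out.to_csv(path, na_rep="")


def tscore(values):
    """Standardize a vector to the T scale (mean 50, sample SD 10).

    Missing entries are preserved.  Raises
    :class:`DegenerateIndicatorError` on fewer than 3 non-missing
    values or zero sample SD.
    """
    series = isinstance(values, pd.Series)
    s = pd.Series(values, dtype=float) if not series else values.astype(float)
    x = s.dropna()
    if x.size < MIN_NONMISSING:
        raise DegenerateIndicatorError(
            f"need >= {MIN_NONMISSING} non-missing values, got {x.size}"
        )
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise DegenerateIndicatorError("degenerate indicator: zero standard deviation")
    out = 50.0 + 10.0 * (s - float(x.mean())) / sd
    return out if series else out.to_numpy()


def percentile_tscore(values):
    """Rank-based deviation values for ceiling indicators.

    Non-missing entries are midranked; percentile p = (rank - 0.5)/n
    avoids the infinite quantiles at p = 0 and 1; the deviation value is
    50 + 10 * Phi^-1(p).  The result is a strictly increasing function
    of rank, with the median country at 50.
    """
    series = isinstance(values, pd.Series)
    s = pd.Series(values, dtype=float) if not series else values.astype(float)
    x = s.dropna()
    if x.size < MIN_NONMISSING:
        raise DegenerateIndicatorError(
            f"need >= {MIN_NONMISSING} non-missing values, got {x.size}"
        )
    ranks = stats.rankdata(x.to_numpy(), method="average")
    p = (ranks - 0.5) / x.size
    out = s.copy()
    out[x.index] = 50.0 + 10.0 * stats.norm.ppf(p)
    return out if series else out.to_numpy()


def orient(values, polarity: str):
    """Orient deviation values so that higher always means more desirable.

    ``higher_desirable`` and ``neutral`` pass through unchanged;
    ``lower_desirable`` is reflected about 50 (t -> 100 - t), which is
    equivalent to negating the raw variable before standardization and
    is an involution.
    """
    if polarity in ("higher_desirable", "neutral"):
        return values
    if polarity == "lower_desirable":
        return 100.0 - values
    raise ValueError(f"unknown polarity {polarity!r}")


def ceiling_fraction(values, attainable_max: float | None = None) -> float:
    """Fraction of non-missing values within 1% of the attainable maximum.

    ``attainable_max`` defaults to 100 for percentage-like vectors
    (all values in [0, 100]) and to the observed maximum otherwise.
    """
    x = pd.Series(values, dtype=float).dropna()
    if x.empty:
        return 0.0
    if attainable_max is None:
        attainable_max = 100.0 if (x.min() >= 0 and x.max() <= 100) else float(x.max())
    if attainable_max == 0:
        return 0.0
    return float((x >= attainable_max * 0.99).mean())


def score_table(
    table: CountryTable,
    fits: Mapping[str, BoxCoxFit] | None = None,
    method_overrides: Mapping[str, str] | None = None,
    grid: tuple[float, float, float] = LAMBDA_GRID,
) -> DeviationMatrix:
    """Score every indicator of a table into oriented deviation values.

    Each indicator is scored by the percentile method if its registry
    spec has ``ceiling=True`` (or an entry in ``method_overrides`` says
    so), otherwise by Box–Cox transform + T-score; scores are then
    oriented by polarity.  Per-indicator failures (constant vector, too
    few values) are collected into ``errors`` instead of aborting the
    run.  Standardization is always against all countries with data for
    the indicator; income-group views are taken afterwards.
    """
    overrides = dict(method_overrides or {})
    fits = dict(fits or {})
    cols: dict[str, pd.Series] = {}
    methods: dict[str, str] = {}
    oriented: dict[str, bool] = {}
    used_fits: dict[str, BoxCoxFit] = {}
    errors: dict[str, str] = {}

    for spec in table.registry:
        raw = table.data[spec.id]
        method = overrides.get(
            spec.id, METHOD_PERCENTILE if spec.ceiling else METHOD_BOXCOX
        )
        if method not in (METHOD_BOXCOX, METHOD_PERCENTILE):
            errors[spec.id] = f"unknown method override {method!r}"
            continue
        try:
            if method == METHOD_PERCENTILE:
                scored = percentile_tscore(raw)
            else:
                frac = ceiling_fraction(raw)
                if frac >= CEILING_WARN_FRACTION:
                    warnings.warn(
                        f"indicator {spec.id!r}: {frac:.0%} of values within 1% of "
                        "the attainable maximum; consider the percentile method",
                        stacklevel=2,
                    )
                fit = fits.get(spec.id)
                if fit is None:
                    fit = estimate_lambda(raw, grid=grid)
                used_fits[spec.id] = fit
                scored = tscore(boxcox_apply(raw, fit))
        except DegenerateIndicatorError as exc:
            errors[spec.id] = str(exc)
            continue
        cols[spec.id] = orient(scored, spec.polarity)
        methods[spec.id] = method
        oriented[spec.id] = spec.polarity == "lower_desirable"

    values = pd.DataFrame(cols, index=table.data.index)
    return DeviationMatrix(
        values=values,
        method=pd.Series(methods, dtype=object),
        oriented=pd.Series(oriented, dtype=bool),
        fits=used_fits,
        errors=errors,
    )
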