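"""Distribution-shape classification of indicator score distributions.

Cross-country indicator distributions fall into four descriptive
shapes: ``normal`` (one mode, roughly symmetric), ``distorted`` (one
mode, clearly skewed), ``bimodal`` and ``trimodal``.  Multimodality is
diagnostically interesting: a bimodal mortality indicator means the
world splits into two clusters of countries rather than spreading
around one centre.

The classifier is parametric: it fits a normal, a skew-normal, and
tied-variance Gaussian mixtures with 2 and 3 components, picks the best
model by AIC, and counts the modes of the selected fitted density
(overlapping mixture components can merge into a single mode, so the
component count alone is not the mode count).  Unimodal fits are then
split into ``normal`` vs ``distorted`` by a skewness gate.  Four or
more detected modes collapse to ``trimodal`` to stay within the
four-label taxonomy.  All thresholds are exposed because they are a
convention of this package, not a community standard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal, stats
from sklearn.mixture import GaussianMixture

from .deviation import DeviationMatrix
from .exceptions import DegenerateIndicatorError

__all__ = ["ModalityConfig", "ModalityLabel", "classify_modality", "classify_table"]

LABELS = ("normal", "distorted", "bimodal", "trimodal")


@dataclass(frozen=True)
class ModalityConfig:
    """Tunable thresholds for :func:`classify_modality`.

    prominence : float
        Minimum mode prominence as a fraction of the fitted density's
        maximum; suppresses shoulder artefacts of the mixture fit.
    skew_threshold : float
        |skewness| above which a unimodal distribution is ``distorted``.
    max_components : int
        Largest mixture size tried (3 matches the trimodal label).
    min_n : int
        Below this many non-missing values the classifier returns
        ``normal`` with ``low_confidence=True`` rather than guessing.
    """

    prominence: float = 0.05
    skew_threshold: float = 0.8
    max_components: int = 3
    min_n: int = 20


@dataclass
class ModalityLabel:
    """Classification result for one indicator distribution."""

    label: str
    n_modes: int
    skewness: float
    low_confidence: bool = False
    diagnostics: dict = field(default_factory=dict)


def _fit_candidates(z: np.ndarray, config: ModalityConfig, random_state: int):
    """AIC for each candidate density model of standardized data ``z``."""
    n = z.size
    candidates: dict[str, tuple[float, object]] = {}
    mu, sd = float(z.mean()), float(z.std())
    ll = float(stats.norm.logpdf(z, mu, sd).sum())
    candidates["normal"] = (2 * 2 - 2 * ll, None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            a, loc, scale = stats.skewnorm.fit(z)
            ll = float(stats.skewnorm.logpdf(z, a, loc, scale).sum())
            if np.isfinite(ll):
                candidates["skewnorm"] = (2 * 3 - 2 * ll, None)
        except Exception:
            pass
    X = z.reshape(-1, 1)
    for k in range(2, config.max_components + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="tied",
            n_init=4,
            random_state=random_state,
        ).fit(X)
        ll = float(gm.score(X)) * n
        # k means + (k-1) weights + 1 shared variance = 2k parameters
        candidates[f"mixture{k}"] = (2 * (2 * k) - 2 * ll, gm)
    return candidates


def _count_modes(gm: GaussianMixture, z: np.ndarray, prominence: float) -> int:
    grid = np.linspace(z.min() - 1.0, z.max() + 1.0, 1024)
    dens = np.exp(gm.score_samples(grid.reshape(-1, 1)))
    peaks, _ = signal.find_peaks(dens, prominence=prominence * dens.max())
    return max(1, len(peaks))


def classify_modality(
    values,
    config: ModalityConfig | None = None,
    random_state: int = 0,
) -> ModalityLabel:
    """Classify one indicator's score distribution.

    Input is standardized internally (and reflected so skewness is
    non-negative), which makes the label exactly invariant under affine
    rescaling of the input vector.

    Raises
    ------
    DegenerateIndicatorError
        On constant input.
    """
    config = config or ModalityConfig()
    x = np.asarray(pd.Series(values, dtype=float).dropna(), dtype=float)
    if x.size == 0 or np.ptp(x) == 0:
        raise DegenerateIndicatorError("degenerate indicator: constant or empty")
    skew = float(stats.skew(x))
    if x.size < config.min_n:
        return ModalityLabel(
            label="normal",
            n_modes=1,
            skewness=skew,
            low_confidence=True,
            diagnostics={"reason": f"n={x.size} < min_n={config.min_n}"},
        )
    z = (x - x.mean()) / x.std(ddof=1)
    if skew < 0:
        z = -z
    candidates = _fit_candidates(z, config, random_state)
    winner = min(candidates, key=lambda k: candidates[k][0])
    gm = candidates[winner][1]
    if gm is None:
        n_modes = 1
    else:
        n_modes = _count_modes(gm, z, config.prominence)
    diagnostics = {
        "model": winner,
        "aic": {k: round(v[0], 3) for k, v in candidates.items()},
        "n": int(x.size),
    }
    if n_modes <= 1:
        label = "distorted" if abs(skew) > config.skew_threshold else "normal"
        n_modes = 1
    elif n_modes == 2:
        label = "bimodal"
    else:
        label = "trimodal"
        if n_modes > 3:
            diagnostics["note"] = f"{n_modes} modes detected; collapsed to trimodal"
            n_modes = 3
    return ModalityLabel(
        label=label, n_modes=n_modes, skewness=skew, diagnostics=diagnostics
    )


def classify_table(
    matrix: DeviationMatrix,
    config: ModalityConfig | None = None,
    random_state: int = 0,
) -> pd.DataFrame:
    """Per-indicator modality report for a scored table.

    Returns a DataFrame indexed by indicator id with columns
    ``label``, ``n_modes``, ``skewness``, ``low_confidence``; write it
    with ``.to_csv`` for the standard report.
    """
    rows = {}
    for col in matrix.values.columns:
        try:
            lab = classify_modality(matrix.values[col], config, random_state)
        except DegenerateIndicatorError as exc:
            rows[col] = {"label": "error", "n_modes": 0, "skewness": np.nan,
                         "low_confidence": True, "note": str(exc)}
            continue
        rows[col] = {
            "label": lab.label,
            "n_modes": lab.n_modes,
            "skewness": lab.skewness,
            "low_confidence": lab.low_confidence,
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "indicator"
    return frame
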