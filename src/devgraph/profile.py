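"""Per-country deviation profiles, qualitative banding and graphs.

A country profile lists the country's oriented deviation values in
life-stage order and attaches a qualitative band to each:

    very_low  < 35
    low       35 .. <45
    middle    45 .. 55
    high      >55 .. <72
    very_high >= 72

The cutpoints mirror the verbal scale typically used when reading
deviation graphs (scores in the 40s read "low", around 50 "middle",
60s "high", above the low 70s "very high"); they are configurable
because the verbal convention is fuzzy at the margins.

Profiles store *oriented* values (higher always better).  For
lower-desirable indicators the raw-direction reading is also carried
(``raw_direction_value`` = 100 - value), so "blood pressure very high
at 73" remains recognizable next to its oriented score of 27.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .deviation import DeviationMatrix
from .exceptions import ValidationError
from .indicators import INCOME_CLASSES, LIFE_STAGES, CountryTable

__all__ = [
    "BANDS",
    "DEFAULT_CUTPOINTS",
    "assign_band",
    "ProfileEntry",
    "CountryProfile",
    "GroupSummary",
    "build_profile",
    "flag_extremes",
    "summarize_group",
    "render_deviation_graph",
]

BANDS = ("very_low", "low", "middle", "high", "very_high")

#: (very_low|low, low|middle, middle|high, high|very_high) boundaries.
DEFAULT_CUTPOINTS: tuple[float, float, float, float] = (35.0, 45.0, 55.0, 72.0)


def assign_band(
    value: float, cutpoints: Sequence[float] = DEFAULT_CUTPOINTS
) -> str:
    """Band a finite deviation value; total and exclusive over the reals."""
    if not math.isfinite(value):
        raise ValueError(f"cannot band non-finite value {value!r}")
    c1, c2, c3, c4 = cutpoints
    if value < c1:
        return "very_low"
    if value < c2:
        return "low"
    if value <= c3:
        return "middle"
    if value < c4:
        return "high"
    return "very_high"


@dataclass
class ProfileEntry:
    """One indicator's contribution to a country profile."""

    indicator: str
    name: str
    life_stage: str
    value: float  # oriented deviation value; NaN if missing
    band: str | None  # None when value is missing
    method: str | None
    polarity: str
    oriented: bool  # True if the raw polarity was lower-desirable
    raw_direction_value: float  # == value unless oriented, then 100 - value


@dataclass
class CountryProfile:
    """A country's deviation values in life-stage order, with bands."""

    country: str
    income_class: str
    entries: list[ProfileEntry] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "indicator": e.indicator,
                    "name": e.name,
                    "life_stage": e.life_stage,
                    "value": e.value,
                    "band": e.band if e.band is not None else "",
                    "method": e.method if e.method is not None else "",
                    "polarity": e.polarity,
                    "oriented": e.oriented,
                    "raw_direction_value": e.raw_direction_value,
                }
                for e in self.entries
            ]
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "country": self.country,
            "income_class": self.income_class,
            "entries": [
                {
                    "indicator": e.indicator,
                    "name": e.name,
                    "life_stage": e.life_stage,
                    "value": None if np.isnan(e.value) else e.value,
                    "band": e.band,
                    "method": e.method,
                    "polarity": e.polarity,
                    "oriented": e.oriented,
                    "raw_direction_value": (
                        None if np.isnan(e.raw_direction_value)
                        else e.raw_direction_value
                    ),
                }
                for e in self.entries
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class GroupSummary:
    """Per-indicator spread of deviation values within one income class."""

    income_class: str
    stats: pd.DataFrame  # index: indicator; columns: mean, min, max, n


def build_profile(
    matrix: DeviationMatrix,
    table: CountryTable,
    country: str,
    cutpoints: Sequence[float] = DEFAULT_CUTPOINTS,
) -> CountryProfile:
    """Assemble one country's profile from a scored table.

    One entry per registry indicator that was scored, ordered by life
    stage (then registry order within a stage); missing values are kept
    as NaN entries with no band.
    """
    if country not in table.data.index:
        raise ValidationError(f"unknown country id {country!r}")
    stage_rank = {s: i for i, s in enumerate(LIFE_STAGES)}
    specs = [s for s in table.registry if s.id in matrix.values.columns]
    specs.sort(key=lambda s: stage_rank[s.life_stage])  # stable within stage
    entries = []
    for spec in specs:
        value = float(matrix.values.at[country, spec.id])
        oriented = bool(matrix.oriented.get(spec.id, False))
        method = str(matrix.method.get(spec.id))
        if np.isnan(value):
            entries.append(
                ProfileEntry(spec.id, spec.name, spec.life_stage, value,
                             None, method, spec.polarity, oriented, value)
            )
            continue
        entries.append(
            ProfileEntry(
                indicator=spec.id,
                name=spec.name,
                life_stage=spec.life_stage,
                value=value,
                band=assign_band(value, cutpoints),
                method=method,
                polarity=spec.polarity,
                oriented=oriented,
                raw_direction_value=100.0 - value if oriented else value,
            )
        )
    return CountryProfile(
        country=country,
        income_class=str(table.income_class[country]),
        entries=entries,
    )


def flag_extremes(
    profile: CountryProfile, k: float = 10.0
) -> list[tuple[str, str]]:
    """List a country's strengths and weaknesses.

    Indicators with an oriented value >= 50 + k are strengths, <= 50 - k
    weaknesses (k defaults to one reference SD); sorted by distance from
    50, largest first.  Neutral-polarity descriptive indicators never
    carry a desirability reading and are excluded.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    flags = []
    for e in profile.entries:
        if np.isnan(e.value) or e.band is None or e.polarity == "neutral":
            continue
        if e.value >= 50 + k:
            flags.append((e.indicator, "strength", abs(e.value - 50)))
        elif e.value <= 50 - k:
            flags.append((e.indicator, "weakness", abs(e.value - 50)))
    flags.sort(key=lambda t: -t[2])
    return [(ind, direction) for ind, direction, _ in flags]


def summarize_group(
    matrix: DeviationMatrix, table: CountryTable, income_class: str
) -> GroupSummary:
    """Mean/min/max deviation per indicator over one income class's members."""
    if income_class not in INCOME_CLASSES:
        raise ValidationError(f"unknown income class {income_class!r}")
    members = table.income_class.index[table.income_class == income_class]
    members = [m for m in members if m in matrix.values.index]
    if not members:
        raise ValidationError(f"no countries in income class {income_class!r}")
    sub = matrix.values.loc[members]
    frame = pd.DataFrame(
        {
            "mean": sub.mean(),
            "min": sub.min(),
            "max": sub.max(),
            "n": sub.notna().sum().astype(int),
        }
    )
    frame.index.name = "indicator"
    return GroupSummary(income_class=income_class, stats=frame)


_STAGE_COLORS = {
    "socioeconomic": "#4c72b0",
    "gestation_birth": "#dd8452",
    "infancy_under5": "#55a868",
    "wash": "#c44e52",
    "adult_lifestyle": "#8172b3",
    "adult_biomarker": "#937860",
    "ncd_mortality": "#da8bc3",
}


def render_deviation_graph(
    profile: CountryProfile,
    out_path: str | Path,
    cutpoints: Sequence[float] = DEFAULT_CUTPOINTS,
    kind: str = "bar",
) -> Path:
    """Render a country's deviation graph and its sidecar CSV.

    Writes a horizontal bar chart (or a radar chart with
    ``kind="radar"``): one mark per indicator, grouped and colored by
    life stage, a reference line at 50 and guides at the band
    cutpoints.  The exact plotted numbers are written next to the image
    as ``<stem>.csv`` — plots are for eyes, the CSV is the record.

    Returns the sidecar CSV path.
    """
    if not profile.entries:
        raise ValidationError("cannot render an empty profile")
    if kind not in ("bar", "radar"):
        raise ValueError(f"unknown graph kind {kind!r}")
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_path = Path(out_path)
    sidecar = out_path.with_suffix(".csv")

    frame = profile.to_frame()
    plotted = frame[frame["value"].notna()]

    if kind == "bar":
        height = max(3.0, 0.28 * len(plotted) + 1.2)
        fig, ax = plt.subplots(figsize=(8.5, height))
        y = np.arange(len(plotted))[::-1]
        colors = [_STAGE_COLORS.get(s, "#777777") for s in plotted["life_stage"]]
        ax.barh(y, plotted["value"] - 50.0, left=50.0, color=colors, height=0.7)
        ax.set_yticks(y)
        ax.set_yticklabels(plotted["name"], fontsize=7)
        ax.axvline(50, color="black", lw=1.2)
        for c in cutpoints:
            ax.axvline(c, color="grey", lw=0.6, ls="--")
        ax.set_xlabel("deviation value (oriented: higher = more desirable)")
    else:
        fig = plt.figure(figsize=(8, 8))
        ax = fig.add_subplot(polar=True)
        theta = np.linspace(0, 2 * np.pi, len(plotted), endpoint=False)
        vals = plotted["value"].to_numpy()
        theta_c = np.concatenate([theta, theta[:1]])
        vals_c = np.concatenate([vals, vals[:1]])
        ax.plot(theta_c, vals_c, lw=1.5)
        ax.fill(theta_c, vals_c, alpha=0.15)
        ax.plot(theta_c, np.full_like(theta_c, 50.0), color="black", lw=0.8)
        ax.set_xticks(theta)
        ax.set_xticklabels(plotted["name"], fontsize=6)
    ax.set_title(
        f"Deviation graph — {profile.country} ({profile.income_class} income)"
    )
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)

    frame.to_csv(sidecar, index=False, na_rep="")
    return sidecar
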