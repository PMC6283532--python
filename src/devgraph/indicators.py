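"""Indicator registry and country table handling.

A run is driven by two CSV files: a countries × indicators data table
(one row per country, keyed by a caller-supplied country id — ISO3
recommended — plus a World Bank style income class) and an indicator
registry describing each column (display name, life-stage group,
polarity, ceiling flag, units).  Countries are stratified into the four
income classes for display and group summaries; stratification never
re-standardizes scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "LIFE_STAGES",
    "POLARITIES",
    "INCOME_CLASSES",
    "IndicatorSpec",
    "CountryTable",
    "read_registry",
    "write_registry",
    "read_country_table",
    "write_country_table",
    "stratify_by_income",
    "partition_by_income",
    "example_registry",
    "MIN_NONMISSING",
]

#: Life-stage groups, in the order profiles and graphs present them
#: (conception → birth → childhood → environment → adult behaviour →
#: adult biology → cause of death).
LIFE_STAGES: tuple[str, ...] = (
    "socioeconomic",
    "gestation_birth",
    "infancy_under5",
    "wash",
    "adult_lifestyle",
    "adult_biomarker",
    "ncd_mortality",
)

POLARITIES: tuple[str, ...] = ("higher_desirable", "lower_desirable", "neutral")

#: World Bank income classes, largest economy first.
INCOME_CLASSES: tuple[str, ...] = ("high", "upper_middle", "lower_middle", "low")

#: Indicators with fewer non-missing values than this cannot be scored
#: (the sample SD is undefined below n=2 and useless at n=2).
MIN_NONMISSING: int = 3

_MISSING_TOKENS = {"", "NA", "NaN", "nan"}


@dataclass(frozen=True)
class IndicatorSpec:
    """Metadata for one indicator column.

    Parameters
    ----------
    id : str
        Short unique identifier (used as the CSV column name).
    name : str
        Human-readable display name.
    life_stage : str
        One of :data:`LIFE_STAGES`.
    polarity : str
        ``higher_desirable`` if a larger raw value is better (literacy),
        ``lower_desirable`` if smaller is better (stunting); ``neutral``
        is reserved for descriptive columns such as total population
        that are standardized but never read as good/bad.
    ceiling : bool
        True for variables compressed against an upper bound (near-100%
        literacy or supplementation coverage); these are scored by the
        rank-percentile method instead of Box–Cox standardization.
    units : str
        Free-text units, for display only.
    """

    id: str
    name: str
    life_stage: str
    polarity: str = "higher_desirable"
    ceiling: bool = False
    units: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("indicator id must be non-empty")
        if self.life_stage not in LIFE_STAGES:
            raise ValidationError(
                f"indicator {self.id!r}: unknown life stage {self.life_stage!r}; "
                f"expected one of {LIFE_STAGES}"
            )
        if self.polarity not in POLARITIES:
            raise ValidationError(
                f"indicator {self.id!r}: unknown polarity {self.polarity!r}; "
                f"expected one of {POLARITIES}"
            )


@dataclass
class CountryTable:
    """A validated countries × indicators table.

    ``data`` is a float DataFrame indexed by country id with one column
    per registry indicator, in registry order; missing cells are NaN.
    ``income_class`` is a Series aligned with ``data.index``.
    """

    data: pd.DataFrame
    income_class: pd.Series
    registry: list[IndicatorSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.registry]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate indicator id(s) in registry: {dupes}")
        if list(self.data.columns) != ids:
            unknown = [c for c in self.data.columns if c not in set(ids)]
            if unknown:
                raise ValidationError(
                    f"column(s) with no registry entry: {unknown}"
                )
            # reorder to registry order, dropping registry entries absent
            # from the data would hide errors, so require exact coverage
            missing = [i for i in ids if i not in set(self.data.columns)]
            if missing:
                raise ValidationError(
                    f"registry indicator(s) missing from data: {missing}"
                )
            self.data = self.data[ids]
        if self.data.index.has_duplicates:
            dupes = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise ValidationError(f"duplicate country id(s): {dupes}")
        self.income_class = self.income_class.reindex(self.data.index)
        bad = self.income_class[~self.income_class.isin(INCOME_CLASSES)]
        if len(bad):
            first = bad.index[0]
            raise ValidationError(
                f"unknown income class {bad.iloc[0]!r} for country {first!r}; "
                f"expected one of {INCOME_CLASSES}"
            )
        self.data = self.data.astype(float)

    @property
    def countries(self) -> list[str]:
        return list(self.data.index)

    @property
    def indicator_ids(self) -> list[str]:
        return [s.id for s in self.registry]

    def spec(self, indicator_id: str) -> IndicatorSpec:
        for s in self.registry:
            if s.id == indicator_id:
                return s
        raise KeyError(indicator_id)

    @property
    def specs(self) -> Mapping[str, IndicatorSpec]:
        return {s.id: s for s in self.registry}

    def class_sizes(self) -> dict[str, int]:
        """Number of countries in each of the four income classes."""
        counts = self.income_class.value_counts()
        return {c: int(counts.get(c, 0)) for c in INCOME_CLASSES}


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, np.integer)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "t", "yes", "y", "1"}:
        return True
    if text in {"false", "f", "no", "n", "0", ""}:
        return False
    raise ValidationError(f"cannot parse boolean ceiling flag {value!r}")


def read_registry(path: str | Path) -> list[IndicatorSpec]:
    """Read an indicator registry CSV (columns id,name,life_stage,polarity,ceiling,units)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "name", "life_stage", "polarity"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"registry {path}: missing column(s) {sorted(missing)}")
    specs = []
    for _, row in frame.iterrows():
        specs.append(
            IndicatorSpec(
                id=row["id"].strip(),
                name=row["name"].strip(),
                life_stage=row["life_stage"].strip(),
                polarity=row["polarity"].strip(),
                ceiling=_parse_bool(row.get("ceiling", "false")),
                units=str(row.get("units", "")).strip(),
            )
        )
    ids = [s.id for s in specs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"registry {path}: duplicate id(s) {dupes}")
    return specs


def write_registry(registry: Iterable[IndicatorSpec], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "id": s.id,
                "name": s.name,
                "life_stage": s.life_stage,
                "polarity": s.polarity,
                "ceiling": str(s.ceiling).lower(),
                "units": s.units,
            }
            for s in registry
        ]
    )
    frame.to_csv(path, index=False)


def read_country_table(
    data_path: str | Path,
    registry_path: str | Path,
    *,
    drop_sparse: bool = True,
) -> CountryTable:
    """Read and validate a country table CSV against a registry CSV.

    The data file must have a header row starting with the country-id
    column, then ``income_class``, then one column per indicator.
    Missing cells may be empty or ``NA``.  Indicators with fewer than
    :data:`MIN_NONMISSING` non-missing values are dropped with a warning
    (set ``drop_sparse=False`` to keep them and let scoring report them).
    """
    registry = read_registry(registry_path)
    frame = pd.read_csv(
        data_path, dtype=str, keep_default_na=False, skipinitialspace=True
    )
    if frame.shape[1] < 2:
        raise ValidationError(f"{data_path}: need country id and income_class columns")
    id_col = frame.columns[0]
    if "income_class" not in frame.columns:
        raise ValidationError(f"{data_path}: no income_class column")
    for pos, row in frame.iterrows():
        label = row["income_class"].strip()
        if label not in INCOME_CLASSES:
            raise ValidationError(
                f"{data_path} row {pos + 2} (country {row[id_col]!r}): "
                f"unknown income class {label!r}"
            )
    index = frame[id_col].str.strip()
    values = frame.drop(columns=[id_col, "income_class"])
    values = values.apply(
        lambda col: pd.to_numeric(col.where(~col.str.strip().isin(_MISSING_TOKENS)))
    )
    values.index = index
    income = frame["income_class"].str.strip()
    income.index = index
    table = CountryTable(data=values, income_class=income, registry=registry)
    if drop_sparse:
        table = _drop_sparse(table)
    return table


def _drop_sparse(table: CountryTable) -> CountryTable:
    counts = table.data.notna().sum()
    sparse = [c for c in table.data.columns if counts[c] < MIN_NONMISSING]
    if not sparse:
        return table
    warnings.warn(
        f"dropping indicator(s) with < {MIN_NONMISSING} non-missing values: {sparse}",
        stacklevel=3,
    )
    keep = [s for s in table.registry if s.id not in set(sparse)]
    return CountryTable(
        data=table.data.drop(columns=sparse),
        income_class=table.income_class,
        registry=keep,
    )


def write_country_table(
    table: CountryTable,
    data_path: str | Path,
    registry_path: str | Path | None = None,
) -> None:
    """Write a country table (and optionally its registry) to CSV.

    Missing cells are written as empty strings so the file round-trips
    through :func:`read_country_table`.
    """
    out = table.data.copy()
    out.insert(0, "income_class", table.income_class)
    out.index.name = out.index.name or "country"
    out.to_csv(data_path, na_rep="")
    if registry_path is not None:
        write_registry(table.registry, registry_path)


def stratify_by_income(table: CountryTable, income_class: str) -> CountryTable:
    """Return the row subset for one income class.

    Subsetting is for display and grouping only — deviation values are
    always computed against the global (all-country) reference, so a
    stratified table must not be re-scored unless that is explicitly
    wanted.
    """
    if income_class not in INCOME_CLASSES:
        raise ValidationError(
            f"unknown income class {income_class!r}; expected one of {INCOME_CLASSES}"
        )
    mask = table.income_class == income_class
    if not mask.any():
        raise ValidationError(f"no countries in income class {income_class!r}")
    return CountryTable(
        data=table.data.loc[mask],
        income_class=table.income_class.loc[mask],
        registry=list(table.registry),
    )


def partition_by_income(table: CountryTable) -> dict[str, CountryTable]:
    """Split the table into the four income-class subsets (disjoint, exhaustive)."""
    return {
        c: stratify_by_income(table, c)
        for c in INCOME_CLASSES
        if (table.income_class == c).any()
    }


def example_registry() -> list[IndicatorSpec]:
    """The packaged example registry.

    A best-effort transcription of the nutrition-related indicator set
    commonly assembled from UNICEF / WHO / World Bank annual tables:
    54 indicators from gestation to death, grouped into the seven
    life-stage groups, with polarity and ceiling flags.  Intended as a
    template and as the default layout for the synthetic generator, not
    as an authoritative variable list.
    """
    ref = resources.files("devgraph.data").joinpath("example_registry.csv")
    with resources.as_file(ref) as path:
        return read_registry(path)
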