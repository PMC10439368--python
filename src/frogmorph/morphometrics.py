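"""Measurement tables, structural totals, Mosimann shape variables and group summaries.

The raw data are linear skeletal measurements (cm) per frog species —
skull, vertebral column, pelvis, sacral width, sacral-diapophysis expansion
(ESD), ilium, urostyle, limb segments and limb-bone widths — plus the iliac
angle (degrees) and three categorical labels: locomotor mode, habitat type
and major phylogenetic group.

Size correction follows Mosimann: each specimen's measurements are divided
by their geometric mean, yielding dimensionless shape ratios whose product
is 1 (log-shape values sum to 0). Angles are never part of the geometric
mean; they carry different units and Table-2-style summaries present them
raw.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LOCOMOTOR_MODES",
    "HABITATS",
    "PHYLO_GROUPS",
    "FULL_VARIABLES",
    "STRUCTURAL_VARIABLES",
    "DEFAULT_COMPOSITION",
    "DIAGNOSTIC_RATIOS",
    "MeasurementTable",
    "ShapeTable",
    "GroupSummary",
    "read_measurements",
    "derive_structural",
    "mosimann_shape",
    "compute_ratios",
    "group_summary",
]

#: Locomotor modes: walker-hopper, burrower-walker-hopper, terrestrial
#: jumper, arboreal jumper, aquatic swimmer.
LOCOMOTOR_MODES = ("WH", "BWH", "TJ", "AJ", "AQ")
HABITATS = ("terrestrial", "arboreal", "riparian", "aquatic")
#: "Neobatrachia" labels the ten species outside Hyloidea/Ranoidea that are
#: not basal; they are excluded from grouped descriptive statistics and
#: held out of clade discriminant training.
PHYLO_GROUPS = ("basal", "Hyloidea", "Ranoidea", "Neobatrachia")

#: The 16 analysed variables of the full dataset (15 lengths + iliac angle).
FULL_VARIABLES = (
    "skull", "vert", "pelv", "sacr_w", "ilium", "uro",
    "fem", "fem_w", "tib", "calc", "foot",
    "hum", "hum_w", "rad", "hand",
    "iliac_angle",
)

#: The 9-variable structural subset: derived totals plus the untouched
#: width/pelvic variables.
STRUCTURAL_VARIABLES = (
    "SVL", "sacr_w", "ilium", "uro", "HL", "fem_w", "FL", "hum_w",
    "iliac_angle",
)

#: Default composition of structural totals from raw segments. The exact
#: published component lists live in supplementary material, so the map is
#: configurable; this default sums the obvious anatomical constituents.
DEFAULT_COMPOSITION: dict[str, tuple[str, ...]] = {
    "SVL": ("skull", "vert", "pelv"),
    "HL": ("fem", "tib", "calc", "foot"),
    "FL": ("hum", "rad", "hand"),
}

#: The ten diagnostic ratios of Table-2 style descriptive statistics,
#: computed per specimen from raw measurements (ratios are scale-free).
DIAGNOSTIC_RATIOS: dict[str, tuple[str, str]] = {
    "HL/FL": ("HL", "FL"),
    "HL/SVL": ("HL", "SVL"),
    "ESD/HL": ("ESD", "HL"),
    "fem/HL": ("fem", "HL"),
    "tib/HL": ("tib", "HL"),
    "calc/HL": ("calc", "HL"),
    "foot/HL": ("foot", "HL"),
    "tib/fem": ("tib", "fem"),
    "fem_w/fem": ("fem_w", "fem"),
    "hum_w/hum": ("hum_w", "hum"),
}

_CATEGORY_LEVELS = {
    "locomotor_mode": LOCOMOTOR_MODES,
    "habitat": HABITATS,
    "phylo_group": PHYLO_GROUPS,
    "locomotor_mode_2": LOCOMOTOR_MODES,
    "habitat_2": HABITATS,
}

#: Columns that hold angles (degrees); excluded from geometric means.
ANGLE_COLUMNS = ("iliac_angle",)


class MeasurementError(ValueError):
    """Invalid measurement table content."""


@dataclass
class MeasurementTable:
    """Species × raw-measurement table with categorical labels.

    ``data`` is indexed by species id; measurement columns are floats in cm
    (iliac_angle in degrees), label columns are strings.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        validate_measurements(self.data)

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def n(self) -> int:
        return len(self.data)

    def measurement_columns(self) -> list[str]:
        return [
            c for c in self.data.columns
            if c not in _CATEGORY_LEVELS and c != "family"
            and pd.api.types.is_numeric_dtype(self.data[c])
            and not pd.api.types.is_bool_dtype(self.data[c])
        ]

    def labels(self, grouping: str) -> pd.Series:
        if grouping not in ("locomotor_mode", "habitat", "phylo_group"):
            raise KeyError(f"unknown grouping {grouping!r}")
        return self.data[grouping]

    def matrix(self, variables: Sequence[str]) -> np.ndarray:
        missing = [v for v in variables if v not in self.data.columns]
        if missing:
            raise MeasurementError(f"missing columns: {missing}")
        return self.data[list(variables)].to_numpy(dtype=float)

    def subset(self, species: Sequence[str]) -> "MeasurementTable":
        missing = [s for s in species if s not in self.data.index]
        if missing:
            raise MeasurementError(f"unknown species: {missing}")
        return MeasurementTable(self.data.loc[list(species)].copy())

    def write(self, path: str | Path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep, index_label="species_id")


@dataclass
class ShapeTable:
    """Size-corrected shape variables per species.

    ``values`` holds Mosimann ratios (``log=False``) or their natural logs
    (``log=True``); ``size`` is the per-specimen geometric mean of the
    selected length measurements (cm).
    """

    values: pd.DataFrame
    size: pd.Series
    log: bool
    variable_set: tuple[str, ...]

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def as_log(self) -> "ShapeTable":
        if self.log:
            return self
        return ShapeTable(np.log(self.values), self.size, True, self.variable_set)

    def as_ratio(self) -> "ShapeTable":
        if not self.log:
            return self
        return ShapeTable(np.exp(self.values), self.size, False, self.variable_set)

    def write(self, path: str | Path, sep: str = ",") -> None:
        out = self.values.copy()
        out.insert(0, "size", self.size)
        out.to_csv(path, sep=sep, index_label="species_id")


@dataclass
class GroupSummary:
    """Per-group descriptive statistics (Table-2 layout).

    ``mean`` and ``se`` are group × variable frames; ``n`` counts species
    per group; ``highest``/``lowest`` name, per variable, the group with
    the extreme mean (ties broken by declared level order).
    """

    grouping: str
    n: pd.Series
    mean: pd.DataFrame
    se: pd.DataFrame
    highest: pd.Series = field(default_factory=pd.Series)
    lowest: pd.Series = field(default_factory=pd.Series)

    def to_record(self) -> dict:
        return {
            "grouping": self.grouping,
            "n": {str(k): int(v) for k, v in self.n.items()},
            "mean": {g: {v: float(x) for v, x in row.items()}
                     for g, row in self.mean.iterrows()},
            "se": {g: {v: float(x) for v, x in row.items()}
                   for g, row in self.se.iterrows()},
            "highest": {str(k): str(v) for k, v in self.highest.items()},
            "lowest": {str(k): str(v) for k, v in self.lowest.items()},
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_record(), indent=2))


def validate_measurements(df: pd.DataFrame) -> None:
    """Raise :class:`MeasurementError` on any invariant violation."""
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise MeasurementError(f"duplicate species_id: {dups}")
    for col, levels in _CATEGORY_LEVELS.items():
        if col not in df.columns:
            continue
        vals = df[col].dropna()
        bad = sorted(set(vals) - set(levels))
        if bad:
            raise MeasurementError(
                f"unknown {col} level(s) {bad}; allowed: {list(levels)}"
            )
    for col in df.columns:
        if col in _CATEGORY_LEVELS or col == "family":
            continue
        if not pd.api.types.is_numeric_dtype(df[col]) or pd.api.types.is_bool_dtype(df[col]):
            continue
        vals = df[col]
        if vals.isna().any():
            rows = df.index[vals.isna()].tolist()
            raise MeasurementError(f"missing value in column {col!r}, rows {rows}")
        if col in ANGLE_COLUMNS:
            bad = df.index[(vals <= 0) | (vals >= 90)].tolist()
            if bad:
                raise MeasurementError(
                    f"iliac_angle outside (0, 90) degrees in rows {bad}"
                )
        elif (vals <= 0).any():
            rows = df.index[vals <= 0].tolist()
            raise MeasurementError(
                f"non-positive measurement in column {col!r}, rows {rows}"
            )


def read_measurements(
    source: str | Path,
    sep: str | None = None,
    drop_incomplete: bool = False,
) -> MeasurementTable:
    """Read a delimited measurement table (comma default, tab accepted).

    The file must have a header row and a ``species_id`` column. Rows with
    missing required values raise by default; with ``drop_incomplete`` they
    are dropped and their ids reported on the returned table's attrs.
    """
    path = Path(source)
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    if "species_id" not in df.columns:
        raise MeasurementError("missing required column 'species_id'")
    df = df.set_index("species_id")
    dropped: list[str] = []
    if drop_incomplete:
        numeric = [c for c in df.columns
                   if c not in _CATEGORY_LEVELS and c != "family"]
        mask = df[numeric].isna().any(axis=1)
        dropped = df.index[mask].tolist()
        df = df.loc[~mask]
    table = MeasurementTable(df)
    table.data.attrs["dropped_rows"] = dropped
    return table


def derive_structural(
    table: MeasurementTable,
    composition: Mapping[str, Sequence[str]] | None = None,
) -> MeasurementTable:
    """Collapse segment measurements into structural totals.

    Each total (default SVL, HL, FL) is the sum of its component columns;
    variables not involved in any total pass through unchanged. The result
    carries the 9 structural variables plus labels and any extra columns
    (ESD is kept when present, for the diagnostic ratios).
    """
    comp = dict(DEFAULT_COMPOSITION if composition is None else composition)
    df = table.data
    for total, parts in comp.items():
        missing = [p for p in parts if p not in df.columns]
        if missing:
            raise MeasurementError(
                f"composition for {total!r} references missing columns {missing}"
            )
    consumed = {p for parts in comp.values() for p in parts}
    out = pd.DataFrame(index=df.index)
    for total, parts in comp.items():
        out[total] = df[list(parts)].sum(axis=1)
    for col in df.columns:
        if col not in consumed and col not in comp:
            out[col] = df[col]
    ordered = [v for v in STRUCTURAL_VARIABLES if v in out.columns]
    rest = [c for c in out.columns if c not in ordered]
    return MeasurementTable(out[ordered + rest])


def with_totals(
    table: MeasurementTable,
    composition: Mapping[str, Sequence[str]] | None = None,
) -> MeasurementTable:
    """Append structural totals (SVL, HL, FL...) without dropping segments.

    Used for the diagnostic ratios, which mix totals (HL/FL) and raw
    segments (tib/fem) in their numerators and denominators.
    """
    comp = dict(DEFAULT_COMPOSITION if composition is None else composition)
    df = table.data.copy()
    for total, parts in comp.items():
        missing = [p for p in parts if p not in df.columns]
        if missing:
            raise MeasurementError(
                f"composition for {total!r} references missing columns {missing}"
            )
        df[total] = df[list(parts)].sum(axis=1)
    return MeasurementTable(df)


def geometric_mean_size(
    table: MeasurementTable, variables: Sequence[str]
) -> pd.Series:
    """Per-specimen geometric mean over the length variables only."""
    lengths = [v for v in variables if v not in ANGLE_COLUMNS]
    if not lengths:
        raise MeasurementError("no length variables for the geometric mean")
    X = table.matrix(lengths)
    if (X <= 0).any():
        raise MeasurementError("geometric mean requires strictly positive values")
    return pd.Series(
        np.exp(np.log(X).mean(axis=1)), index=table.data.index, name="size"
    )


def mosimann_shape(
    table: MeasurementTable,
    variables: Sequence[str] | None = None,
    log: bool = True,
    include_angle: bool = False,
) -> ShapeTable:
    """Size-correct measurements into Mosimann shape variables.

    size_i = (prod_j x_ij)^(1/p) over the length variables; shape_ij =
    x_ij / size_i, natural-logged when ``log``. Computed as log-then-
    row-center, which is algebraically identical to divide-then-log.
    Angle columns never enter the geometric mean and by default are
    excluded from the shape table altogether (mixed units).
    """
    if variables is None:
        variables = [
            v for v in table.measurement_columns()
            if include_angle or v not in ANGLE_COLUMNS
        ]
    lengths = [v for v in variables if v not in ANGLE_COLUMNS]
    size = geometric_mean_size(table, lengths)
    logX = np.log(table.matrix(lengths))
    log_shape = logX - logX.mean(axis=1, keepdims=True)
    values = pd.DataFrame(log_shape, index=table.data.index, columns=lengths)
    if not log:
        values = np.exp(values)
    return ShapeTable(values, size, log, tuple(lengths))


def compute_ratios(
    table: MeasurementTable,
    ratios: Mapping[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-specimen diagnostic ratios from raw measurements.

    The pipeline always averages specimen ratios, never takes ratios of
    group means. ESD falls back to sacr_w-independent column 'ESD' only if
    present.
    """
    spec = dict(DIAGNOSTIC_RATIOS if ratios is None else ratios)
    df = table.data
    out = pd.DataFrame(index=df.index)
    for name, (num, den) in spec.items():
        for col in (num, den):
            if col not in df.columns:
                raise MeasurementError(f"ratio {name!r} needs missing column {col!r}")
        out[name] = df[num] / df[den]
    return out


def group_summary(
    values: pd.DataFrame,
    groups: pd.Series,
    grouping: str = "group",
    level_order: Sequence[str] | None = None,
    exclude: Sequence[str] = (),
) -> GroupSummary:
    """Mean ± standard error per group, with extreme-group flags.

    SE = sd/sqrt(n) with ddof=1. ``exclude`` drops whole groups before
    summarising (e.g. the 10 "Neobatrachia" species in clade groupings).
    Max/min ties resolve to the first group in ``level_order``.
    """
    groups = groups.loc[values.index]
    keep = ~groups.isin(set(exclude))
    values, groups = values.loc[keep], groups.loc[keep]
    if level_order is None:
        level_order = [g for g in groups.unique()]
    present = [g for g in level_order if (groups == g).any()]
    empty = [g for g in level_order if g not in present]
    if empty:
        raise MeasurementError(f"group(s) with no members after exclusions: {empty}")
    n = pd.Series({g: int((groups == g).sum()) for g in present})
    mean = pd.DataFrame(
        {g: values.loc[groups == g].mean() for g in present}
    ).T
    se = pd.DataFrame(
        {
            g: values.loc[groups == g].std(ddof=1) / math.sqrt(n[g])
            for g in present
        }
    ).T.fillna(0.0)
    # idxmax/idxmin on the level-ordered frame breaks ties by first level
    highest = mean.idxmax(axis=0)
    lowest = mean.idxmin(axis=0)
    return GroupSummary(grouping, n, mean, se, highest, lowest)
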