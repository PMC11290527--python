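"""Domain vocabulary, tabular schemas, validation, and readers/writers.

Conventions used throughout the package:

* Ages are in Ma before present; **larger values are older**.  Every
  interval is stored as ``(older_bound, younger_bound)``.
* The four input tables (fossil occurrences, rock units, fossiliferous
  surfaces, geochemical samples) are tidy, UTF-8, comma- or tab-delimited
  text files with a header row; the delimiter is auto-detected from the
  header line.  Missing values are empty fields.
* Collections are plain :class:`pandas.DataFrame` objects validated against
  the schemas below; downstream modules operate on these frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "TimeGrid",
    "read_table",
    "write_table",
    "validate_table",
    "partition_by_age",
    "AFFINITIES",
    "ASSEMBLAGES",
    "RECORD_CLASSES",
    "LITHO_GROUPS",
    "DEPTH_CLASSES",
    "DEPTH_BEARING_GROUPS",
    "NONMARINE_GROUPS",
    "CONSTRAINT_QUALITIES",
    "SCHEMAS",
    "EDIACARAN_CAMBRIAN_BOUNDARY_MA",
    "BACE_ONSET_MA",
]

# Controlled vocabularies -------------------------------------------------

#: Lithological affinity of a fossil occurrence (lithology of the hosting bed).
AFFINITIES = (
    "shallow_mid_siliciclastic",
    "deep_siliciclastic",
    "shallow_mid_limestone",
    "shallow_mid_dolostone",
)

#: The four successive Ediacaran--Cambrian paleocommunities.
ASSEMBLAGES = ("Avalon", "WhiteSea", "Nama", "Cambrian")

RECORD_CLASSES = ("body", "trace", "holdfast_only", "excluded_taxon")

LITHO_GROUPS = (
    "siliciclastic",
    "limestone",
    "dolostone",
    "phosphorite",
    "diamictite",
    "evaporitic_semirestricted",
    "fluvial_subaerial",
    "volcanic",
)

DEPTH_CLASSES = (
    "shallow_inner_shelf",
    "mid_outer_shelf_upper_slope",
    "lower_slope_basinal",
    "not_applicable",
)

#: Groups that carry a water-depth subdivision.
DEPTH_BEARING_GROUPS = ("siliciclastic", "limestone", "dolostone")

#: Lithological groups treated as nonmarine (or semi-restricted) settings.
NONMARINE_GROUPS = ("evaporitic_semirestricted", "fluvial_subaerial", "volcanic")

CONSTRAINT_QUALITIES = ("well_constrained", "uncertain")

#: Default split of rock units into Ediacaran vs Cambrian.
EDIACARAN_CAMBRIAN_BOUNDARY_MA = 538.8
#: Default pre/post partition age for biotic data (onset of the basal
#: Cambrian carbon-isotope excursion).
BACE_ONSET_MA = 535.0


class SchemaError(ValueError):
    """A table is structurally incompatible with the requested schema."""


class ValidationError(ValueError):
    """A table row violates a domain invariant."""


# Schemas -----------------------------------------------------------------

SCHEMAS: dict[str, dict] = {
    "occurrences": {
        "required": [
            "genus",
            "region",
            "max_age",
            "min_age",
            "uncertainty_category",
            "lithology_affinity",
            "assemblage",
            "record_class",
            "lagerstatte",
        ],
        "floats": ["max_age", "min_age"],
        "ints": ["uncertainty_category"],
        "bools": ["lagerstatte"],
        "categorical": {
            "lithology_affinity": AFFINITIES,
            "assemblage": ASSEMBLAGES,
            "record_class": RECORD_CLASSES,
        },
    },
    "rock_units": {
        "required": [
            "region",
            "unit_id",
            "group",
            "depth",
            "marine",
            "mean_thickness",
            "area",
            "base_age",
            "top_age",
        ],
        "floats": ["mean_thickness", "area", "base_age", "top_age"],
        "ints": [],
        "bools": ["marine"],
        "categorical": {"group": LITHO_GROUPS, "depth": DEPTH_CLASSES},
    },
    "surfaces": {
        "required": ["surface_id", "region", "max_age", "min_age", "constraint_quality"],
        "floats": ["max_age", "min_age"],
        "ints": [],
        "bools": [],
        "categorical": {"constraint_quality": CONSTRAINT_QUALITIES},
    },
    "geochem": {
        "required": ["age", "d13C", "d238U", "provenance", "paired"],
        "floats": ["age", "d13C", "d238U"],
        "ints": [],
        "bools": ["paired"],
        "categorical": {},
    },
}

_TRUTHY = {"true": True, "false": False, "1": True, "0": False}


def _coerce_bool(series: pd.Series, name: str) -> pd.Series:
    if series.dtype == bool:
        return series
    out = series.map(
        lambda v: _TRUTHY.get(str(v).strip().lower())
        if not isinstance(v, (bool, np.bool_))
        else bool(v)
    )
    if out.isna().any():
        bad = out[out.isna()].index[0]
        raise ValidationError(f"column {name!r}: unparseable boolean at row {bad}")
    return out.astype(bool)


def validate_table(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    """Validate *df* against a named schema; returns a coerced copy."""
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    rules = SCHEMAS[schema]
    missing = [c for c in rules["required"] if c not in df.columns]
    if missing:
        raise SchemaError(f"schema {schema!r}: missing required column(s) {missing}")
    df = df.copy()
    for c in rules["floats"]:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    for c in rules["ints"]:
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            row = int(vals[vals.isna()].index[0])
            raise ValidationError(f"column {c!r}: non-integer value at row {row}")
        df[c] = vals.astype(int)
    for c in rules["bools"]:
        df[c] = _coerce_bool(df[c], c)
    for c, allowed in rules["categorical"].items():
        bad = ~df[c].isin(allowed)
        if bad.any():
            row = int(df.index[bad][0])
            raise ValidationError(
                f"column {c!r}: unknown token {df.loc[row, c]!r} at row {row}; "
                f"expected one of {list(allowed)}"
            )
    _check_invariants(df, schema)
    return df


def _check_invariants(df: pd.DataFrame, schema: str) -> None:
    if schema == "occurrences":
        bad = df["min_age"] > df["max_age"]
        if bad.any():
            row = int(df.index[bad][0])
            raise ValidationError(f"row {row}: min_age > max_age")
        bad = df["min_age"] <= 0
        if bad.any():
            row = int(df.index[bad][0])
            raise ValidationError(f"row {row}: ages must be positive")
        bad = ~df["uncertainty_category"].isin((1, 2, 3, 4))
        if bad.any():
            row = int(df.index[bad][0])
            raise ValidationError(f"row {row}: uncertainty_category must be in 1..4")
    elif schema == "rock_units":
        bad = df["base_age"] <= df["top_age"]
        if bad.any():
            row = int(df.index[bad][0])
            raise ValidationError(
                f"row {row} (unit {df.loc[row, 'unit_id']!r}): base_age must exceed top_age"
            )
        if (df["mean_thickness"] < 0).any():
            row = int(df.index[df["mean_thickness"] < 0][0])
            raise ValidationError(f"row {row}: negative mean_thickness")
        if (df["area"] <= 0).any():
            row = int(df.index[df["area"] <= 0][0])
            raise ValidationError(f"row {row}: area must be positive")
        # depth applies only to depth-bearing groups
        depth_bearing = df["group"].isin(DEPTH_BEARING_GROUPS)
        bad = ~depth_bearing & (df["depth"] != "not_applicable")
        if bad.any():
            row = int(df.index[bad][0])
            raise ValidationError(
                f"row {row}: depth class only applies to {DEPTH_BEARING_GROUPS}"
            )
    elif schema == "surfaces":
        bad = df["min_age"] > df["max_age"]
        if bad.any():
            row = int(df.index[bad][0])
            raise ValidationError(f"row {row}: min_age > max_age")
    elif schema == "geochem":
        bad = df["d13C"].isna() & df["d238U"].isna()
        if bad.any():
            row = int(df.index[bad][0])
            raise ValidationError(f"row {row}: at least one of d13C, d238U must be present")


def _sniff_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate one of the four input tables.

    The delimiter (comma or tab) is auto-detected from the header line.
    """
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, encoding="utf-8")
    return validate_table(df, schema)


def write_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a record collection or derived series as delimited text."""
    df.to_csv(path, sep=sep, index=False, encoding="utf-8")


# Age partitioning --------------------------------------------------------

def partition_by_age(
    data, cutoff: float, on: str | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records or a labelled series at an age *cutoff*.

    Every element is assigned to exactly one side.  The comparison value is,
    in order of preference: the column named by *on*; a ``label`` column; an
    ``age`` column; otherwise the midpoint of ``(max_age, min_age)``.  An
    element whose comparison value equals the cutoff goes to the **older**
    side, matching the field's ``>cutoff`` phrasing for pre-excursion
    subsets.

    Returns ``(older, younger)``.
    """
    df = pd.DataFrame(data)
    if df.empty:
        return df.copy(), df.copy()
    if on is None:
        if "label" in df.columns:
            on_vals = df["label"]
        elif "age" in df.columns:
            on_vals = df["age"]
        elif {"max_age", "min_age"}.issubset(df.columns):
            on_vals = (df["max_age"] + df["min_age"]) / 2.0
        else:
            raise SchemaError("no age-like column found; pass `on=` explicitly")
    else:
        on_vals = df[on]
    older_mask = on_vals >= cutoff
    return df[older_mask].copy(), df[~older_mask].copy()


# Time grid ---------------------------------------------------------------

_CONVENTIONS = {
    # label L spans (L + older_offset, L - younger_offset), ages in Ma
    "printed_example": (0.4, 0.5),
    "symmetric_1ma": (0.5, 0.5),
}


@dataclass(frozen=True)
class TimeGrid:
    """Shared binning convention for the whole pipeline.

    Moving windows are labelled in Ma and stepped by ``step`` (default
    100 ka).  Under the default ``printed_example`` convention the window
    labelled ``L`` spans ``(L + 0.4, L - 0.5)`` Ma -- e.g. label 570.5
    covers 570.9 to 570.0 Ma -- so consecutive windows overlap by
    span − step.  ``symmetric_1ma`` swaps in a symmetric (L + 0.5, L − 0.5)
    span.  Rock flux is accumulated on a finer half-open grid of
    ``flux_bin``-wide bins (default 50 ka).
    """

    oldest: float = 580.0
    youngest: float = 510.0
    step: float = 0.1
    flux_bin: float = 0.05
    window_convention: str = "printed_example"

    def __post_init__(self):
        if not self.oldest > self.youngest:
            raise ValueError("oldest must exceed youngest")
        if self.step <= 0 or self.flux_bin <= 0:
            raise ValueError("step and flux_bin must be positive")
        if self.window_convention not in _CONVENTIONS:
            raise ValueError(
                f"unknown window_convention {self.window_convention!r}; "
                f"expected one of {sorted(_CONVENTIONS)}"
            )

    @property
    def window_span(self) -> float:
        older_off, younger_off = _CONVENTIONS[self.window_convention]
        return older_off + younger_off

    def windows(self) -> pd.DataFrame:
        """Ordered (old → young) moving windows: label, older, younger, span.

        Integer tick arithmetic (1 tick = 1 ka) keeps labels and edges exact
        on the printed grid.
        """
        older_off, younger_off = _CONVENTIONS[self.window_convention]
        o_ticks = round(older_off * 1000)
        y_ticks = round(younger_off * 1000)
        step_ticks = round(self.step * 1000)
        first = round(self.oldest * 1000) - o_ticks
        last = round(self.youngest * 1000) + y_ticks
        if first < last:
            raise ValueError("grid too short for a single window")
        ticks = np.arange(first, last - 1, -step_ticks)
        return pd.DataFrame(
            {
                "label": ticks / 1000.0,
                "older": (ticks + o_ticks) / 1000.0,
                "younger": (ticks - y_ticks) / 1000.0,
                "span": self.window_span,
            }
        )

    def flux_bins(self) -> tuple[np.ndarray, np.ndarray]:
        """Half-open 50-ka bins ``[older, younger)`` covering the grid.

        Returns ``(older_edges, younger_edges)`` ordered old → young.
        """
        step_ticks = round(self.flux_bin * 1000)
        edges = np.arange(
            round(self.oldest * 1000), round(self.youngest * 1000) - 1, -step_ticks
        )
        return edges[:-1] / 1000.0, edges[1:] / 1000.0
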