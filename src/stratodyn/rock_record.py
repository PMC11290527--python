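"""Rock-unit volume/area flux budgeting on the 50-ka bin grid.

A rock unit's preserved volume is ``area (km²) × mean thickness (km)``.
Deposition is assumed continuous over the unit's age span, so the volume is
spread uniformly in time and apportioned to 50-ka bins by proportional
overlap.  Partial overlap with a bin receives a proportional share; a unit
boundary exactly on a grid line contributes only to the older bin (the bin
grid is half-open, ``[older, younger)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model_io import (
    DEPTH_BEARING_GROUPS,
    NONMARINE_GROUPS,
    TimeGrid,
    ValidationError,
)

__all__ = [
    "FluxSeries",
    "AreaSeries",
    "class_key",
    "marine_nonevaporitic_mask",
    "compute_volume_flux",
    "lithofacies_percentages",
    "compute_area_series",
    "leave_region_out",
    "normalize_to_unit_max",
    "AFFINITY_CLASS_KEYS",
]

#: Map from fossil lithology affinities to the lithofacies class keys that
#: host them (shallow + mid depths pooled, as in the affinity vocabulary).
AFFINITY_CLASS_KEYS = {
    "shallow_mid_siliciclastic": (
        "siliciclastic:shallow_inner_shelf",
        "siliciclastic:mid_outer_shelf_upper_slope",
    ),
    "deep_siliciclastic": ("siliciclastic:lower_slope_basinal",),
    "shallow_mid_limestone": (
        "limestone:shallow_inner_shelf",
        "limestone:mid_outer_shelf_upper_slope",
    ),
    "shallow_mid_dolostone": (
        "dolostone:shallow_inner_shelf",
        "dolostone:mid_outer_shelf_upper_slope",
    ),
}


def class_key(group: str, depth: str) -> str:
    """Compact lithofacies identifier, e.g. ``siliciclastic:lower_slope_basinal``."""
    if group in DEPTH_BEARING_GROUPS:
        return f"{group}:{depth}"
    return group


def marine_nonevaporitic_mask(
    units: pd.DataFrame,
    include_phosphorite: bool = True,
    include_diamictite: bool = True,
) -> pd.Series:
    """Boolean mask of units in the marine nonevaporitic universe.

    Whether phosphorite and diamictite belong in that universe is not fixed
    by convention; both are included by default and togglable.
    """
    mask = units["marine"] & ~units["group"].isin(NONMARINE_GROUPS)
    if not include_phosphorite:
        mask &= units["group"] != "phosphorite"
    if not include_diamictite:
        mask &= units["group"] != "diamictite"
    return mask


@dataclass
class FluxSeries:
    """Per-bin volume flux (km³ per 50-ka bin), with partitions.

    ``by_class`` and ``by_region`` are bin × key frames whose row sums equal
    ``total`` up to numerical tolerance.
    """

    bin_older: np.ndarray
    bin_younger: np.ndarray
    total: np.ndarray
    by_class: pd.DataFrame
    by_region: pd.DataFrame
    class_marine: dict = field(default_factory=dict)

    @property
    def bin_mid(self) -> np.ndarray:
        return (self.bin_older + self.bin_younger) / 2.0

    def class_subtotal(self, keys) -> np.ndarray:
        """Summed volume over a set of lithofacies class keys."""
        present = [k for k in keys if k in self.by_class.columns]
        if not present:
            return np.zeros_like(self.total)
        return self.by_class[present].to_numpy().sum(axis=1)


@dataclass
class AreaSeries:
    """Per-bin marine depositional area (km²) and nondeposition fraction.

    ``by_region`` is a bin × region presence table; ``class_presence`` maps a
    lithofacies class key to its own bin × region presence table so that
    pooled class areas never double-count a region.
    """

    bin_older: np.ndarray
    bin_younger: np.ndarray
    area: np.ndarray
    nondeposition_fraction: np.ndarray
    by_region: pd.DataFrame
    region_areas: dict = field(default_factory=dict)
    class_presence: dict = field(default_factory=dict)

    @property
    def bin_mid(self) -> np.ndarray:
        return (self.bin_older + self.bin_younger) / 2.0

    def class_subtotal(self, keys) -> np.ndarray:
        """Area of regions hosting any unit of the given lithofacies classes."""
        present = [k for k in keys if k in self.class_presence]
        if not present:
            return np.zeros_like(self.area)
        pooled = None
        for k in present:
            tbl = self.class_presence[k]
            pooled = tbl if pooled is None else (pooled | tbl)
        weights = np.array([self.region_areas[r] for r in pooled.columns])
        return pooled.to_numpy() @ weights


def _overlap_matrix(units: pd.DataFrame, grid: TimeGrid) -> tuple[np.ndarray, ...]:
    bo, by = grid.flux_bins()
    base = units["base_age"].to_numpy(float)[:, None]
    top = units["top_age"].to_numpy(float)[:, None]
    ov = np.clip(np.minimum(base, bo[None, :]) - np.maximum(top, by[None, :]), 0.0, None)
    return bo, by, ov


def compute_volume_flux(units: pd.DataFrame, grid: TimeGrid) -> FluxSeries:
    """Bin rock-unit volumes onto the 50-ka grid.

    Volume is conserved: each unit's allocations sum to area × thickness
    (thickness converted m → km) to within floating-point accuracy.
    """
    units = units.reset_index(drop=True)
    duration = units["base_age"] - units["top_age"]
    if (duration <= 0).any():
        uid = units.loc[duration.le(0).idxmax(), "unit_id"]
        raise ValidationError(f"unit {uid!r} has non-positive duration")
    volume = units["area"].to_numpy(float) * units["mean_thickness"].to_numpy(float) / 1000.0
    rate = volume / duration.to_numpy(float)  # km³ per Ma
    bo, by, ov = _overlap_matrix(units, grid)
    alloc = rate[:, None] * ov  # unit × bin volumes

    keys = [class_key(g, d) for g, d in zip(units["group"], units["depth"])]
    alloc_df = pd.DataFrame(alloc)
    by_class = alloc_df.groupby(pd.Series(keys), sort=True).sum().T
    by_region = alloc_df.groupby(units["region"], sort=True).sum().T
    class_marine = {}
    for k, marine, grp in zip(keys, units["marine"], units["group"]):
        class_marine[k] = bool(marine) and grp not in NONMARINE_GROUPS
    return FluxSeries(
        bin_older=bo,
        bin_younger=by,
        total=alloc.sum(axis=0),
        by_class=by_class,
        by_region=by_region,
        class_marine=class_marine,
    )


def lithofacies_percentages(
    flux: FluxSeries,
    universe: list[str] | None = None,
    include_phosphorite: bool = True,
    include_diamictite: bool = True,
) -> pd.DataFrame:
    """Per-bin percentage of marine nonevaporitic volume by lithofacies class.

    Evaporitic and nonmarine classes are excluded from numerator and
    denominator.  Bins with zero denominator are missing (NaN), not zero.
    """
    if universe is None:
        universe = [k for k, marine in flux.class_marine.items() if marine]
        if not include_phosphorite:
            universe = [k for k in universe if k != "phosphorite"]
        if not include_diamictite:
            universe = [k for k in universe if k != "diamictite"]
    cols = [c for c in flux.by_class.columns if c in set(universe)]
    sub = flux.by_class[cols]
    denom = sub.sum(axis=1)
    pct = sub.div(denom.where(denom > 0), axis=0) * 100.0
    return pct


def compute_area_series(
    units: pd.DataFrame,
    region_areas: dict[str, float],
    grid: TimeGrid,
    include_phosphorite: bool = True,
    include_diamictite: bool = True,
) -> AreaSeries:
    """Marine depositional area per 50-ka bin, presence/absence style.

    A region contributes its full terrane area to every bin overlapped by at
    least one of its marine nonevaporitic units; the nondeposition fraction
    is the complementary share of total terrane area.
    """
    unknown = set(units["region"]) - set(region_areas)
    if unknown:
        raise ValidationError(f"unit(s) reference unknown region(s): {sorted(unknown)}")
    units = units.reset_index(drop=True)
    mask = marine_nonevaporitic_mask(units, include_phosphorite, include_diamictite)
    marine_units = units[mask].reset_index(drop=True)
    bo, by = grid.flux_bins()
    total_area = float(sum(region_areas.values()))
    n_bins = bo.size

    region_names = sorted(region_areas)
    covered = pd.DataFrame(False, index=range(n_bins), columns=region_names)
    class_presence: dict[str, pd.DataFrame] = {}
    if not marine_units.empty:
        _, _, ov = _overlap_matrix(marine_units, grid)
        present = ov > 0.0  # unit × bin
        for region, rows in marine_units.groupby("region").groups.items():
            covered[region] = present[np.asarray(rows)].any(axis=0)
        keys = [
            class_key(g, d) for g, d in zip(marine_units["group"], marine_units["depth"])
        ]
        for key in sorted(set(keys)):
            rows = np.array([i for i, k in enumerate(keys) if k == key])
            tbl = pd.DataFrame(False, index=range(n_bins), columns=region_names)
            for region, rr in marine_units.iloc[rows].groupby("region").groups.items():
                tbl[region] = present[np.asarray(rr)].any(axis=0)
            class_presence[key] = tbl

    area = covered.to_numpy() @ np.array([region_areas[r] for r in region_names])
    frac = (total_area - area) / total_area
    return AreaSeries(
        bin_older=bo,
        bin_younger=by,
        area=area,
        nondeposition_fraction=frac,
        by_region=covered,
        region_areas=dict(region_areas),
        class_presence=class_presence,
    )


def leave_region_out(
    units: pd.DataFrame, occurrences: pd.DataFrame | None, region: str
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Drop every record from *region* (sensitivity re-runs compose on this)."""
    in_units = (units["region"] == region).any() if units is not None else False
    in_occ = (
        occurrences is not None and (occurrences["region"] == region).any()
    )
    if not in_units and not in_occ:
        raise KeyError(f"region {region!r} not present in data")
    units_out = units[units["region"] != region].reset_index(drop=True)
    occ_out = None
    if occurrences is not None:
        occ_out = occurrences[occurrences["region"] != region].reset_index(drop=True)
    return units_out, occ_out


def normalize_to_unit_max(values) -> np.ndarray:
    """Scale a series so its maximum is 1; missing values stay missing."""
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    if not finite.any():
        raise ValueError("cannot normalize an empty/all-missing series")
    m = arr[finite].max()
    if m <= 0:
        raise ValueError("cannot normalize a series with non-positive maximum")
    return arr / m
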