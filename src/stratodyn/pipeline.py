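"""End-to-end orchestration: replicates → diversity → rock flux → correlations.

This module glues the library together for the command-line interface and
for scripted reproduction runs.  Everything here is a thin composition of
the public functions in the sibling modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import (
    age_resampling,
    correlation_stats,
    diversity_dynamics,
    rock_record,
    sampling_intensity,
)
from .data_model_io import BACE_ONSET_MA, TimeGrid
from .rock_record import AFFINITY_CLASS_KEYS

__all__ = ["PipelineResult", "run_pipeline", "rock_window_series"]


@dataclass
class PipelineResult:
    windows: pd.DataFrame
    diversity: pd.DataFrame  # replicate summary per window
    flux_bins: pd.DataFrame  # 50-ka bin table
    rock_windows: pd.DataFrame  # window-aggregated rock series
    intensity: pd.DataFrame
    correlations: pd.DataFrame
    geochem_correlations: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def rock_window_series(
    units: pd.DataFrame,
    region_areas: dict[str, float],
    grid: TimeGrid,
    windows: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """50-ka flux/area bin table plus its window-mean aggregation.

    Volume and area series cover the marine nonevaporitic universe in total
    and split by the lithology affinities that host fossils.
    """
    flux = rock_record.compute_volume_flux(units, grid)
    area = rock_record.compute_area_series(units, region_areas, grid)
    marine_keys = [k for k, m in flux.class_marine.items() if m]

    bin_cols = {
        "bin_older": flux.bin_older,
        "bin_younger": flux.bin_younger,
        "vol_all": flux.class_subtotal(marine_keys),
        "area_all": area.area,
        "nondeposition_fraction": area.nondeposition_fraction,
    }
    for aff, keys in AFFINITY_CLASS_KEYS.items():
        bin_cols[f"vol_{aff}"] = flux.class_subtotal(keys)
        bin_cols[f"area_{aff}"] = area.class_subtotal(keys)
    # pooled carbonate (limestone + dolostone) convenience series
    carb_keys = AFFINITY_CLASS_KEYS["shallow_mid_limestone"] + AFFINITY_CLASS_KEYS[
        "shallow_mid_dolostone"
    ]
    bin_cols["vol_shallow_mid_carbonate"] = flux.class_subtotal(carb_keys)
    bin_cols["area_shallow_mid_carbonate"] = area.class_subtotal(carb_keys)
    bins = pd.DataFrame(bin_cols)

    win_cols = {"label": windows["label"].to_numpy()}
    for col in bins.columns:
        if col.startswith("bin_"):
            continue
        win_cols[col] = correlation_stats.bins_to_windows(
            flux.bin_older, flux.bin_younger, bins[col].to_numpy(), windows
        )
    return bins, pd.DataFrame(win_cols)


def run_pipeline(
    occurrences: pd.DataFrame,
    units: pd.DataFrame,
    surfaces: pd.DataFrame | None = None,
    geochem: pd.DataFrame | None = None,
    grid: TimeGrid | None = None,
    n_replicates: int = 100,
    master_seed: int = 0,
    bace_cutoff: float = BACE_ONSET_MA,
    region_areas: dict[str, float] | None = None,
    exclude_regions: tuple[str, ...] = (),
    filters: age_resampling.DiversityFilters = age_resampling.DEFAULT_FILTERS,
) -> PipelineResult:
    """Run the full analysis and return every derived table."""
    grid = grid or TimeGrid()
    for region in exclude_regions:
        units, occurrences = rock_record.leave_region_out(units, occurrences, region)
        if surfaces is not None:
            surfaces = surfaces[surfaces["region"] != region].reset_index(drop=True)
    if region_areas is None:
        region_areas = units.groupby("region")["area"].max().to_dict()

    windows = diversity_dynamics.build_windows(grid)
    replicates = age_resampling.generate_replicates(
        occurrences, n_replicates, master_seed, filters=filters
    )
    per_rep = [diversity_dynamics.diversity_series(rep, windows) for rep in replicates]
    summary = diversity_dynamics.aggregate_replicates(per_rep)

    bins, rock_win = rock_window_series(units, region_areas, grid, windows)

    labels = windows["label"].to_numpy(float)
    subsets = {
        "all": np.ones(labels.size, dtype=bool),
        f"pre-BACE >{bace_cutoff:g} Ma": labels >= bace_cutoff,
        f"post-BACE <{bace_cutoff:g} Ma": labels < bace_cutoff,
    }
    predictors = {
        c: rock_win[c].to_numpy()
        for c in rock_win.columns
        if c.startswith(("vol_", "area_"))
    }
    report = correlation_stats.correlation_report(
        labels, summary["richness_mean"].to_numpy(), predictors, subsets
    )

    if surfaces is not None:
        intensity = sampling_intensity.intensity_series(surfaces, windows)
        # raw mode only: differencing maximum-possible counts is meaningless
        intensity_report = correlation_stats.correlation_report(
            labels,
            summary["richness_mean"].to_numpy(),
            {"sampling_intensity": intensity["total"].to_numpy(float)},
            subsets,
            modes=("raw",),
        )
        report = pd.concat([report, intensity_report], ignore_index=True)
    else:
        intensity = pd.DataFrame(
            {"label": labels, "total": np.zeros(labels.size, dtype=int)}
        )

    geo_report = None
    if geochem is not None:
        rows = []
        for mode in ("raw_paired", "moving_mean_vs_mean", "moving_mean_vs_min"):
            try:
                c_vals, u_vals = correlation_stats.pair_geochem(geochem, mode)
            except ValueError:
                continue
            res = correlation_stats.spearman(c_vals, u_vals, mode="raw", subset=mode)
            rows.append({"pairing": mode, "mode": "raw", "rho": res.rho,
                         "p_value": res.p_value, "n": res.n})
            if c_vals.size >= 4:
                res_d = correlation_stats.spearman(
                    correlation_stats.first_differences(c_vals),
                    correlation_stats.first_differences(u_vals),
                    mode="first_difference", subset=mode,
                )
                rows.append({"pairing": mode, "mode": "first_difference",
                             "rho": res_d.rho, "p_value": res_d.p_value, "n": res_d.n})
        geo_report = pd.DataFrame(rows)

    return PipelineResult(
        windows=windows,
        diversity=summary,
        flux_bins=bins,
        rock_windows=rock_win,
        intensity=intensity,
        correlations=report,
        geochem_correlations=geo_report,
    )
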