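"""Moving-window richness, boundary-crosser counts, and per-capita rates.

Windows follow the grid convention in :class:`~stratodyn.data_model_io.TimeGrid`:
the window labelled ``L`` spans ``(L + 0.4, L - 0.5)`` Ma by default, so
label 570.5 covers 570.9–570.0 Ma.  A taxon's realized range ``[lad, fad]``
is intersected with windows as a closed interval.

Edge rules (used consistently by richness and the crosser counts):

* crosses the older edge ``o``  ⇔  ``fad >= o`` and ``lad < o``
* crosses the younger edge ``y``  ⇔  ``lad <= y`` and ``fad > y``

The four Foote classes partition the taxa present in a window:
``N_bt`` crosses both edges, ``N_bL`` only the older (bottom) edge,
``N_Ft`` only the younger (top) edge, ``N_FL`` is confined to the window.
Per-capita rates per Ma over a window of span ``dt``:

    p = ln((N_bt + N_Ft) / N_bt) / dt        (origination)
    q = ln((N_bt + N_bL) / N_bt) / dt        (extinction)

Both are missing (NaN) when no taxon ranges through (``N_bt = 0``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model_io import TimeGrid
from .rock_record import normalize_to_unit_max

__all__ = [
    "build_windows",
    "richness_per_window",
    "boundary_crossers",
    "foote_rates",
    "diversity_series",
    "aggregate_replicates",
    "genus_density",
    "RICHNESS_TRUNCATION_MA",
    "EXTINCTION_TRUNCATION_MA",
]

#: Youngest window label (Ma) for which richness is reported; younger bins
#: under-sample true ranges (no full occurrence coverage there).
RICHNESS_TRUNCATION_MA = 522.0
#: Youngest window label (Ma) for which the extinction rate is reported;
#: ranges truncated by the edge of the data would inflate q beyond this.
EXTINCTION_TRUNCATION_MA = 530.0


def build_windows(grid: TimeGrid) -> pd.DataFrame:
    """Ordered old→young moving windows (label, older, younger, span)."""
    return grid.windows()


def _edges(windows: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    return windows["older"].to_numpy(float), windows["younger"].to_numpy(float)


def richness_per_window(ranges: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    """Range-through richness: taxa whose closed [lad, fad] meets each window."""
    o, y = _edges(windows)
    if ranges.empty:
        return np.zeros(len(windows), dtype=int)
    fad = ranges["fad"].to_numpy(float)[:, None]
    lad = ranges["lad"].to_numpy(float)[:, None]
    inter = (fad >= y[None, :]) & (lad <= o[None, :])
    return inter.sum(axis=0)


def boundary_crossers(ranges: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Foote boundary-crosser bookkeeping per window (N_bt, N_bL, N_Ft, N_FL)."""
    o, y = _edges(windows)
    n_win = len(windows)
    if ranges.empty:
        zeros = np.zeros(n_win, dtype=int)
        return pd.DataFrame(
            {"label": windows["label"], "N_bt": zeros, "N_bL": zeros,
             "N_Ft": zeros, "N_FL": zeros}
        )
    fad = ranges["fad"].to_numpy(float)[:, None]
    lad = ranges["lad"].to_numpy(float)[:, None]
    ob, yb = o[None, :], y[None, :]
    cross_o = (fad >= ob) & (lad < ob)
    cross_y = (lad <= yb) & (fad > yb)
    inter = (fad >= yb) & (lad <= ob)
    return pd.DataFrame(
        {
            "label": windows["label"].to_numpy(),
            "N_bt": (cross_o & cross_y).sum(axis=0),
            "N_bL": (cross_o & ~cross_y).sum(axis=0),
            "N_Ft": (~cross_o & cross_y).sum(axis=0),
            "N_FL": (inter & ~cross_o & ~cross_y).sum(axis=0),
        }
    )


def foote_rates(counts: pd.DataFrame, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-capita origination (p) and extinction (q) rates per Ma.

    Rates are NaN where ``N_bt = 0`` (undefined, not zero).
    """
    if dt <= 0:
        raise ValueError("window span dt must be positive")
    nbt = counts["N_bt"].to_numpy(float)
    nft = counts["N_Ft"].to_numpy(float)
    nbl = counts["N_bL"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(nbt > 0, np.log((nbt + nft) / nbt) / dt, np.nan)
        q = np.where(nbt > 0, np.log((nbt + nbl) / nbt) / dt, np.nan)
    return p, q


def diversity_series(
    ranges: pd.DataFrame,
    windows: pd.DataFrame,
    richness_truncation: float | None = RICHNESS_TRUNCATION_MA,
    extinction_truncation: float | None = EXTINCTION_TRUNCATION_MA,
) -> pd.DataFrame:
    """Per-window richness and turnover rates for one realized range set.

    Origination is reported over the full grid; extinction and richness are
    masked (NaN) younger than their truncation labels.
    """
    counts = boundary_crossers(ranges, windows)
    dt = float(windows["span"].iloc[0]) if len(windows) else 1.0
    p, q = foote_rates(counts, dt)
    richness = richness_per_window(ranges, windows).astype(float)
    labels = windows["label"].to_numpy(float)
    if richness_truncation is not None:
        richness = np.where(labels >= richness_truncation, richness, np.nan)
    if extinction_truncation is not None:
        q = np.where(labels >= extinction_truncation, q, np.nan)
    return pd.DataFrame({"label": labels, "richness": richness, "p": p, "q": q})


def aggregate_replicates(series: list[pd.DataFrame]) -> pd.DataFrame:
    """Element-wise mean/min/max of richness, p and q across replicates.

    Missing values are ignored pairwise; a window missing in every replicate
    stays missing.  All replicates must share the window grid.
    """
    if not series:
        raise ValueError("need at least one replicate")
    labels = series[0]["label"].to_numpy()
    for s in series[1:]:
        if len(s) != len(labels) or not np.array_equal(s["label"].to_numpy(), labels):
            raise ValueError("replicates are on mismatched window grids")
    out = {"label": labels}
    for stat in ("richness", "p", "q"):
        stack = np.vstack([s[stat].to_numpy(float) for s in series])
        with np.errstate(invalid="ignore"):
            all_nan = np.isnan(stack).all(axis=0)
            mean = np.where(all_nan, np.nan, np.nanmean(np.where(all_nan, 0.0, stack), axis=0))
            mn = np.where(all_nan, np.nan, np.nanmin(np.where(all_nan, np.inf, stack), axis=0))
            mx = np.where(all_nan, np.nan, np.nanmax(np.where(all_nan, -np.inf, stack), axis=0))
        out[f"{stat}_mean"] = mean
        out[f"{stat}_min"] = mn
        out[f"{stat}_max"] = mx
    return pd.DataFrame(out)


def genus_density(
    richness, rock, normalize: bool = False
) -> np.ndarray:
    """Richness divided by a rock quantity on the same window grid.

    Windows with zero or missing rock quantity are missing (and excluded
    from the unit-max normalization when ``normalize=True``).
    """
    r = np.asarray(richness, dtype=float)
    k = np.asarray(rock, dtype=float)
    if r.shape != k.shape:
        raise ValueError("richness and rock series are on mismatched grids")
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(np.isfinite(k) & (k > 0), r / k, np.nan)
    if normalize:
        dens = normalize_to_unit_max(dens)
    return dens
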