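"""Smoothing, first differences, Spearman correlation, and series pairing.

Monotonic association between series is measured with Spearman's rank
correlation on average ranks (ties share the mean rank); the p-value uses
the large-sample t approximation with n − 2 degrees of freedom.  Because
moving-window averages are autoregressive, the same test is also applied to
first differences of window series.

Isotope series (δ¹³C_carb, δ²³⁸U_carb) are compared either raw on paired
samples, or after k-point moving smoothing (moving mean for δ¹³C, moving
mean or moving minimum for δ²³⁸U — the minimum tracks the reliable baseline
through the gappy uranium record), pairing smoothed points by nearest age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "moving_stat",
    "first_differences",
    "spearman",
    "align_windows",
    "bins_to_windows",
    "pair_geochem",
    "correlation_report",
]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    mode: str = "raw"
    subset: str = "all"


def moving_stat(ages, values, k: int, stat: str = "mean") -> tuple[np.ndarray, np.ndarray]:
    """k-point moving statistic over consecutive age-ordered samples.

    Input must be ordered old → young (descending age).  Each run of k
    consecutive samples is reported at the mean age of the run; output
    length is ``n − k + 1`` (empty when ``n < k``).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if stat not in ("mean", "min"):
        raise ValueError("stat must be 'mean' or 'min'")
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if np.any(np.diff(ages) > 0):
        raise ValueError("samples must be ordered old -> young (descending age)")
    if ages.size < k:
        return np.empty(0), np.empty(0)
    win_a = np.lib.stride_tricks.sliding_window_view(ages, k)
    win_v = np.lib.stride_tricks.sliding_window_view(values, k)
    out = win_v.mean(axis=1) if stat == "mean" else win_v.min(axis=1)
    return win_a.mean(axis=1), out


def first_differences(values) -> np.ndarray:
    """Old→young first differences ``d_i = x_{i+1} − x_i``; NaN propagates."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values to difference")
    return arr[1:] - arr[:-1]


def spearman(x, y, mode: str = "raw", subset: str = "all") -> CorrelationResult:
    """Spearman rank correlation after pairwise deletion of missing values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.unique(x[ok]).size < 2 or np.unique(y[ok]).size < 2:
        # rank correlation is undefined for a constant margin
        return CorrelationResult(rho=np.nan, p_value=np.nan, n=n,
                                 mode=mode, subset=subset)
    rho, p = stats.spearmanr(x[ok], y[ok])
    return CorrelationResult(rho=float(rho), p_value=float(p), n=n,
                             mode=mode, subset=subset)


def align_windows(
    labels_a, values_a, labels_b, values_b
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pair two window series by shared labels (old → young).

    Returns ``(labels, a, b)``; raises if the label sets are disjoint.
    """
    la = np.asarray(labels_a, dtype=float)
    lb = np.asarray(labels_b, dtype=float)
    common = np.intersect1d(la, lb)
    if common.size == 0:
        raise ValueError("window series share no labels")
    common = common[::-1]  # old -> young
    a = pd.Series(np.asarray(values_a, dtype=float), index=la).loc[common].to_numpy()
    b = pd.Series(np.asarray(values_b, dtype=float), index=lb).loc[common].to_numpy()
    return common, a, b


def bins_to_windows(
    bin_older, bin_younger, values, windows: pd.DataFrame
) -> np.ndarray:
    """Average fine (50-ka) bins within each moving window.

    A bin belongs to a window when its midpoint falls inside the window
    span; windows covering no bin are missing.
    """
    mid = (np.asarray(bin_older, float) + np.asarray(bin_younger, float)) / 2.0
    o = windows["older"].to_numpy(float)
    y = windows["younger"].to_numpy(float)
    vals = np.asarray(values, dtype=float)
    inside = ((mid[:, None] <= o[None, :]) & (mid[:, None] >= y[None, :])).astype(float)
    counts = inside.sum(axis=0)
    if counts.max() == 0:
        raise ValueError("bin grid and window grid are disjoint")
    sums = np.where(np.isnan(vals), 0.0, vals) @ inside
    valid = (~np.isnan(vals)).astype(float) @ inside
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(valid > 0, sums / valid, np.nan)
    return out


def pair_geochem(
    samples: pd.DataFrame,
    mode: str = "raw_paired",
    k: int = 10,
    max_age_gap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair δ¹³C and δ²³⁸U series for correlation.

    Modes: ``raw_paired`` pairs same-sample values (rows flagged
    ``paired`` with both isotopes present); ``moving_mean_vs_mean`` and
    ``moving_mean_vs_min`` smooth each isotope's own age-ordered series
    (δ¹³C by k-point mean; δ²³⁸U by k-point mean or minimum) and pair the
    smoothed points by nearest age within ``max_age_gap`` Ma.
    """
    if mode == "raw_paired":
        sel = samples[samples["paired"] & samples["d13C"].notna() & samples["d238U"].notna()]
        if sel.empty:
            raise ValueError("no qualifying paired samples")
        sel = sel.sort_values("age", ascending=False)
        return sel["d13C"].to_numpy(float), sel["d238U"].to_numpy(float)
    if mode not in ("moving_mean_vs_mean", "moving_mean_vs_min"):
        raise ValueError(f"unknown mode {mode!r}")
    c = samples[samples["d13C"].notna()].sort_values("age", ascending=False)
    u = samples[samples["d238U"].notna()].sort_values("age", ascending=False)
    if len(c) < k or len(u) < k:
        raise ValueError(f"k={k} exceeds the length of an isotope series")
    ca, cv = moving_stat(c["age"], c["d13C"], k, "mean")
    u_stat = "mean" if mode == "moving_mean_vs_mean" else "min"
    ua, uv = moving_stat(u["age"], u["d238U"], k, u_stat)
    # nearest-age pairing of the two smoothed series
    order = np.argsort(ua)
    idx = np.searchsorted(ua[order], ca)
    idx = np.clip(idx, 1, ua.size - 1)
    left, right = order[idx - 1], order[idx]
    pick = np.where(np.abs(ua[left] - ca) <= np.abs(ua[right] - ca), left, right)
    gap = np.abs(ua[pick] - ca)
    keep = gap <= max_age_gap
    if not keep.any():
        raise ValueError(f"no smoothed pairs within {max_age_gap} Ma of each other")
    return cv[keep], uv[pick[keep]]


def correlation_report(
    labels,
    response: np.ndarray,
    predictors: dict[str, np.ndarray],
    subsets: dict[str, np.ndarray] | None = None,
    modes: tuple[str, ...] = ("raw", "first_difference"),
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Tidy table of Spearman tests: one row per (predictor, subset, mode).

    *subsets* maps a label (e.g. ``"pre-BACE >535 Ma"``) to a boolean mask
    over the window labels; first differences are taken within each subset
    after masking.  Untestable combinations (too few complete pairs) are
    reported with missing rho/p and the pair count available.
    """
    labels = np.asarray(labels, dtype=float)
    if subsets is None:
        subsets = {"all": np.ones(labels.size, dtype=bool)}
    rows = []
    for subset_name, mask in subsets.items():
        r_sub = np.asarray(response, float)[mask]
        for pred_name, pred in predictors.items():
            p_sub = np.asarray(pred, float)[mask]
            for mode in modes:
                if mode == "raw":
                    xx, yy = r_sub, p_sub
                else:
                    if r_sub.size < 2:
                        continue
                    xx, yy = first_differences(r_sub), first_differences(p_sub)
                ok = np.isfinite(xx) & np.isfinite(yy)
                if ok.sum() < min_pairs:
                    rows.append(
                        {"subset": subset_name, "predictor": pred_name, "mode": mode,
                         "rho": np.nan, "p_value": np.nan, "n": int(ok.sum())}
                    )
                    continue
                res = spearman(xx, yy, mode=mode, subset=subset_name)
                rows.append(
                    {"subset": subset_name, "predictor": pred_name, "mode": mode,
                     "rho": res.rho, "p_value": res.p_value, "n": res.n}
                )
    return pd.DataFrame(rows)
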