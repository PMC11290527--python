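"""Moving-sum sampling-intensity series from fossiliferous surfaces.

Sampling intensity is the number of fossiliferous beds / bedding-plane
surfaces (or sites/sections, whatever one row of the surfaces table
represents) per moving window.  A surface whose permitted age interval spans
several windows is counted in **every** window it intersects, so the series
is the total maximum possible sampling intensity at any given time — the
appropriate reading for poorly constrained surfaces whose age is known only
to the duration of the host unit.

The surfaces table is expected to contain body-fossil records only
(trace-fossil-only surfaces are excluded at data preparation); unlike the
diversity filters, holdfast-only and taxonomically excluded body-fossil
records are retained here.

No first differences are offered for this series: when many surfaces are
stretched across their maximum possible range the differenced series is
artificially flattened around zero and is not meaningful.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["intensity_series"]


def intensity_series(surfaces: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Surfaces per window, broken down by age-constraint quality.

    A surface ``(max_age, min_age)`` is counted in every window whose closed
    span it intersects; a point-aged surface counts in every window
    containing that age.
    """
    labels = windows["label"].to_numpy(float)
    o = windows["older"].to_numpy(float)[None, :]
    y = windows["younger"].to_numpy(float)[None, :]
    n_win = labels.size
    if surfaces.empty:
        zeros = np.zeros(n_win, dtype=int)
        return pd.DataFrame(
            {"label": labels, "total": zeros,
             "well_constrained": zeros, "uncertain": zeros}
        )
    smax = surfaces["max_age"].to_numpy(float)[:, None]
    smin = surfaces["min_age"].to_numpy(float)[:, None]
    hits = (smax >= y) & (smin <= o)  # surface × window
    well = surfaces["constraint_quality"].to_numpy() == "well_constrained"
    return pd.DataFrame(
        {
            "label": labels,
            "total": hits.sum(axis=0),
            "well_constrained": hits[well].sum(axis=0),
            "uncertain": hits[~well].sum(axis=0),
        }
    )
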