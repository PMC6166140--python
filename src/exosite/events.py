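"""Fusion-event kinetics: binned frequencies and ring-positive fractions.

Live imaging scores each granule-fusion event by its time since
stimulation (on a 5-s frame grid over a 10-min movie) and by whether a
contractile actomyosin ring was recruited. These operations bin those
events over the 600-s window, report the percentage of ring-positive
events overall and per bin, and fit a logistic recruitment-probability
curve to the per-bin fractions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ACQUISITION_WINDOW_S",
    "event_frequency_histogram",
    "fraction_positive",
    "positive_fraction_timecourse",
    "fit_logistic_recruitment",
]

logger = logging.getLogger(__name__)

#: Events are scored over a 10-min (600 s) acquisition after stimulation.
ACQUISITION_WINDOW_S = 600.0


def _clean(events: pd.DataFrame) -> pd.DataFrame:
    for col in ("time_s", "ring_positive"):
        if col not in events.columns:
            raise ValueError(f"event table missing column {col!r}")
    in_range = (events["time_s"] >= 0) & (events["time_s"] <= ACQUISITION_WINDOW_S)
    n_rejected = int((~in_range).sum())
    if n_rejected:
        logger.warning("rejecting %d event(s) outside [0, %g] s", n_rejected, ACQUISITION_WINDOW_S)
    return events.loc[in_range]


def event_frequency_histogram(events: pd.DataFrame, bin_width_s: float = 50.0) -> pd.DataFrame:
    """Counts of ring-positive and ring-negative events per time bin.

    Bins are [0, w), [w, 2w), ... covering [0, 600] with the final bin
    closed at 600 s; events outside the window are rejected with a
    logged count. Totals are conserved over the retained events.
    """
    if bin_width_s <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width_s}")
    ev = _clean(events)
    edges = np.arange(0.0, ACQUISITION_WINDOW_S + bin_width_s / 2, bin_width_s)
    if edges[-1] < ACQUISITION_WINDOW_S:
        edges = np.append(edges, ACQUISITION_WINDOW_S)
    t = ev["time_s"].to_numpy(dtype=np.float64)
    pos = ev["ring_positive"].to_numpy(dtype=bool)
    n_pos, _ = np.histogram(t[pos], bins=edges)
    n_neg, _ = np.histogram(t[~pos], bins=edges)
    return pd.DataFrame(
        {
            "bin_start_s": edges[:-1],
            "bin_end_s": edges[1:],
            "n_positive": n_pos,
            "n_negative": n_neg,
        }
    )


def fraction_positive(events: pd.DataFrame, window_s: tuple[float, float] = (0.0, 600.0)) -> float:
    """Percentage of ring-positive events in a closed time window.

    NaN when the window holds no events. The window must lie within the
    600-s acquisition and have start < end.
    """
    start, end = float(window_s[0]), float(window_s[1])
    if start >= end:
        raise ValueError(f"window start must precede end, got {window_s}")
    if start < 0 or end > ACQUISITION_WINDOW_S:
        raise ValueError(f"window must lie within [0, {ACQUISITION_WINDOW_S}] s")
    ev = _clean(events)
    sel = (ev["time_s"] >= start) & (ev["time_s"] <= end)
    total = int(sel.sum())
    if total == 0:
        return float("nan")
    return 100.0 * float(ev.loc[sel, "ring_positive"].sum()) / total


def positive_fraction_timecourse(events: pd.DataFrame, bin_width_s: float = 50.0) -> pd.DataFrame:
    """Per-bin percentage of ring-positive events; NaN for empty bins."""
    hist = event_frequency_histogram(events, bin_width_s)
    total = hist["n_positive"] + hist["n_negative"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * hist["n_positive"] / total
    out = hist.copy()
    out["n_events"] = total
    out["pct_positive"] = pct.where(total > 0, np.nan)
    return out


def _logistic(t, p_start, p_end, midpoint, scale):
    return p_start + (p_end - p_start) / (1.0 + np.exp(-(t - midpoint) / scale))


def fit_logistic_recruitment(
    events: pd.DataFrame, bin_width_s: float = 50.0
) -> dict[str, float]:
    """Least-squares logistic fit to the per-bin positive fractions.

    Bins are weighted by their event counts. Returns the fitted
    parameters p_start, p_end (probabilities), midpoint_s and scale_s.
    """
    tc = positive_fraction_timecourse(events, bin_width_s)
    occupied = tc["n_events"] > 0
    t = (0.5 * (tc["bin_start_s"] + tc["bin_end_s"]))[occupied].to_numpy()
    frac = (tc["pct_positive"][occupied] / 100.0).to_numpy()
    w = tc["n_events"][occupied].to_numpy(dtype=np.float64)
    if t.size < 4:
        raise ValueError("need at least 4 occupied bins to fit a logistic")
    p0 = (max(frac[0], 0.01), min(max(frac[-1], 0.02), 0.99), 150.0, 60.0)
    popt, _ = curve_fit(
        _logistic,
        t,
        frac,
        p0=p0,
        sigma=1.0 / np.sqrt(w),
        bounds=([0.0, 0.0, 0.0, 1.0], [1.0, 1.0, ACQUISITION_WINDOW_S, ACQUISITION_WINDOW_S]),
        maxfev=20000,
    )
    return {"p_start": popt[0], "p_end": popt[1], "midpoint_s": popt[2], "scale_s": popt[3]}
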