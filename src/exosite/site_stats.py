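"""Per-well and per-condition statistics on segmented exocytic sites.

The statistical unit is the well: site counts and cell counts are summed
over a well's fields of view before any ratio is taken, site areas are
pooled within the well, and condition-level dispersion is reported as
mean +/- SEM over wells. Area distributions across conditions are
compared with the two-sample Kolmogorov-Smirnov statistic, and the
fraction of "large" sites (area strictly greater than 2 um^2, the
actomyosin-ring proxy) can be normalised to a control condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import kolmogorov

__all__ = [
    "LARGE_SITE_THRESHOLD_UM2",
    "WellSummary",
    "summarize_well",
    "proportion_large",
    "cumulative_area_distribution",
    "ks_two_sample",
    "normalize_to_control",
    "timecourse_counts",
    "condition_prop_large",
]

logger = logging.getLogger(__name__)

#: Sites with area strictly greater than this are "large" (ring-positive proxy).
LARGE_SITE_THRESHOLD_UM2 = 2.0


@dataclass(frozen=True)
class WellSummary:
    """Aggregates for one well: the sum of its fields of view."""

    well: str
    condition: str
    n_fields: int
    n_sites: int
    n_cells: int
    sites_per_cell: float  # NaN when the well has no cells
    median_area_um2: float  # NaN when the well has no sites
    prop_large: float  # NaN when the well has no sites

    def to_dict(self) -> dict:
        return {
            "well": self.well,
            "condition": self.condition,
            "n_fields": self.n_fields,
            "n_sites": self.n_sites,
            "n_cells": self.n_cells,
            "sites_per_cell": self.sites_per_cell,
            "median_area_um2": self.median_area_um2,
            "prop_large": self.prop_large,
        }


def proportion_large(
    areas: Sequence[float], threshold_um2: float = LARGE_SITE_THRESHOLD_UM2
) -> float:
    """Fraction of sites with area strictly greater than the threshold.

    An area exactly at the threshold counts as NOT large. Empty input
    gives NaN (a well with no sites has no defined proportion).
    """
    if threshold_um2 <= 0:
        raise ValueError(f"threshold must be positive, got {threshold_um2}")
    a = np.asarray(areas, dtype=np.float64)
    if a.size == 0:
        return float("nan")
    if (a < 0).any():
        raise ValueError("areas must be non-negative")
    return float(np.mean(a > threshold_um2))


def summarize_well(
    site_tables: Sequence[pd.DataFrame] | pd.DataFrame,
    cell_counts: Sequence[int],
    well: str = "",
    condition: str = "",
    threshold_um2: float = LARGE_SITE_THRESHOLD_UM2,
) -> WellSummary:
    """Summarise one well from its fields' site tables and cell counts.

    Counts are summed over fields before the sites-per-cell ratio is
    formed; the median is over the well's pooled site areas. A well with
    zero cells reports sites_per_cell as NaN rather than infinity.
    """
    if isinstance(site_tables, pd.DataFrame):
        pooled = site_tables
        if len(cell_counts) == 0:
            raise ValueError("need at least one field's cell count")
    else:
        site_tables = list(site_tables)
        if not site_tables:
            raise ValueError("need at least one field")
        if len(site_tables) != len(cell_counts):
            raise ValueError(
                f"{len(site_tables)} site tables but {len(cell_counts)} cell counts"
            )
        pooled = (
            pd.concat(site_tables, ignore_index=True)
            if site_tables
            else pd.DataFrame(columns=["area_um2"])
        )
    n_sites = int(len(pooled))
    n_cells = int(sum(cell_counts))
    areas = pooled["area_um2"].to_numpy(dtype=np.float64) if n_sites else np.array([])
    return WellSummary(
        well=well,
        condition=condition,
        n_fields=len(cell_counts),
        n_sites=n_sites,
        n_cells=n_cells,
        sites_per_cell=(n_sites / n_cells) if n_cells > 0 else float("nan"),
        median_area_um2=float(np.median(areas)) if n_sites else float("nan"),
        prop_large=proportion_large(areas, threshold_um2) if n_sites else float("nan"),
    )


def cumulative_area_distribution(areas: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """ECDF of site areas: (sorted unique support, cumulative fractions).

    Right-continuous step function; the final cumulative fraction is 1.
    """
    a = np.asarray(areas, dtype=np.float64)
    if a.size == 0:
        raise ValueError("cannot form an ECDF from an empty sample")
    support, counts = np.unique(a, return_counts=True)
    return support, np.cumsum(counts) / a.size


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value.

    D is the supremum distance between the two ECDFs, evaluated at all
    pooled sample points (which handles ties exactly). The p-value uses
    the asymptotic Kolmogorov distribution with effective sample size
    n*m/(n+m); it is approximate for small samples.
    """
    xa = np.sort(np.asarray(a, dtype=np.float64))
    xb = np.sort(np.asarray(b, dtype=np.float64))
    n, m = xa.size, xb.size
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([xa, xb])
    fa = np.searchsorted(xa, pooled, side="right") / n
    fb = np.searchsorted(xb, pooled, side="right") / m
    d = float(np.max(np.abs(fa - fb)))
    ne = n * m / (n + m)
    p = float(kolmogorov(np.sqrt(ne) * d))
    return d, min(max(p, 0.0), 1.0)


def normalize_to_control(
    treated_prop_large: Sequence[float], control_prop_large: Sequence[float]
) -> tuple[float, float]:
    """Ratio of mean large-site proportions, treated over control.

    Returns (ratio, propagated standard error) with first-order error
    propagation of the two per-well SEMs:
    se = ratio * sqrt((SEM_t/mean_t)^2 + (SEM_c/mean_c)^2).
    """
    t = np.asarray(treated_prop_large, dtype=np.float64)
    c = np.asarray(control_prop_large, dtype=np.float64)
    t = t[~np.isnan(t)]
    c = c[~np.isnan(c)]
    if t.size == 0 or c.size == 0:
        raise ValueError("both groups need at least one well with sites")
    mean_c = float(np.mean(c))
    if mean_c <= 0:
        raise ValueError("control mean proportion is zero; ratio undefined")
    mean_t = float(np.mean(t))
    ratio = mean_t / mean_c
    sem_t = float(np.std(t, ddof=1) / np.sqrt(t.size)) if t.size > 1 else 0.0
    sem_c = float(np.std(c, ddof=1) / np.sqrt(c.size)) if c.size > 1 else 0.0
    rel_t = (sem_t / mean_t) ** 2 if mean_t > 0 else 0.0
    se = ratio * np.sqrt(rel_t + (sem_c / mean_c) ** 2)
    return ratio, float(se)


def timecourse_counts(summaries: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM of per-well site counts at each fixation time.

    ``summaries`` needs columns time_min, well, n_sites. Returns one row
    per timepoint, sorted by time, with columns time_min, mean_sites,
    sem_sites, n_wells; a single-well timepoint reports SEM 0 and is
    identifiable by n_wells == 1.
    """
    required = {"time_min", "n_sites"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"summaries missing columns: {sorted(missing)}")
    rows = []
    for t, grp in summaries.groupby("time_min"):
        counts = grp["n_sites"].to_numpy(dtype=np.float64)
        sem = float(np.std(counts, ddof=1) / np.sqrt(counts.size)) if counts.size > 1 else 0.0
        rows.append(
            {
                "time_min": float(t),
                "mean_sites": float(np.mean(counts)),
                "sem_sites": sem,
                "n_wells": int(counts.size),
            }
        )
    return pd.DataFrame(rows).sort_values("time_min", ignore_index=True)


def condition_prop_large(
    well_summaries: Sequence[WellSummary] | pd.DataFrame,
) -> pd.DataFrame:
    """Per-condition mean +/- SEM of the per-well large-site proportion.

    Wells with no sites (NaN prop_large) are excluded, with the excluded
    count logged — a blank well carries no information about site size.
    """
    if isinstance(well_summaries, pd.DataFrame):
        df = well_summaries
    else:
        df = pd.DataFrame([w.to_dict() for w in well_summaries])
    n_excluded = int(df["prop_large"].isna().sum())
    if n_excluded:
        logger.info("condition_prop_large: excluding %d well(s) with no sites", n_excluded)
    df = df.dropna(subset=["prop_large"])
    rows = []
    for cond, grp in df.groupby("condition", sort=True):
        p = grp["prop_large"].to_numpy(dtype=np.float64)
        sem = float(np.std(p, ddof=1) / np.sqrt(p.size)) if p.size > 1 else 0.0
        rows.append(
            {
                "condition": cond,
                "mean_prop_large": float(np.mean(p)),
                "sem_prop_large": sem,
                "n_wells": int(p.size),
            }
        )
    return pd.DataFrame(rows, columns=["condition", "mean_prop_large", "sem_prop_large", "n_wells"])
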