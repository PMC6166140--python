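"""Synthetic plate generator with known ground truth.

Emulates the acquisition geometry of a 96-well endothelial exocytosis
screen: nine confocal fields of view per well, ~11.6 cells per field
(so a full 864-field dataset holds ~10 000 cells), a nuclear-stain
channel with disc-like nuclei, and a VWF channel in which each exocytic
site is an elliptical blob whose footprint area is drawn from a two-mode
log-normal mixture. The weight of the large-area mode stands in for the
probability that the fused granule recruited a contractile actomyosin
ring (which expels more cargo and leaves a larger antibody-retained
patch); it is a generator parameter, not a mechanistic model.

Blob rendering: each site carries a Gaussian intensity profile truncated
at half maximum, so its support is an ellipse of exactly the drawn area.
This gives the rendered site a well-defined physical footprint (the
conventional full-width-half-maximum area) that a global threshold
anywhere between background and the half-maximum level recovers, while
keeping the interior profile smooth and peaked at the ground-truth
centre pixel.

All randomness flows from explicit seeds; identical seeds give
bit-identical images, ground truth and event tables.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.stats import norm

from .segmentation import FieldImage

__all__ = [
    "ConditionSpec",
    "PlateLayout",
    "NoiseModel",
    "GroundTruth",
    "simulate_field",
    "simulate_plate",
    "simulate_timecourse",
    "simulate_fusion_events",
    "simulate_strings",
    "constant_rate",
    "ring_prob_constant",
    "ring_prob_logistic",
    "lognormal_lengths",
    "CELLS_PER_FIELD_DEFAULT",
]

#: 864 fields of view hold approximately 10 000 cells.
CELLS_PER_FIELD_DEFAULT = 10000.0 / 864.0

_KINETICS = ("fast_saturating", "linear")
_TIMECOURSE_MAX_MIN = 20.0

# Rendering constants (counts above background; 16-bit range).
SITE_AMPLITUDE = 2000.0
NUCLEUS_AMPLITUDE = 1200.0
NUCLEUS_RADIUS_UM = 4.0
SITE_PLACEMENT_RADIUS_UM = 10.0


@dataclass(frozen=True)
class ConditionSpec:
    """Secretagogue condition: how many sites, how big, how fast.

    site_rate_per_cell : expected exocytic sites per cell (Poisson).
    large_fraction : weight of the large-area mode of the site-area
        mixture; proxies the fraction of fusion events that recruit the
        actomyosin ring (~0.15 histamine, ~0.40 histamine/adrenalin/
        IBMX, ~0.65 PMA).
    small_mode / large_mode : (log-mean, log-sd) of the log-normal area
        modes in um^2. Calibration requirement: the small mode must lie
        at or below 2 um^2 and the large mode above it, each with
        probability >= 0.99, so that the ground-truth fraction of sites
        larger than 2 um^2 equals large_fraction.
    kinetics : "fast_saturating" (histamine-like, 1 - exp(-t/tau)) or
        "linear" (PMA-like) cumulative release over a 20-min window.
    """

    name: str
    site_rate_per_cell: float = 3.0
    large_fraction: float = 0.4
    small_mode: tuple[float, float] = (math.log(0.8), 0.3)
    large_mode: tuple[float, float] = (math.log(4.5), 0.25)
    kinetics: str = "fast_saturating"
    tau_min: float = 3.0

    def __post_init__(self) -> None:
        if self.site_rate_per_cell < 0:
            raise ValueError("site_rate_per_cell must be non-negative")
        if not 0.0 <= self.large_fraction <= 1.0:
            raise ValueError(f"large_fraction must be in [0,1], got {self.large_fraction}")
        for label, (mu, sd) in (("small_mode", self.small_mode), ("large_mode", self.large_mode)):
            if sd <= 0 or not math.isfinite(mu):
                raise ValueError(f"{label} must have finite log-mean and positive log-sd")
        if self.kinetics not in _KINETICS:
            raise ValueError(f"unknown kinetics label {self.kinetics!r}; expected one of {_KINETICS}")
        if self.tau_min <= 0:
            raise ValueError("tau_min must be positive")
        # Mode calibration against the 2 um^2 large-site boundary.
        p_small_below = norm.cdf((math.log(2.0) - self.small_mode[0]) / self.small_mode[1])
        p_large_above = norm.sf((math.log(2.0) - self.large_mode[0]) / self.large_mode[1])
        if p_small_below < 0.99:
            raise ValueError(
                f"small mode is not calibrated: P(area <= 2 um^2) = {p_small_below:.4f} < 0.99"
            )
        if p_large_above < 0.99:
            raise ValueError(
                f"large mode is not calibrated: P(area > 2 um^2) = {p_large_above:.4f} < 0.99"
            )


@dataclass(frozen=True)
class PlateLayout:
    """Wells, fields per well and field geometry of a simulated plate."""

    wells: tuple[tuple[str, ConditionSpec], ...]
    fields_per_well: int = 9
    cells_per_field: float = CELLS_PER_FIELD_DEFAULT
    field_shape: tuple[int, int] = (512, 688)  # (rows, cols) px
    pixel_size_um: float = 0.3

    def __post_init__(self) -> None:
        object.__setattr__(self, "wells", tuple((str(w), c) for w, c in self.wells))
        ids = [w for w, _ in self.wells]
        if len(set(ids)) != len(ids):
            dupes = sorted({w for w in ids if ids.count(w) > 1})
            raise ValueError(f"duplicate well ids: {dupes}")
        if self.fields_per_well <= 0:
            raise ValueError("fields_per_well must be positive")
        if self.cells_per_field < 0:
            raise ValueError("cells_per_field must be non-negative")
        if min(self.field_shape) <= 0:
            raise ValueError(f"field dimensions must be positive, got {self.field_shape}")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel size must be positive, got {self.pixel_size_um}")


@dataclass(frozen=True)
class NoiseModel:
    """Camera/background noise: smooth background plus shot and read noise.

    With every term zero the rendered image equals the noiseless
    rendering exactly (bit-identical uint16).
    """

    background: float = 200.0
    gradient_amplitude: float = 30.0
    shot_noise: bool = True
    read_noise_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.background < 0 or self.gradient_amplitude < 0 or self.read_noise_sd < 0:
            raise ValueError("noise parameters must be non-negative")

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(background=0.0, gradient_amplitude=0.0, shot_noise=False, read_noise_sd=0.0)


@dataclass
class GroundTruth:
    """Known truth behind rendered fields.

    nuclei : one row per nucleus (well, field, row, col in px).
    sites : one row per site (well, field, row, col px, area_um2,
        axis_major_um, axis_minor_um, orientation_rad, mode).
    """

    nuclei: pd.DataFrame
    sites: pd.DataFrame

    NUCLEI_COLUMNS = ["well", "field", "row", "col"]
    SITE_COLUMNS = [
        "well",
        "field",
        "row",
        "col",
        "area_um2",
        "axis_major_um",
        "axis_minor_um",
        "orientation_rad",
        "mode",
    ]

    @classmethod
    def empty(cls) -> "GroundTruth":
        return cls(
            nuclei=pd.DataFrame(columns=cls.NUCLEI_COLUMNS),
            sites=pd.DataFrame(columns=cls.SITE_COLUMNS),
        )

    @classmethod
    def concat(cls, parts: Iterable["GroundTruth"]) -> "GroundTruth":
        parts = list(parts)
        if not parts:
            return cls.empty()
        return cls(
            nuclei=pd.concat([p.nuclei for p in parts], ignore_index=True),
            sites=pd.concat([p.sites for p in parts], ignore_index=True),
        )


def field_seed(master_seed: int, well: str, field_index: int) -> np.random.SeedSequence:
    """Deterministic per-field seed derived from the master seed."""
    return np.random.SeedSequence(
        entropy=(int(master_seed), zlib.crc32(str(well).encode()), int(field_index))
    )


def _sample_nuclei(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    pixel_size_um: float,
    min_sep_um: float = 2.0 * NUCLEUS_RADIUS_UM,
) -> np.ndarray:
    """Dart-throwing placement of nucleus centres with a soft minimum separation."""
    margin = NUCLEUS_RADIUS_UM / pixel_size_um
    lo_r, hi_r = margin, shape[0] - 1 - margin
    lo_c, hi_c = margin, shape[1] - 1 - margin
    min_sep_px = min_sep_um / pixel_size_um
    centers: list[tuple[float, float]] = []
    for _ in range(n):
        for _attempt in range(50):
            r = rng.uniform(lo_r, hi_r)
            c = rng.uniform(lo_c, hi_c)
            if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep_px**2 for r0, c0 in centers):
                break
        centers.append((r, c))
    out = np.array(centers, dtype=np.float64).reshape(-1, 2)
    return np.round(out)  # snap to pixel centres


def _render_truncated_gaussian(
    canvas: np.ndarray,
    row: float,
    col: float,
    sigma_major_px: float,
    sigma_minor_px: float,
    theta: float,
    amplitude: float,
) -> None:
    """Add an elliptical Gaussian blob truncated at half maximum, in place."""
    r_half = sigma_major_px * math.sqrt(2.0 * math.log(2.0))
    pad = int(math.ceil(r_half)) + 2
    r0 = max(int(row) - pad, 0)
    r1 = min(int(row) + pad + 1, canvas.shape[0])
    c0 = max(int(col) - pad, 0)
    c1 = min(int(col) + pad + 1, canvas.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = rr - row
    dc = cc - col
    u = dr * math.cos(theta) + dc * math.sin(theta)
    v = -dr * math.sin(theta) + dc * math.cos(theta)
    q = (u / sigma_major_px) ** 2 + (v / sigma_minor_px) ** 2
    inside = q <= 2.0 * math.log(2.0)  # half-max contour
    blob = np.where(inside, amplitude * np.exp(-0.5 * q), 0.0)
    canvas[r0:r1, c0:c1] += blob


def _sample_site_geometry(
    rng: np.random.Generator, condition: ConditionSpec, n_sites: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw (area_um2, axis ratio, orientation, mode) for n_sites sites."""
    is_large = rng.random(n_sites) < condition.large_fraction
    mu = np.where(is_large, condition.large_mode[0], condition.small_mode[0])
    sd = np.where(is_large, condition.large_mode[1], condition.small_mode[1])
    areas = np.exp(rng.normal(mu, sd))
    ratios = rng.uniform(1.0, 2.0, n_sites)
    thetas = rng.uniform(0.0, math.pi, n_sites)
    return areas, ratios, thetas, is_large


def simulate_field(
    condition: ConditionSpec,
    layout: PlateLayout,
    noise: NoiseModel,
    seed: int | np.random.SeedSequence,
    well: str = "A1",
    field_index: int = 0,
    site_amplitude: float = SITE_AMPLITUDE,
) -> tuple[FieldImage, GroundTruth]:
    """Render one two-channel field of view plus its ground truth.

    Nuclei are discs in the "nuclei" channel; exocytic sites are
    half-max-truncated elliptical Gaussian blobs in the "vwf" channel,
    placed uniformly within a fixed radius of a parent nucleus. Site
    counts are Poisson(site_rate_per_cell x n_cells); areas come from
    the condition's two-mode log-normal mixture. Identical seeds yield
    bit-identical output.
    """
    shape = layout.field_shape
    px = layout.pixel_size_um
    rng = np.random.default_rng(seed)

    n_cells = int(rng.poisson(layout.cells_per_field))
    nuclei_centers = _sample_nuclei(rng, n_cells, shape, px)

    n_sites = int(rng.poisson(condition.site_rate_per_cell * n_cells)) if n_cells else 0
    areas, ratios, thetas, is_large = _sample_site_geometry(rng, condition, n_sites)

    site_rows = np.empty(n_sites)
    site_cols = np.empty(n_sites)
    place_r_px = SITE_PLACEMENT_RADIUS_UM / px
    for i in range(n_sites):
        parent = nuclei_centers[rng.integers(n_cells)]
        ang = rng.uniform(0.0, 2.0 * math.pi)
        rad = place_r_px * math.sqrt(rng.uniform())
        site_rows[i] = np.clip(round(parent[0] + rad * math.cos(ang)), 1, shape[0] - 2)
        site_cols[i] = np.clip(round(parent[1] + rad * math.sin(ang)), 1, shape[1] - 2)

    vwf = np.zeros(shape, dtype=np.float64)
    nuc = np.zeros(shape, dtype=np.float64)
    nuc_sigma = (NUCLEUS_RADIUS_UM / px) / math.sqrt(2.0 * math.log(2.0))
    for r, c in nuclei_centers:
        _render_truncated_gaussian(nuc, r, c, nuc_sigma, nuc_sigma, 0.0, NUCLEUS_AMPLITUDE)
    half_log2 = math.sqrt(2.0 * math.log(2.0))
    axis_major = np.sqrt(areas * ratios / math.pi)  # semi-axes, um
    axis_minor = np.sqrt(areas / (ratios * math.pi))
    for i in range(n_sites):
        _render_truncated_gaussian(
            vwf,
            site_rows[i],
            site_cols[i],
            (axis_major[i] / px) / half_log2,
            (axis_minor[i] / px) / half_log2,
            thetas[i],
            site_amplitude,
        )

    def _finish(channel: np.ndarray) -> np.ndarray:
        img = channel + noise.background
        if noise.gradient_amplitude > 0:
            gr = np.linspace(0.0, 1.0, shape[0])[:, None]
            gc = np.linspace(0.0, 1.0, shape[1])[None, :]
            img = img + noise.gradient_amplitude * 0.5 * (gr + gc)
        if noise.shot_noise:
            img = rng.poisson(np.clip(img, 0.0, None)).astype(np.float64)
        if noise.read_noise_sd > 0:
            img = img + rng.normal(0.0, noise.read_noise_sd, size=shape)
        return np.clip(np.round(img), 0, 65535).astype(np.uint16)

    field_img = FieldImage(
        channels={"vwf": _finish(vwf), "nuclei": _finish(nuc)},
        pixel_size_um=px,
        well=well,
        field=field_index,
    )
    gt = GroundTruth(
        nuclei=pd.DataFrame(
            {
                "well": well,
                "field": field_index,
                "row": nuclei_centers[:, 0],
                "col": nuclei_centers[:, 1],
            },
            columns=GroundTruth.NUCLEI_COLUMNS,
        ),
        sites=pd.DataFrame(
            {
                "well": well,
                "field": field_index,
                "row": site_rows,
                "col": site_cols,
                "area_um2": areas,
                "axis_major_um": axis_major,
                "axis_minor_um": axis_minor,
                "orientation_rad": thetas,
                "mode": np.where(is_large, "large", "small"),
            },
            columns=GroundTruth.SITE_COLUMNS,
        ),
    )
    return field_img, gt


def simulate_plate(
    layout: PlateLayout,
    noise: NoiseModel,
    seed: int,
    site_amplitude: float = SITE_AMPLITUDE,
) -> tuple[list[FieldImage], GroundTruth]:
    """Render every field of a plate; one deterministic sub-seed per field."""
    if not layout.wells:
        raise ValueError("plate layout has no wells")
    fields: list[FieldImage] = []
    truths: list[GroundTruth] = []
    for well, condition in layout.wells:
        for f in range(layout.fields_per_well):
            img, gt = simulate_field(
                condition,
                layout,
                noise,
                field_seed(seed, well, f),
                well=well,
                field_index=f,
                site_amplitude=site_amplitude,
            )
            fields.append(img)
            truths.append(gt)
    return fields, GroundTruth.concat(truths)


def _activation_times(
    rng: np.random.Generator, condition: ConditionSpec, n: int
) -> np.ndarray:
    """Per-site activation times (min) realising the condition's kinetics."""
    if condition.kinetics == "fast_saturating":
        return rng.exponential(condition.tau_min, n)
    return rng.uniform(0.0, _TIMECOURSE_MAX_MIN, n)


def simulate_timecourse(
    condition: ConditionSpec,
    timepoints: Sequence[float],
    layout: PlateLayout,
    noise: NoiseModel,
    seed: int,
    render: bool = True,
) -> dict[float, tuple[list[FieldImage] | None, GroundTruth]]:
    """Plates fixed at successive times after stimulation.

    Each field draws its plateau complement of sites once, assigns every
    site an activation time from the condition's kinetics (exponential
    with tau for fast_saturating, uniform over the 20-min window for
    linear), and exposes at each timepoint only the sites already
    active — sites persist once deposited, so expected counts are
    cumulative: proportional to 1 - exp(-t/tau) or to t. With
    ``render=False`` only ground truth is produced (images are None),
    which keeps large kinetics simulations cheap.
    """
    tp = [float(t) for t in timepoints]
    if not tp:
        raise ValueError("timepoints must be non-empty")
    if any(t1 <= t0 for t0, t1 in zip(tp, tp[1:])):
        raise ValueError("timepoints must be strictly increasing")
    if tp[0] < 0 or tp[-1] > _TIMECOURSE_MAX_MIN:
        raise ValueError(f"timepoints must lie within [0, {_TIMECOURSE_MAX_MIN}] min")
    truths: dict[float, list[GroundTruth]] = {t: [] for t in tp}
    images: dict[float, list[FieldImage]] = {t: [] for t in tp}
    for well, _ in layout.wells:
        for f in range(layout.fields_per_well):
            rng = np.random.default_rng(field_seed(seed, well, f))
            n_cells = int(rng.poisson(layout.cells_per_field))
            nuclei = _sample_nuclei(rng, n_cells, layout.field_shape, layout.pixel_size_um)
            n_plateau = (
                int(rng.poisson(condition.site_rate_per_cell * n_cells)) if n_cells else 0
            )
            areas, ratios, thetas, is_large = _sample_site_geometry(rng, condition, n_plateau)
            t_act = _activation_times(rng, condition, n_plateau)
            place_r_px = SITE_PLACEMENT_RADIUS_UM / layout.pixel_size_um
            rows = np.empty(n_plateau)
            cols = np.empty(n_plateau)
            for i in range(n_plateau):
                parent = nuclei[rng.integers(n_cells)]
                ang = rng.uniform(0.0, 2.0 * math.pi)
                rad = place_r_px * math.sqrt(rng.uniform())
                rows[i] = np.clip(round(parent[0] + rad * math.cos(ang)), 1, layout.field_shape[0] - 2)
                cols[i] = np.clip(round(parent[1] + rad * math.sin(ang)), 1, layout.field_shape[1] - 2)
            axis_major = np.sqrt(areas * ratios / math.pi)
            axis_minor = np.sqrt(areas / (ratios * math.pi))
            for t in tp:
                active = t_act <= t
                gt = GroundTruth(
                    nuclei=pd.DataFrame(
                        {"well": well, "field": f, "row": nuclei[:, 0], "col": nuclei[:, 1]},
                        columns=GroundTruth.NUCLEI_COLUMNS,
                    ),
                    sites=pd.DataFrame(
                        {
                            "well": well,
                            "field": f,
                            "row": rows[active],
                            "col": cols[active],
                            "area_um2": areas[active],
                            "axis_major_um": axis_major[active],
                            "axis_minor_um": axis_minor[active],
                            "orientation_rad": thetas[active],
                            "mode": np.where(is_large[active], "large", "small"),
                        },
                        columns=GroundTruth.SITE_COLUMNS,
                    ),
                )
                truths[t].append(gt)
                if render:
                    vwf = np.zeros(layout.field_shape, dtype=np.float64)
                    nuc = np.zeros(layout.field_shape, dtype=np.float64)
                    half_log2 = math.sqrt(2.0 * math.log(2.0))
                    nuc_sigma = (NUCLEUS_RADIUS_UM / layout.pixel_size_um) / half_log2
                    for r, c in nuclei:
                        _render_truncated_gaussian(nuc, r, c, nuc_sigma, nuc_sigma, 0.0, NUCLEUS_AMPLITUDE)
                    for i in np.flatnonzero(active):
                        _render_truncated_gaussian(
                            vwf,
                            rows[i],
                            cols[i],
                            (axis_major[i] / layout.pixel_size_um) / half_log2,
                            (axis_minor[i] / layout.pixel_size_um) / half_log2,
                            thetas[i],
                            SITE_AMPLITUDE,
                        )
                    noise_rng = np.random.default_rng(
                        np.random.SeedSequence(
                            entropy=(int(seed), zlib.crc32(str(well).encode()), f, int(round(t * 1000)))
                        )
                    )

                    def _finish(channel: np.ndarray) -> np.ndarray:
                        img = channel + noise.background
                        if noise.gradient_amplitude > 0:
                            gr = np.linspace(0.0, 1.0, layout.field_shape[0])[:, None]
                            gc = np.linspace(0.0, 1.0, layout.field_shape[1])[None, :]
                            img = img + noise.gradient_amplitude * 0.5 * (gr + gc)
                        if noise.shot_noise:
                            img = noise_rng.poisson(np.clip(img, 0.0, None)).astype(np.float64)
                        if noise.read_noise_sd > 0:
                            img = img + noise_rng.normal(0.0, noise.read_noise_sd, size=img.shape)
                        return np.clip(np.round(img), 0, 65535).astype(np.uint16)

                    images[t].append(
                        FieldImage(
                            channels={"vwf": _finish(vwf), "nuclei": _finish(nuc)},
                            pixel_size_um=layout.pixel_size_um,
                            well=well,
                            field=f,
                        )
                    )
    return {
        t: (images[t] if render else None, GroundTruth.concat(truths[t])) for t in tp
    }


# --- fusion events -----------------------------------------------------------


def constant_rate(total_events: float, duration_s: float = 600.0) -> Callable[[float], float]:
    """Rate function (events/s) with the given expected total over the window."""
    return lambda t: total_events / duration_s


def ring_prob_constant(p: float) -> Callable[[float], float]:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must be in [0,1], got {p}")
    return lambda t: p


def ring_prob_logistic(
    p_start: float, p_end: float, midpoint_s: float = 150.0, scale_s: float = 60.0
) -> Callable[[float], float]:
    """Monotone non-decreasing logistic recruitment probability."""
    for p in (p_start, p_end):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability must be in [0,1], got {p}")
    if p_end < p_start:
        raise ValueError("logistic ring probability must be non-decreasing")

    def prob(t: float) -> float:
        return p_start + (p_end - p_start) / (1.0 + math.exp(-(t - midpoint_s) / scale_s))

    return prob


def simulate_fusion_events(
    rate_fn: Callable[[float], float],
    ring_prob_fn: Callable[[float], float],
    duration_s: float = 600.0,
    frame_s: float = 5.0,
    seed: int | None = None,
    condition: str = "sim",
) -> pd.DataFrame:
    """Granule fusion events on the acquisition frame grid.

    Frames are 0, frame_s, 2*frame_s, ... < duration_s; per-frame event
    counts are Poisson(rate_fn(t) * frame_s) and each event's
    ring-positive flag is Bernoulli(ring_prob_fn(t)). Returns a table
    with columns time_s, ring_positive, condition, movie.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n_frames = duration_s / frame_s
    if frame_s <= 0 or abs(n_frames - round(n_frames)) > 1e-9:
        raise ValueError(f"frame interval {frame_s} must divide duration {duration_s}")
    rng = np.random.default_rng(seed)
    times: list[float] = []
    flags: list[bool] = []
    for k in range(int(round(n_frames))):
        t = k * frame_s
        p = float(ring_prob_fn(t))
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"ring_prob_fn({t}) = {p} outside [0, 1]")
        lam = float(rate_fn(t)) * frame_s
        if lam < 0:
            raise ValueError(f"rate_fn({t}) is negative")
        n = int(rng.poisson(lam))
        times.extend([t] * n)
        flags.extend(rng.random(n) < p)
    return pd.DataFrame(
        {
            "time_s": np.array(times, dtype=np.float64),
            "ring_positive": np.array(flags, dtype=bool),
            "condition": condition,
            "movie": 0,
        }
    )


# --- VWF strings -------------------------------------------------------------


def lognormal_lengths(mean_um: float = 35.0, log_sd: float = 0.5) -> Callable:
    """Length sampler: log-normal with the given median length in um."""
    if mean_um <= 0:
        raise ValueError("mean length must be positive")
    mu = math.log(mean_um)

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return np.exp(rng.normal(mu, log_sd, n))

    return sample


def simulate_strings(
    n: int,
    length_dist: Callable[[np.random.Generator, int], np.ndarray] | Sequence[float] | None = None,
    pixel_size_um: float = 0.3,
    seed: int | None = None,
    step_um: float = 2.0,
    curvature_sd_rad: float = 0.12,
    width_px: int = 1,
) -> tuple[pd.DataFrame, list[np.ndarray], list[np.ndarray]]:
    """Curved VWF-string polylines with rendered binary masks.

    Each string is a random-walk polyline (fixed step, small Gaussian
    heading increments) whose summed segment length equals the drawn
    target exactly; the mask is the rasterised polyline dilated by
    ``width_px``. Strings are rendered on separate canvases so masks
    never merge. Returns (records, polylines in um coordinates, masks);
    records has columns string_id, length_um.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if pixel_size_um <= 0:
        raise ValueError(f"pixel size must be positive, got {pixel_size_um}")
    rng = np.random.default_rng(seed)
    if length_dist is None:
        lengths = lognormal_lengths()(rng, n)
    elif callable(length_dist):
        lengths = np.asarray(length_dist(rng, n), dtype=np.float64)
    else:
        lengths = np.asarray(length_dist, dtype=np.float64)
        if len(lengths) != n:
            raise ValueError(f"expected {n} lengths, got {len(lengths)}")
    if n and lengths.min() <= 0:
        raise ValueError("string lengths must be positive")

    from skimage.draw import line as draw_line
    from skimage.morphology import disk

    records = []
    polylines: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    selem = disk(width_px)
    for i in range(n):
        target = float(lengths[i])
        pts = [(0.0, 0.0)]
        heading = rng.uniform(0.0, 2.0 * math.pi)
        remaining = target
        while remaining > 1e-12:
            step = min(step_um, remaining)
            heading += rng.normal(0.0, curvature_sd_rad)
            r0, c0 = pts[-1]
            pts.append((r0 + step * math.sin(heading), c0 + step * math.cos(heading)))
            remaining -= step
        poly = np.asarray(pts, dtype=np.float64)
        polylines.append(poly)
        records.append({"string_id": i, "length_um": target})

        poly_px = poly / pixel_size_um
        pad = width_px + 2
        rmin, cmin = poly_px.min(axis=0)
        poly_px = poly_px - [rmin, cmin] + pad
        shape = tuple(int(np.ceil(v)) + pad + 1 for v in poly_px.max(axis=0))
        mask = np.zeros(shape, dtype=bool)
        ipts = np.round(poly_px).astype(int)
        for (ra, ca), (rb, cb) in zip(ipts[:-1], ipts[1:]):
            rr, cc = draw_line(ra, ca, rb, cb)
            mask[rr, cc] = True
        masks.append(ndi.binary_dilation(mask, structure=selem))
    return pd.DataFrame(records, columns=["string_id", "length_um"]), polylines, masks
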