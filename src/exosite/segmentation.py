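"""Automated segmentation of antibody-retained exocytic sites.

The pipeline mirrors classical spot segmentation for high-content
screening images: Gaussian denoising, a global moment-preserving (Tsai)
threshold, marker-based watershed splitting of touching sites, removal
of objects below the optical resolution limit, and per-object
morphometric measurement in physical units. Nuclei counting reuses the
same pipeline with a larger minimum-area filter, so that sites-per-cell
statistics need only the nuclear stain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import relabel_sequential, watershed

from .optics import OpticalConfig, subresolution_cutoff

__all__ = [
    "DegenerateImageError",
    "FieldImage",
    "SegmentationParams",
    "gaussian_denoise",
    "moment_preserving_threshold",
    "binarize",
    "split_touching_sites",
    "filter_subresolution",
    "measure_sites",
    "count_nuclei",
    "segment_field",
    "validate_against_annotation",
    "SITE_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Fixed column order of a site table (CSV contract).
SITE_COLUMNS = [
    "site_id",
    "well",
    "field",
    "area_um2",
    "equiv_diameter_um",
    "perimeter_um",
    "centroid_row",
    "centroid_col",
    "eccentricity",
    "mean_intensity",
    "integrated_intensity",
]


class DegenerateImageError(ValueError):
    """Raised when an image has too little gray-level structure to threshold."""


@dataclass
class FieldImage:
    """One field of view: named channels plus physical pixel size.

    channels maps channel name (e.g. ``"vwf"``, ``"nuclei"``) to a 2-D
    non-negative intensity array; all channels must share one shape.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    well: str = ""
    field: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel size must be positive, got {self.pixel_size_um}")
        if not self.channels:
            raise ValueError("FieldImage needs at least one channel")
        shapes = {np.asarray(c).shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels have mismatched shapes: {shapes}")
        (shape,) = shapes
        if len(shape) != 2 or min(shape) == 0:
            raise ValueError(f"channels must be non-empty 2-D arrays, got shape {shape}")
        for name, chan in self.channels.items():
            arr = np.asarray(chan)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class SegmentationParams:
    """Tunable knobs of the segmentation pipeline.

    sigma_px: Gaussian denoising sigma in pixels (1.0 by default).
    marker_min_distance_px: minimum separation of watershed markers.
    min_area_um2: override of the optical sub-resolution cutoff (None =
        compute from the OpticalConfig).
    nucleus_min_area_um2: minimum nucleus area; smaller objects in the
        nuclear channel are debris.
    """

    sigma_px: float = 1.0
    marker_min_distance_px: int = 2
    min_area_um2: float | None = None
    nucleus_min_area_um2: float = 20.0
    vwf_channel: str = "vwf"
    nuclei_channel: str = "nuclei"
    histogram_bins: int = 256
    # Stained objects cover at most a few percent of a field; a global
    # threshold that marks more than this fraction as foreground has
    # collapsed into the background mode (signal-free image) and the
    # field is treated as empty rather than segmented into noise.
    max_foreground_fraction: float = 0.25
    match_radius_um: float | None = None  # annotation matching; None = adaptive


def gaussian_denoise(image: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian blur with reflect boundary handling; sigma 0 is the identity."""
    if sigma_px < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma_px}")
    img = np.asarray(image, dtype=np.float64)
    if sigma_px == 0:
        return img.copy()
    return ndi.gaussian_filter(img, sigma=sigma_px, mode="reflect")


def _histogram_moments(p: np.ndarray, z: np.ndarray) -> tuple[float, float, float]:
    m1 = float(np.sum(p * z))
    m2 = float(np.sum(p * z**2))
    m3 = float(np.sum(p * z**3))
    return m1, m2, m3


def moment_preserving_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Tsai's bilevel moment-preserving threshold.

    The image histogram (``nbins`` equal-width bins over the intensity
    range) is replaced by a two-level image with below-threshold fraction
    p0 and representative levels z0 < z1 chosen so the first three
    gray-level moments are preserved. The returned threshold is the
    smallest gray level (bin centre) whose cumulative histogram fraction
    reaches p0; binarization takes strictly-greater pixels as foreground.

    Raises
    ------
    DegenerateImageError
        For constant images or histograms with fewer than two occupied
        bins, where the moment system has no bilevel solution.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0 or not np.all(np.isfinite(img)):
        raise ValueError("image must be non-empty and finite")
    lo = float(img.min())
    hi = float(img.max())
    if hi == lo:
        raise DegenerateImageError("constant image: moment system is degenerate")
    hist, edges = np.histogram(img.ravel(), bins=nbins, range=(lo, hi))
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError("fewer than two occupied gray levels")
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = hist / hist.sum()
    m1, m2, m3 = _histogram_moments(p, centers)
    cd = m2 - m1 * m1  # m0 = 1
    if cd <= 0:
        raise DegenerateImageError("zero-variance histogram")
    c0 = (m1 * m3 - m2 * m2) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = max(c1 * c1 - 4.0 * c0, 0.0)
    root = np.sqrt(disc)
    z0 = 0.5 * (-c1 - root)
    z1 = 0.5 * (-c1 + root)
    if z1 == z0:
        raise DegenerateImageError("coincident representative levels")
    p0 = (z1 - m1) / (z1 - z0)
    p0 = min(max(p0, 0.0), 1.0)
    cum = np.cumsum(p)
    idx = int(np.searchsorted(cum, p0 - 1e-12))
    idx = min(idx, nbins - 1)
    return float(centers[idx])


def binarize(image: np.ndarray, threshold: float) -> np.ndarray:
    """Foreground mask: pixels strictly greater than the threshold."""
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    return np.asarray(image) > threshold


def split_touching_sites(mask: np.ndarray, marker_min_distance_px: int = 2) -> np.ndarray:
    """Split touching objects by marker-based watershed flooding.

    Markers are the local maxima of the Euclidean distance transform of
    the mask (minimum separation ``marker_min_distance_px``; connected
    plateau maxima are merged into a single marker). The negated
    distance transform is then flooded within the mask, assigning every
    foreground pixel to exactly one label. Labels are contiguous 1..K.
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        return np.zeros(m.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(m)
    # Rasterised objects give the EDT near-plateau maxima broken by tiny
    # dips; a light smoothing merges them into one detectable peak.
    dist_smooth = ndi.gaussian_filter(dist, sigma=1.0)
    coords = peak_local_max(
        dist_smooth,
        min_distance=marker_min_distance_px,
        labels=m,
        exclude_border=False,
    )
    marker_mask = np.zeros(m.shape, dtype=bool)
    if coords.size:
        marker_mask[tuple(coords.T)] = True
    else:  # pathological plateaus: fall back to one marker per component
        marker_mask = m
    markers, _ = ndi.label(marker_mask, structure=np.ones((3, 3), dtype=int))
    labels = watershed(-dist_smooth, markers, mask=m, connectivity=2)
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def filter_subresolution(
    labels: np.ndarray,
    optical: OpticalConfig | None = None,
    pixel_size_um: float | None = None,
    min_area_um2: float | None = None,
) -> np.ndarray:
    """Remove labelled objects strictly below the resolution-limit area.

    The cutoff is ``min_area_um2`` if given, otherwise computed from the
    OpticalConfig. Objects exactly at the cutoff are kept. Survivors are
    relabelled contiguously, preserving the original label order.
    """
    lab = np.asarray(labels)
    if pixel_size_um is None:
        if optical is None:
            raise ValueError("need pixel_size_um or an OpticalConfig")
        pixel_size_um = optical.pixel_size_um
    if pixel_size_um <= 0:
        raise ValueError(f"pixel size must be positive, got {pixel_size_um}")
    if min_area_um2 is None:
        if optical is None:
            raise ValueError("need min_area_um2 or an OpticalConfig")
        min_area_um2 = subresolution_cutoff(optical)
    n = int(lab.max())
    if n == 0:
        return lab.astype(np.int32)
    counts = np.bincount(lab.ravel(), minlength=n + 1)
    areas = counts[1:] * pixel_size_um**2
    keep = areas >= min_area_um2  # "beneath" read as strictly below
    lut = np.zeros(n + 1, dtype=np.int32)
    lut[1:][keep] = np.arange(1, int(keep.sum()) + 1, dtype=np.int32)
    n_removed = n - int(keep.sum())
    if n_removed:
        logger.info("filter_subresolution: removed %d/%d objects", n_removed, n)
    return lut[lab]


def measure_sites(
    labels: np.ndarray,
    intensity: np.ndarray,
    pixel_size_um: float,
    well: str = "",
    field: int = 0,
) -> pd.DataFrame:
    """Morphometrics per labelled site, in physical units.

    Returns a DataFrame with the :data:`SITE_COLUMNS` layout: area and
    perimeter converted by the pixel size, 0-based pixel centroids, the
    fitted-ellipse eccentricity, and mean/integrated raw intensity.
    """
    lab = np.asarray(labels)
    img = np.asarray(intensity, dtype=np.float64)
    if lab.shape != img.shape:
        raise ValueError(f"label/image shape mismatch: {lab.shape} vs {img.shape}")
    if pixel_size_um <= 0:
        raise ValueError(f"pixel size must be positive, got {pixel_size_um}")
    rows = []
    for rp in regionprops(lab, intensity_image=img):
        rows.append(
            {
                "site_id": int(rp.label),
                "well": well,
                "field": int(field),
                "area_um2": rp.area * pixel_size_um**2,
                "equiv_diameter_um": rp.equivalent_diameter_area * pixel_size_um,
                "perimeter_um": rp.perimeter * pixel_size_um,
                "centroid_row": rp.centroid[0],
                "centroid_col": rp.centroid[1],
                "eccentricity": rp.eccentricity,
                "mean_intensity": rp.intensity_mean,
                "integrated_intensity": rp.intensity_mean * rp.area,
            }
        )
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def count_nuclei(
    nuclei_channel: np.ndarray,
    pixel_size_um: float,
    params: SegmentationParams | None = None,
) -> int:
    """Count nuclei with the site pipeline plus a minimum-area filter.

    A degenerate (constant) channel yields a count of 0 with a logged
    warning rather than an error, so blank wells do not abort a plate.
    """
    params = params or SegmentationParams()
    img = np.asarray(nuclei_channel)
    if img.size == 0:
        raise ValueError("empty nuclei channel")
    smoothed = gaussian_denoise(img, params.sigma_px)
    try:
        thr = moment_preserving_threshold(smoothed, nbins=params.histogram_bins)
    except DegenerateImageError:
        logger.warning("degenerate nuclei channel; reporting 0 cells")
        return 0
    mask = binarize(smoothed, thr)
    if mask.mean() > params.max_foreground_fraction:
        logger.warning(
            "nuclei threshold collapsed (%.0f%% foreground); reporting 0 cells",
            100 * mask.mean(),
        )
        return 0
    labels = split_touching_sites(mask, params.marker_min_distance_px)
    labels = filter_subresolution(
        labels, pixel_size_um=pixel_size_um, min_area_um2=params.nucleus_min_area_um2
    )
    return int(labels.max())


def segment_field(
    field_image: FieldImage,
    optical: OpticalConfig | None = None,
    params: SegmentationParams | None = None,
) -> tuple[pd.DataFrame, int]:
    """Full pipeline on one field: site table plus nuclei count.

    denoise -> moment threshold -> binarize -> watershed split ->
    sub-resolution filter -> measure, on the VWF channel; nuclei are
    counted from the nuclear channel. A blank (constant) VWF channel
    yields an empty site table.
    """
    params = params or SegmentationParams()
    optical = optical or OpticalConfig(pixel_size_um=field_image.pixel_size_um)
    for chan in (params.vwf_channel, params.nuclei_channel):
        if chan not in field_image.channels:
            raise KeyError(
                f"channel {chan!r} missing from field "
                f"{field_image.well}/f{field_image.field} "
                f"(have {sorted(field_image.channels)})"
            )
    px = field_image.pixel_size_um
    vwf = field_image.channels[params.vwf_channel]
    smoothed = gaussian_denoise(vwf, params.sigma_px)
    try:
        thr = moment_preserving_threshold(smoothed, nbins=params.histogram_bins)
        mask = binarize(smoothed, thr)
    except DegenerateImageError:
        mask = np.zeros(smoothed.shape, dtype=bool)
    if mask.mean() > params.max_foreground_fraction:
        logger.warning(
            "site threshold collapsed (%.0f%% foreground) in %s/f%d; "
            "treating field as signal-free",
            100 * mask.mean(),
            field_image.well,
            field_image.field,
        )
        mask = np.zeros(smoothed.shape, dtype=bool)
    labels = split_touching_sites(mask, params.marker_min_distance_px)
    n_raw = int(labels.max())
    labels = filter_subresolution(
        labels,
        optical=optical,
        pixel_size_um=px,
        min_area_um2=params.min_area_um2,
    )
    sites = measure_sites(labels, vwf, px, well=field_image.well, field=field_image.field)
    n_cells = count_nuclei(field_image.channels[params.nuclei_channel], px, params)
    logger.info(
        "segment_field %s/f%d: %d raw objects, %d sites after filtering, %d nuclei",
        field_image.well,
        field_image.field,
        n_raw,
        len(sites),
        n_cells,
    )
    return sites, n_cells


def validate_against_annotation(
    detected: pd.DataFrame,
    annotated_centers: np.ndarray,
    pixel_size_um: float,
    match_radius_um: float | None = None,
) -> tuple[float, float, float]:
    """Precision/recall/F1 of detected sites against annotated centres.

    Detected centroids (pixel coordinates in the site table) are matched
    one-to-one, greedily by increasing distance, to annotated centres
    (N x 2 array of (row, col) pixel coordinates). A pair may match when
    their distance is at most ``2 * sqrt(area / pi)`` of the detected
    site, or the fixed ``match_radius_um`` when given. Undefined ratios
    (no detections / no annotations) are reported as NaN.
    """
    ann = np.asarray(annotated_centers, dtype=np.float64).reshape(-1, 2)
    n_det = len(detected)
    n_ann = len(ann)
    if n_det == 0 and n_ann == 0:
        return (np.nan, np.nan, np.nan)
    if n_det == 0:
        return (np.nan, 0.0, np.nan)
    if n_ann == 0:
        return (0.0, np.nan, np.nan)
    det_xy = detected[["centroid_row", "centroid_col"]].to_numpy(dtype=np.float64)
    dists = np.hypot(
        det_xy[:, None, 0] - ann[None, :, 0], det_xy[:, None, 1] - ann[None, :, 1]
    ) * pixel_size_um
    if match_radius_um is None:
        radii = 2.0 * np.sqrt(detected["area_um2"].to_numpy(dtype=np.float64) / np.pi)
    else:
        radii = np.full(n_det, float(match_radius_um))
    candidates = np.argwhere(dists <= radii[:, None])
    order = np.argsort(dists[candidates[:, 0], candidates[:, 1]], kind="stable")
    used_det = np.zeros(n_det, dtype=bool)
    used_ann = np.zeros(n_ann, dtype=bool)
    matched = 0
    for i, j in candidates[order]:
        if not used_det[i] and not used_ann[j]:
            used_det[i] = used_ann[j] = True
            matched += 1
    precision = matched / n_det
    recall = matched / n_ann
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return (precision, recall, f1)
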