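"""End-to-end orchestration: simulate (or load) a plate, segment every
field, and emit per-well and per-condition summary tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclass_field
from itertools import combinations
from pathlib import Path

import pandas as pd

from . import __version__
from .io import config_hash, write_field, write_table
from .optics import OpticalConfig
from .segmentation import FieldImage, SegmentationParams, segment_field
from .site_stats import (
    LARGE_SITE_THRESHOLD_UM2,
    condition_prop_large,
    ks_two_sample,
    normalize_to_control,
    summarize_well,
)
from .synthetic import ConditionSpec, NoiseModel, PlateLayout, simulate_plate

__all__ = ["RunConfig", "run_pipeline", "layout_from_config", "segment_plate", "summarize_plate"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs, resolvable from a TOML/YAML file."""

    layout: PlateLayout
    noise: NoiseModel = dataclass_field(default_factory=NoiseModel)
    optical: OpticalConfig = dataclass_field(default_factory=OpticalConfig)
    segmentation: SegmentationParams = dataclass_field(default_factory=SegmentationParams)
    large_site_threshold_um2: float = LARGE_SITE_THRESHOLD_UM2
    control_condition: str | None = None
    seed: int = 0
    output_dir: Path = Path("exosite_output")
    write_images: bool = False

    def as_metadata(self) -> dict:
        desc = {
            "wells": [(w, c.name, c.site_rate_per_cell, c.large_fraction) for w, c in self.layout.wells],
            "fields_per_well": self.layout.fields_per_well,
            "cells_per_field": self.layout.cells_per_field,
            "field_shape": self.layout.field_shape,
            "pixel_size_um": self.layout.pixel_size_um,
            "noise": vars(self.noise) if hasattr(self.noise, "__dict__") else str(self.noise),
            "sigma_px": self.segmentation.sigma_px,
            "threshold_um2": self.large_site_threshold_um2,
            "seed": self.seed,
        }
        return {
            "exosite_version": __version__,
            "config_hash": config_hash(desc),
            "seed": self.seed,
        }


def layout_from_config(cfg: dict) -> PlateLayout:
    """Build a PlateLayout from a parsed config mapping.

    Expected shape::

        [plate]
        fields_per_well = 9
        cells_per_field = 11.574
        pixel_size_um = 0.3

        [[conditions]]
        name = "pma"
        wells = ["A1", "A2"]
        site_rate_per_cell = 3.0
        large_fraction = 0.65
    """
    plate = cfg.get("plate", {})
    wells: list[tuple[str, ConditionSpec]] = []
    for cond_cfg in cfg.get("conditions", []):
        cond_kwargs = {
            k: v for k, v in cond_cfg.items() if k not in ("wells",)
        }
        if "small_mode" in cond_kwargs:
            cond_kwargs["small_mode"] = tuple(cond_kwargs["small_mode"])
        if "large_mode" in cond_kwargs:
            cond_kwargs["large_mode"] = tuple(cond_kwargs["large_mode"])
        cond = ConditionSpec(**cond_kwargs)
        for well in cond_cfg.get("wells", []):
            wells.append((well, cond))
    if not wells:
        raise ValueError("configuration defines no wells")
    kwargs = {}
    for key in ("fields_per_well", "cells_per_field", "pixel_size_um"):
        if key in plate:
            kwargs[key] = plate[key]
    if "field_shape" in plate:
        kwargs["field_shape"] = tuple(plate["field_shape"])
    return PlateLayout(wells=tuple(wells), **kwargs)


def segment_plate(
    fields: list[FieldImage],
    optical: OpticalConfig,
    params: SegmentationParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment every field; returns (site table, per-field cell counts)."""
    site_tables = []
    cell_rows = []
    for fi in fields:
        sites, n_cells = segment_field(fi, optical, params)
        if len(sites):
            site_tables.append(sites)
        cell_rows.append({"well": fi.well, "field": fi.field, "n_cells": n_cells})
    from .segmentation import SITE_COLUMNS

    sites = (
        pd.concat(site_tables, ignore_index=True)
        if site_tables
        else pd.DataFrame(columns=SITE_COLUMNS)
    )
    return sites, pd.DataFrame(cell_rows, columns=["well", "field", "n_cells"])


def summarize_plate(
    sites: pd.DataFrame,
    cells: pd.DataFrame,
    layout: PlateLayout,
    threshold_um2: float = LARGE_SITE_THRESHOLD_UM2,
) -> pd.DataFrame:
    """One WellSummary row per well of the layout."""
    rows = []
    for well, condition in layout.wells:
        well_cells = cells.loc[cells["well"] == well].sort_values("field")
        well_sites = (
            sites.loc[sites["well"] == well]
            if len(sites)
            else pd.DataFrame(columns=["area_um2"])
        )
        summary = summarize_well(
            well_sites,
            well_cells["n_cells"].tolist(),
            well=well,
            condition=condition.name,
            threshold_um2=threshold_um2,
        )
        rows.append(summary.to_dict())
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Simulate, segment and summarise one plate; write all outputs.

    Outputs (all CSV, with version/config-hash/seed header lines):
    ``sites.csv``, ``cells.csv``, ``well_summaries.csv``,
    ``condition_prop_large.csv`` and, when more than one condition is
    present, ``condition_comparisons.csv`` with pairwise KS statistics
    on pooled site areas (plus the prop_large ratio to the configured
    control). Deterministic: identical config and seed give
    byte-identical CSVs.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = config.as_metadata()

    logger.info("simulating plate (seed %d)", config.seed)
    fields, truth = simulate_plate(config.layout, config.noise, config.seed)
    if config.write_images:
        for fi in fields:
            write_field(fi, out_dir / "images")
        write_table(truth.sites, out_dir / "ground_truth_sites.csv", meta)
        write_table(truth.nuclei, out_dir / "ground_truth_nuclei.csv", meta)

    logger.info("segmenting %d fields", len(fields))
    sites, cells = segment_plate(fields, config.optical, config.segmentation)
    summaries = summarize_plate(sites, cells, config.layout, config.large_site_threshold_um2)
    per_condition = condition_prop_large(summaries)

    condition_names = list(dict.fromkeys(c.name for _, c in config.layout.wells))
    comparison_rows = []
    for cond_a, cond_b in combinations(condition_names, 2):
        areas_a = sites.loc[sites["well"].isin(
            [w for w, c in config.layout.wells if c.name == cond_a]
        ), "area_um2"]
        areas_b = sites.loc[sites["well"].isin(
            [w for w, c in config.layout.wells if c.name == cond_b]
        ), "area_um2"]
        if len(areas_a) == 0 or len(areas_b) == 0:
            continue
        d, p = ks_two_sample(areas_a, areas_b)
        row = {"condition_a": cond_a, "condition_b": cond_b, "ks_D": d, "ks_p": p}
        if config.control_condition is not None and cond_b == config.control_condition:
            ratio, se = normalize_to_control(
                summaries.loc[summaries["condition"] == cond_a, "prop_large"],
                summaries.loc[summaries["condition"] == cond_b, "prop_large"],
            )
            row["prop_large_ratio"] = ratio
            row["prop_large_ratio_se"] = se
        comparison_rows.append(row)
    comparisons = pd.DataFrame(comparison_rows)

    write_table(sites, out_dir / "sites.csv", meta)
    write_table(cells, out_dir / "cells.csv", meta)
    write_table(summaries, out_dir / "well_summaries.csv", meta)
    write_table(per_condition, out_dir / "condition_prop_large.csv", meta)
    if len(comparisons):
        write_table(comparisons, out_dir / "condition_comparisons.csv", meta)
    return {
        "sites": sites,
        "cells": cells,
        "well_summaries": summaries,
        "condition_prop_large": per_condition,
        "condition_comparisons": comparisons,
        "ground_truth": truth,
        "metadata": meta,
    }
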