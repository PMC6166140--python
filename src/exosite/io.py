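"""File formats: 16-bit TIFF fields, CSV tables with provenance headers,
TOML/YAML run configuration."""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .segmentation import FieldImage

__all__ = [
    "write_field",
    "read_field",
    "write_table",
    "read_table",
    "load_config_file",
    "config_hash",
]


def write_field(field: FieldImage, out_dir: str | Path) -> list[Path]:
    """Write one TIFF per channel, named ``<well>_f<field>_<channel>.tif``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, chan in field.channels.items():
        path = out_dir / f"{field.well}_f{field.field}_{name}.tif"
        tifffile.imwrite(path, np.asarray(chan, dtype=np.uint16))
        paths.append(path)
    return paths


def read_field(
    directory: str | Path,
    well: str,
    field_index: int,
    channels: tuple[str, ...] = ("vwf", "nuclei"),
    pixel_size_um: float = 0.3,
) -> FieldImage:
    """Load one field of view from per-channel TIFFs.

    A missing or unreadable file fails fast, naming the offending
    well/field/channel.
    """
    directory = Path(directory)
    loaded = {}
    for name in channels:
        path = directory / f"{well}_f{field_index}_{name}.tif"
        try:
            loaded[name] = tifffile.imread(path)
        except (FileNotFoundError, OSError, ValueError) as exc:
            raise IOError(
                f"cannot read channel {name!r} of well {well} field {field_index}: "
                f"{path} ({exc})"
            ) from exc
    return FieldImage(channels=loaded, pixel_size_um=pixel_size_um, well=well, field=field_index)


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping (changes iff it does)."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame, path: str | Path, metadata: dict | None = None
) -> Path:
    """Write a CSV with ``#``-prefixed provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def load_config_file(path: str | Path) -> dict:
    """Load a TOML (preferred) or YAML run configuration."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            return yaml.safe_load(fh)
    raise ValueError(f"unsupported config format: {path.suffix!r} (use .toml or .yaml)")
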