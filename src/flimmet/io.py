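"""Readers and writers for the pipeline's on-disk formats.

Decay cubes travel as multi-page TIFF (T pages of identical H×W integer
frames) with the time-axis metadata stored as JSON in the TIFF
ImageDescription tag (a ``<name>.json`` sidecar is also honoured on
read). Maps are 32-bit float TIFF with NaN marking missing pixels;
tables are plain CSV (comma separator, '.' decimal, UTF-8) with units in
parentheses in the header row. Every run writes a provenance JSON with
the seed, config and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .decay_model import DEFAULT_N_BINS, DEFAULT_PERIOD_NS, TimeAxis
from .errors import FormatError
from .pipeline import TcspcCube

logger = logging.getLogger(__name__)

__all__ = [
    "read_cube",
    "write_cube",
    "read_map",
    "write_map",
    "write_table",
    "write_provenance",
    "write_outputs",
]

#: Units for known table columns, written into CSV headers.
COLUMN_UNITS = {
    "tau_avg": "ns",
    "tau_avg_mean": "ns",
    "tau_avg_median": "ns",
    "tau1": "ns",
    "tau2": "ns",
    "centroid_row": "px",
    "centroid_col": "px",
    "n_pixels": "px",
}


def write_cube(path: str | Path, cube: TcspcCube) -> Path:
    """Write a cube as a multi-page TIFF (T pages of H×W) with metadata."""
    path = Path(path)
    meta = {
        "n_bins": cube.axis.n_bins,
        "period_ns": cube.axis.period,
        "bin_width_ns": cube.axis.bin_width,
        "channel": cube.channel,
        **cube.metadata,
    }
    pages = np.moveaxis(cube.counts.astype(np.uint32), 2, 0)
    tifffile.imwrite(path, pages, description=json.dumps(meta))
    return path


def read_cube(path: str | Path) -> TcspcCube:
    """Read a multi-page TIFF cube written by :func:`write_cube`.

    Metadata is taken from the ImageDescription tag, else from a
    ``<stem>.json`` sidecar; missing fields fall back to the documented
    defaults (256 bins over a 12.5 ns / 80 MHz period) with a warning.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) != 1:
            raise FormatError(f"pages of {path} have mixed shapes: {sorted(shapes)}")
        data = tif.asarray()
        desc = tif.pages[0].description
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"{path} is not a T-page stack of 2-D frames")
    if np.any(data < 0):
        raise FormatError(f"{path} contains negative photon counts")

    # sidecar fills in what the in-file tag does not carry; the tag wins
    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    if desc:
        try:
            tag = json.loads(desc)
        except json.JSONDecodeError:
            tag = {}
        if isinstance(tag, dict):
            tag.pop("shape", None)  # tifffile's own default description
            meta.update(tag)

    period = meta.get("period_ns")
    if period is None:
        period = DEFAULT_PERIOD_NS
        logger.warning(
            "%s: no laser-period metadata; assuming %.1f ns (80 MHz)", path, period
        )
    n_bins = int(meta.get("n_bins", data.shape[0]))
    if n_bins != data.shape[0]:
        raise FormatError(
            f"{path}: metadata says {n_bins} bins but file has {data.shape[0]} pages"
        )
    axis = TimeAxis(
        n_bins=n_bins,
        period=float(period),
        bin_width=float(meta.get("bin_width_ns", 0.0)),
    )
    extra = {
        k: v
        for k, v in meta.items()
        if k not in ("n_bins", "period_ns", "bin_width_ns", "channel", "shape")
    }
    return TcspcCube(
        counts=np.moveaxis(data, 0, 2).astype(np.int64),
        axis=axis,
        channel=str(meta.get("channel", "NADPH")),
        metadata=extra,
    )


def write_map(path: str | Path, array: np.ndarray) -> Path:
    """Write a 2-D map as 32-bit float TIFF; NaN marks missing pixels."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))
    return path


def read_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.float32)


def _header_with_units(columns: list[str]) -> list[str]:
    return [
        f"{c} ({COLUMN_UNITS[c]})" if c in COLUMN_UNITS else c for c in columns
    ]


def write_table(path: str | Path, table: pd.DataFrame) -> Path:
    """Write a table as CSV with units in parentheses in the header."""
    path = Path(path)
    out = table.copy()
    out.columns = _header_with_units(list(table.columns))
    out.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, stripping unit suffixes."""
    table = pd.read_csv(Path(path))
    table.columns = [c.split(" (")[0] for c in table.columns]
    return table


def write_provenance(
    path: str | Path, seed: int, config: object | None = None, **extra
) -> Path:
    """Write the provenance JSON: seed, config, package version, hash."""
    path = Path(path)
    cfg = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else config
    payload = {"seed": int(seed), "version": __version__, "config": cfg, **extra}
    blob = json.dumps(payload, sort_keys=True, default=str)
    payload["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path


def write_outputs(
    outdir: str | Path,
    maps: dict[str, np.ndarray] | None = None,
    tables: dict[str, pd.DataFrame] | None = None,
    config: object | None = None,
    seed: int = 0,
) -> dict[str, Path]:
    """Write all pipeline artefacts under ``outdir``.

    Maps become ``<name>.tif`` float TIFFs, tables ``<name>.csv``, and a
    ``provenance.json`` records the seed, config and version.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, arr in (maps or {}).items():
        written[name] = write_map(outdir / f"{name}.tif", arr)
    for name, tab in (tables or {}).items():
        written[name] = write_table(outdir / f"{name}.csv", tab)
    written["provenance"] = write_provenance(
        outdir / "provenance.json", seed=seed, config=config
    )
    return written
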