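"""Plain-text and TIFF exchange formats.

Cell tables travel as CSV with 0/1 marker columns; mask stacks as
multi-page TIFF with channel names and pixel size in the image description;
configurations as YAML.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import tifffile
import yaml

from .simulate import MARKER_CHANNELS, MaskStack, RenderConfig, SimConfig


def write_cells_csv(cells: pd.DataFrame, path) -> None:
    out = cells.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


def read_cells_csv(path, bool_columns: tuple[str, ...] | None = None) -> pd.DataFrame:
    cells = pd.read_csv(path)
    if bool_columns is None:
        bool_columns = tuple(c for c in cells.columns
                             if c in MARKER_CHANNELS
                             or set(cells[c].dropna().unique()) <= {0, 1}
                             and c not in ("id",) and cells[c].dtype != float)
    for col in bool_columns:
        if col in cells.columns:
            cells[col] = cells[col].astype(bool)
    return cells


def save_mask_stack(stack: MaskStack, path) -> None:
    meta = {"channels": stack.channel_names, "pixel_size_um": stack.pixel_size_um}
    pages = np.stack([stack[c].astype(np.uint8) for c in stack.channel_names])
    tifffile.imwrite(path, pages, description=json.dumps(meta))


def load_mask_stack(path) -> MaskStack:
    with tifffile.TiffFile(path) as tif:
        meta = json.loads(tif.pages[0].description)
        pages = tif.asarray()
    if pages.ndim == 2:
        pages = pages[None]
    channels = {name: pages[i].astype(bool)
                for i, name in enumerate(meta["channels"])}
    return MaskStack(channels=channels, pixel_size_um=float(meta["pixel_size_um"]))


def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        return SimConfig.from_dict(yaml.safe_load(fh) or {})


def save_sim_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)


def load_render_config(path) -> RenderConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if "image_shape_px" in d:
        d["image_shape_px"] = tuple(d["image_shape_px"])
    return RenderConfig(**d)


def read_counts_tsv(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index.name = "gene"
    return counts


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def read_de_tsv(path) -> pd.DataFrame:
    de = pd.read_csv(path, sep="\t")
    de.columns = [c.lower() if c.lower() in ("gene", "pvalue") else c for c in de.columns]
    return de
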