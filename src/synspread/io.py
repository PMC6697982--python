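"""File formats: TIFF stacks with JSON channel sidecars, CSV/TSV tables, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .morphometry import RGBSection
from .transfer_quant import ChannelStack
from .transcriptomics import CountMatrix

__all__ = [
    "write_stack", "read_stack",
    "write_section", "read_section",
    "write_counts", "read_counts",
    "read_roi", "write_roi",
    "load_yaml", "dump_yaml",
]


def write_stack(path, stack: ChannelStack) -> None:
    """Multi-page TIFF (pages = channels x z, channel-major) + JSON sidecar."""
    path = Path(path)
    pages = stack.voxels.reshape(-1, *stack.voxels.shape[2:])
    tifffile.imwrite(path, pages)
    meta = dict(channel_map=stack.channel_map, bit_depth=stack.bit_depth,
                pixel_size=stack.pixel_size, z_step=stack.z_step,
                n_z=int(stack.voxels.shape[1]), page_order="channel_major")
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_stack(path) -> ChannelStack:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    pages = tifffile.imread(path)
    n_z = meta["n_z"]
    voxels = pages.reshape(len(meta["channel_map"]), n_z, *pages.shape[1:])
    return ChannelStack(voxels=voxels, channel_map=meta["channel_map"],
                        bit_depth=meta["bit_depth"],
                        pixel_size=meta["pixel_size"], z_step=meta["z_step"])


def write_section(path, section: RGBSection) -> None:
    path = Path(path)
    tifffile.imwrite(path, section.pixels)
    meta = dict(pixel_size=section.pixel_size, provenance=section.provenance)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_section(path) -> RGBSection:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return RGBSection(pixels=tifffile.imread(path),
                      pixel_size=meta.get("pixel_size", 1.0),
                      provenance=meta.get("provenance", str(path)))


def write_counts(counts_path, cm: CountMatrix, samples_path=None) -> None:
    """Counts as genes x samples TSV plus a sample sheet (sample_id, group)."""
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    if samples_path is not None:
        pd.DataFrame({"sample_id": cm.groups.index, "group": cm.groups.values}
                     ).to_csv(samples_path, index=False)


def read_counts(counts_path, samples_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep=None, engine="python", index_col=0)
    sheet = pd.read_csv(samples_path)
    groups = pd.Series(sheet["group"].values, index=sheet["sample_id"].values)
    counts = np.round(counts).astype(int)
    return CountMatrix(counts=counts, groups=groups.reindex(counts.columns))


def read_roi(path) -> list:
    """GeoJSON-style polygon: {"type": "Polygon", "coordinates": [[[x, y], ...]]}.

    Returns the vertex list as (y, x) pixel coordinates.
    """
    obj = json.loads(Path(path).read_text())
    ring = obj["coordinates"][0]
    return [(y, x) for x, y in ring]


def write_roi(path, vertices_yx) -> None:
    ring = [[float(x), float(y)] for y, x in vertices_yx]
    Path(path).write_text(json.dumps(
        {"type": "Polygon", "coordinates": [ring]}, indent=1))


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def dump_yaml(path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))
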