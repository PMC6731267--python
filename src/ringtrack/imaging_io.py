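"""Reading microscopy images and writing masks and tables.

Supported inputs are plain grayscale TIFF (8/16-bit, single- or
multi-page, including OME-TIFF) and 8-bit grayscale PNG.  Channel
assignment is always explicit through a channel map — file order is
never interpreted — because export layouts differ between microscopes:

* one file per channel: ``{"dapi": "dapi.tif", "gh2ax": "gh2ax.tif"}``
* one multi-page file:  ``read_field("stack.ome.tif", {"dapi": 0, "gh2ax": 1})``
* mixed: map values may also be ``(path, page)`` pairs.

Intensities are passed through exactly as stored; no rescaling happens
on read.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .model import (
    CapacityError,
    ChannelImage,
    ChannelRole,
    ConfigurationError,
    FieldOfView,
    FormatError,
    LabelMask,
)

__all__ = [
    "NUCLEUS_TABLE_COLUMNS",
    "read_field",
    "read_channel",
    "write_label_mask",
    "read_label_mask",
    "write_table",
]

#: Fixed column order of the per-nucleus results table.
NUCLEUS_TABLE_COLUMNS = [
    "field_id",
    "condition",
    "nucleus_id",
    "area_px",
    "perimeter_px",
    "centroid_row",
    "centroid_col",
    "eccentricity",
    "circularity",
    "mean_dapi",
    "accepted",
    "rejection_reason",
    "foci_count",
    "foci_density",
    "ring_score",
    "phenotype",
    "pearson_gh2ax_53bp1",
]

_DTYPE_BIT_DEPTH = {np.dtype(np.uint8): 8, np.dtype(np.uint16): 16}


def _load_page(path: str | os.PathLike, page: int | None) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input image not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            index = 0 if page is None else int(page)
            if index >= len(tf.pages):
                raise FormatError(f"{path} has {len(tf.pages)} page(s); page {index} requested")
            arr = tf.pages[index].asarray()
    elif suffix == ".png":
        with Image.open(path) as im:
            arr = np.asarray(im)
        if page not in (None, 0):
            raise FormatError(f"PNG files are single-page; page {page} requested from {path}")
    else:
        raise FormatError(f"unsupported image format: {path}")
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise FormatError(f"{path} is not a single-channel 2-D image (shape {arr.shape})")
    return arr


def read_channel(source, role: ChannelRole | str, *, default_path=None) -> ChannelImage:
    """Read one channel.

    ``source`` is a path, a ``(path, page)`` pair, or a bare page index
    (in which case ``default_path`` must point at the multi-page file).
    """
    if isinstance(source, (tuple, list)):
        path, page = source
    elif isinstance(source, (int, np.integer)):
        if default_path is None:
            raise ConfigurationError("page index given without a multi-page file path")
        path, page = default_path, int(source)
    else:
        path, page = source, None
    arr = _load_page(path, page)
    bit_depth = _DTYPE_BIT_DEPTH.get(arr.dtype)
    if bit_depth is None:
        raise FormatError(f"unsupported bit depth / dtype {arr.dtype} in {path}")
    return ChannelImage(pixels=arr, channel_role=ChannelRole(role), bit_depth=bit_depth)


def read_field(
    paths_or_multipage,
    channel_map: Mapping[str, object],
    condition: str,
    field_id: str | None = None,
    pixel_size_um: float | None = None,
) -> FieldOfView:
    """Assemble a :class:`FieldOfView` from files and an explicit channel map.

    Parameters
    ----------
    paths_or_multipage
        A single multi-page file (when map values are page indices) or
        ignored when every map value carries its own path.
    channel_map
        Maps channel roles (``dapi``, ``gh2ax``, ``p53bp1``) to paths,
        page indices, or ``(path, page)`` pairs.
    condition
        Experimental condition label attached to every nucleus of the field.
    """
    roles = {ChannelRole(r) for r in channel_map}
    for required in (ChannelRole.DAPI, ChannelRole.GH2AX):
        if required not in roles:
            raise ConfigurationError(f"channel_map must assign a {required.value} channel")
    if isinstance(paths_or_multipage, (list, tuple)) and len(paths_or_multipage) == 1:
        paths_or_multipage = paths_or_multipage[0]
    default_path = paths_or_multipage if not isinstance(paths_or_multipage, (list, tuple)) else None
    channels = {
        ChannelRole(role): read_channel(src, role, default_path=default_path)
        for role, src in channel_map.items()
    }
    if field_id is None:
        anchor = default_path or next(iter(channel_map.values()))
        if isinstance(anchor, (tuple, list)):
            anchor = anchor[0]
        field_id = Path(str(anchor)).stem
    return FieldOfView(
        channels=channels,
        field_id=str(field_id),
        condition=condition,
        pixel_size_um=pixel_size_um,
    )


def write_label_mask(mask: LabelMask, path: str | os.PathLike) -> None:
    """Write a label mask as a 16-bit grayscale TIFF (lossless round trip)."""
    if mask.n_objects >= 65536:
        raise CapacityError(f"{mask.n_objects} objects exceed the 16-bit label capacity")
    tifffile.imwrite(Path(path), mask.labels.astype(np.uint16))


def read_label_mask(path: str | os.PathLike) -> LabelMask:
    return LabelMask(labels=tifffile.imread(Path(path)).astype(np.int64))


def write_table(rows: pd.DataFrame | Sequence[Mapping], path: str | os.PathLike) -> None:
    """Write the per-nucleus table as deterministic UTF-8 CSV.

    The column set and order are fixed (:data:`NUCLEUS_TABLE_COLUMNS`),
    rows are sorted by ``(field_id, nucleus_id)``, the decimal mark is
    ``.`` and the line terminator is ``\\n``, so identical inputs yield
    byte-identical files.
    """
    df = pd.DataFrame(rows)
    if df.empty and not len(df.columns):
        df = pd.DataFrame(columns=NUCLEUS_TABLE_COLUMNS)
    missing = set(NUCLEUS_TABLE_COLUMNS) - set(df.columns)
    extra = set(df.columns) - set(NUCLEUS_TABLE_COLUMNS)
    if missing or extra:
        raise ConfigurationError(
            f"table schema mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}"
        )
    df = df[NUCLEUS_TABLE_COLUMNS]
    if len(df):
        df = df.sort_values(["field_id", "nucleus_id"], kind="mergesort").reset_index(drop=True)
    df.to_csv(Path(path), index=False, encoding="utf-8", lineterminator="\n")
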