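"""File interchange: multi-channel TIFF images, label masks, region tables.

Images are channels-first multi-page or OME TIFF; channel names come from
OME metadata when present, else from a sidecar JSON (``<stem>.channels.json``
holding a list of names).  Masks are single-channel integer TIFF or PNG.
Region tables are JSON objects mapping label id to region name.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .sampling import AtlasLabeledImage, MultiplexImage
from .training import ClickSet

__all__ = [
    "read_multiplex_image",
    "write_multiplex_image",
    "read_mask",
    "write_mask",
    "read_region_table",
    "write_region_table",
    "read_clicks",
    "write_clicks",
    "read_atlas",
]


def read_multiplex_image(path) -> MultiplexImage:
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        names: tuple[str, ...] = ()
        if tif.ome_metadata:
            # minimal OME parse: channel Name attributes in document order
            import re

            names = tuple(re.findall(r'<Channel[^>]*\bName="([^"]+)"', tif.ome_metadata))
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"cannot interpret {path} with shape {data.shape} as (C, H, W)")
    sidecar = path.with_suffix("").with_suffix(".channels.json")
    if not names and sidecar.exists():
        names = tuple(json.loads(sidecar.read_text()))
    if names and len(names) != data.shape[0]:
        names = ()
    return MultiplexImage(data, names)


def write_multiplex_image(path, image: MultiplexImage) -> None:
    path = Path(path)
    meta = None
    if image.channel_names:
        meta = {"axes": "CYX", "Channel": {"Name": list(image.channel_names)}}
    tifffile.imwrite(path, image.data, metadata=meta)
    if image.channel_names:
        sidecar = path.with_suffix("").with_suffix(".channels.json")
        sidecar.write_text(json.dumps(list(image.channel_names)))


def read_mask(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        arr = np.asarray(Image.open(path))
    else:
        arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"mask {path} is not single-channel (shape {arr.shape})")
    return arr.astype(np.int64)


def write_mask(path, mask: np.ndarray) -> None:
    path = Path(path)
    mask = np.asarray(mask)
    if path.suffix.lower() == ".png":
        from PIL import Image

        Image.fromarray(mask.astype(np.uint16)).save(path)
    else:
        tifffile.imwrite(path, mask.astype(np.int32))


def read_region_table(path) -> dict[int, str]:
    d = json.loads(Path(path).read_text())
    return {int(k): str(v) for k, v in d.items()}


def write_region_table(path, table: dict[int, str]) -> None:
    Path(path).write_text(json.dumps({str(k): v for k, v in table.items()}, indent=2))


def read_clicks(path, region: str | None = None) -> ClickSet:
    return ClickSet.from_jsonl(Path(path).read_text(), region=region)


def write_clicks(path, clicks: ClickSet) -> None:
    Path(path).write_text(clicks.to_jsonl())


def read_atlas(image_path, mask_path, regions_path=None) -> AtlasLabeledImage:
    image = read_multiplex_image(image_path)
    mask = read_mask(mask_path)
    table = read_region_table(regions_path) if regions_path else {}
    return AtlasLabeledImage(image, mask, table)
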