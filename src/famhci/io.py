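"""Field and table I/O.

Rendered fields are written as multi-page TIFF (one page per channel in the
fixed order nuclear → cellmask → phospholipid → neutral_lipid) with a JSON
sidecar carrying pixel size, channel names, seed and preset name.  Label
masks go to separate int32 TIFFs plus a JSON parent map; feature tables and
summaries are plain CSV.  Channel order is validated against the sidecar on
read, never inferred from intensities.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .synthgen import CHANNEL_ORDER, LabelMasks, MultiChannelImage

__all__ = [
    "write_field",
    "read_field",
    "write_masks",
    "read_masks",
    "write_overlay_png",
]


def write_field(
    directory: str | Path,
    image: MultiChannelImage,
    name: str = "field",
    seed=None,
    preset_name: str | None = None,
) -> Path:
    """Write one field as <name>.tif + <name>.json sidecar; returns the stem."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = np.stack([image.channels[ch] for ch in CHANNEL_ORDER])
    tifffile.imwrite(
        directory / f"{name}.tif", stack, photometric="minisblack"
    )
    sidecar = {
        "channels": list(CHANNEL_ORDER),
        "pixel_size_um": image.pixel_size_um,
        "seed": int(seed) if isinstance(seed, (int, np.integer)) else
                (None if seed is None else str(seed)),
        "preset": preset_name,
    }
    (directory / f"{name}.json").write_text(json.dumps(sidecar, indent=1))
    return directory / name


def read_field(stem: str | Path) -> MultiChannelImage:
    """Read a field written by :func:`write_field` (sidecar required)."""
    stem = Path(stem)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    if sidecar["channels"] != list(CHANNEL_ORDER):
        raise ValueError(
            f"sidecar channel order {sidecar['channels']} does not match "
            f"the expected {list(CHANNEL_ORDER)}"
        )
    stack = tifffile.imread(stem.with_suffix(".tif"))
    channels = {ch: stack[i] for i, ch in enumerate(CHANNEL_ORDER)}
    return MultiChannelImage(channels=channels, pixel_size_um=sidecar["pixel_size_um"])


def write_masks(directory: str | Path, masks: LabelMasks, name: str = "field") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for kind in ("nuclei", "cells", "vacuoles"):
        tifffile.imwrite(
            directory / f"{name}_{kind}.tif", getattr(masks, kind).astype(np.int32)
        )
    (directory / f"{name}_vacuole_parent.json").write_text(
        json.dumps({str(k): int(v) for k, v in masks.vacuole_parent.items()})
    )


def read_masks(directory: str | Path, name: str = "field") -> LabelMasks:
    directory = Path(directory)
    arrays = {
        kind: tifffile.imread(directory / f"{name}_{kind}.tif")
        for kind in ("nuclei", "cells", "vacuoles")
    }
    parent_path = directory / f"{name}_vacuole_parent.json"
    parent = (
        {int(k): int(v) for k, v in json.loads(parent_path.read_text()).items()}
        if parent_path.exists()
        else {}
    )
    return LabelMasks(vacuole_parent=parent, **arrays)


def write_overlay_png(
    path: str | Path, image: MultiChannelImage, masks: LabelMasks
) -> None:
    """QC overlay: cytoplasm channel with cell/nucleus/vacuole boundaries."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from skimage.segmentation import find_boundaries

    base = image.channels["cellmask"].astype(float)
    base = base / max(base.max(), 1.0)
    rgb = np.stack([base, base, base], axis=-1)
    rgb[find_boundaries(masks.cells, mode="outer")] = (1.0, 0.9, 0.1)
    rgb[find_boundaries(masks.nuclei, mode="outer")] = (0.2, 0.4, 1.0)
    rgb[find_boundaries(masks.vacuoles, mode="outer")] = (1.0, 0.2, 0.2)
    plt.imsave(str(path), rgb)
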