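"""Nucleus-seeded cell segmentation and negative-stain vacuole detection.

The protocol mirrors standard high-content image analysis of stained
macrophage fields: nucleated cells are identified from the nuclear channel,
cell bodies are delineated from the cytoplasm channel by marker-based
watershed seeded with the nuclei, and vacuoles are segmented as enclosed
low-intensity ("negative stain") regions within each cell.

All thresholds are relative (Otsu, or a fraction of the per-cell median
cytoplasm intensity), so the output is invariant to a global positive gain
on the intensities.  Areas are measured in pixels and converted to µm²
downstream via ``pixel_size_um**2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import watershed

from .synthgen import LabelMasks, MultiChannelImage

__all__ = [
    "SegmentationParams",
    "segment_nuclei",
    "segment_cells",
    "segment_vacuoles",
    "segment_field",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity

# radius-2 disk used to close pinched cytoplasm strips before the vacuole
# enclosure test
_CLOSE_DISK = (
    np.hypot(*np.mgrid[-2:3, -2:3]) <= 2.0
)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the segmentation protocol.

    ``vacuole_relative_threshold`` is the fraction of a cell's median
    cytoplasm intensity below which a pixel counts as negative stain.
    ``min_vacuole_area_um2`` defaults to 0.5 µm² — below the smallest
    plausible mean single-vacuole area yet above single-pixel noise at a
    0.325 µm pixel.
    """

    nuclear_threshold_method: str = "otsu"
    nuclear_threshold_value: float | None = None
    min_nucleus_area_um2: float = 20.0
    cell_threshold_method: str = "otsu"
    cell_threshold_value: float | None = None
    min_cell_area_um2: float = 50.0
    vacuole_relative_threshold: float = 0.5
    min_vacuole_area_um2: float = 0.5
    max_vacuole_area_fraction: float = 0.5
    exclude_border_cells: bool = True
    smoothing_sigma_px: float = 1.0
    # The cytoplasm channel is thresholded with a lighter blur: heavy
    # smoothing erases the thin cytoplasm strip around membrane-proximal
    # vacuoles, opening their holes to the background.
    cell_smoothing_sigma_px: float = 0.5
    # Vacuoles are small, high-contrast holes: smoothing erodes them, so the
    # negative-stain threshold runs on the raw channel by default.
    vacuole_smoothing_sigma_px: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.vacuole_relative_threshold < 1.0:
            raise ValueError("vacuole_relative_threshold must be in (0,1)")
        if not 0.0 < self.max_vacuole_area_fraction <= 1.0:
            raise ValueError("max_vacuole_area_fraction must be in (0,1]")
        for attr in ("min_nucleus_area_um2", "min_cell_area_um2",
                     "min_vacuole_area_um2"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        for method, value in (
            (self.nuclear_threshold_method, self.nuclear_threshold_value),
            (self.cell_threshold_method, self.cell_threshold_value),
        ):
            if method not in ("otsu", "fixed"):
                raise ValueError("threshold method must be 'otsu' or 'fixed'")
            if method == "fixed" and value is None:
                raise ValueError("fixed threshold requires a threshold value")


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2D intensity image")
    if image.size and image.min() < 0:
        raise ValueError("intensities must be nonnegative")
    return image.astype(np.float64, copy=False)


def _foreground(image, method, value, sigma):
    smoothed = gaussian(image, sigma=sigma, preserve_range=True) if sigma > 0 else image
    if method == "fixed":
        return smoothed > value
    if smoothed.max() == smoothed.min():
        return np.zeros(image.shape, dtype=bool)
    return smoothed > threshold_otsu(smoothed)


def _remove_small(labels: np.ndarray, min_px: float) -> np.ndarray:
    if labels.max() == 0:
        return labels
    counts = np.bincount(labels.ravel())
    kill = counts < min_px
    kill[0] = False
    if kill.any():
        labels = labels.copy()
        labels[kill[labels]] = 0
    return labels


def _relabel(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1, dtype=np.int32)
    return lut[labels]


def segment_nuclei(
    nuclear_channel: np.ndarray,
    params: SegmentationParams,
    pixel_size_um: float,
) -> np.ndarray:
    """Label nuclei: smooth, threshold, split touching nuclei by watershed.

    Touching nuclei are separated by a watershed on the Euclidean distance
    transform; components smaller than ``min_nucleus_area_um2`` are
    removed.  A constant image yields an empty labeling.
    """
    image = _check_image(nuclear_channel)
    fg = _foreground(
        image,
        params.nuclear_threshold_method,
        params.nuclear_threshold_value,
        params.smoothing_sigma_px,
    )
    fg = ndi.binary_fill_holes(fg)
    if not fg.any():
        return np.zeros(image.shape, dtype=np.int32)

    min_px = params.min_nucleus_area_um2 / (pixel_size_um**2)
    dist = ndi.distance_transform_edt(fg)
    min_dist = max(3, int(round(math.sqrt(max(min_px, 1.0) / math.pi))))
    coords = peak_local_max(
        dist, min_distance=min_dist, labels=fg, exclude_border=False
    )
    peaks = np.zeros(image.shape, dtype=bool)
    peaks[tuple(coords.T)] = True
    markers, _ = ndi.label(peaks, structure=_STRUCT8)
    labels = watershed(-dist, markers, mask=fg, connectivity=2)
    labels = _remove_small(labels.astype(np.int32), min_px)
    return _relabel(labels)


def segment_cells(
    cellmask_channel: np.ndarray,
    nuclei: np.ndarray,
    params: SegmentationParams,
    pixel_size_um: float,
) -> np.ndarray:
    """Delineate cell bodies seeded by nuclei.

    Foreground is the thresholded cytoplasm channel with interior holes
    filled (vacuoles belong to the cell body); a marker-based watershed
    from the nucleus labels partitions touching cells along equidistant
    lines.  Foreground with no nucleus is discarded, border-touching cells
    optionally excluded, and each returned cell carries the label of its
    (single) seed nucleus.
    """
    image = _check_image(cellmask_channel)
    nuclei = np.asarray(nuclei)
    if nuclei.shape != image.shape:
        raise ValueError(
            f"nuclei shape {nuclei.shape} does not match image shape {image.shape}"
        )
    if nuclei.max() == 0:
        return np.zeros(image.shape, dtype=np.int32)

    fg = _foreground(
        image,
        params.cell_threshold_method,
        params.cell_threshold_value,
        params.cell_smoothing_sigma_px,
    )
    fg = ndi.binary_fill_holes(fg)
    fg |= nuclei > 0  # a nucleus is always part of its cell

    labels = watershed(
        np.zeros(image.shape, dtype=np.uint8), nuclei, mask=fg, connectivity=2
    ).astype(np.int32)

    if params.exclude_border_cells:
        border = np.unique(
            np.concatenate(
                [labels[0], labels[-1], labels[:, 0], labels[:, -1]]
            )
        )
        border = border[border > 0]
        if border.size:
            labels[np.isin(labels, border)] = 0

    min_px = params.min_cell_area_um2 / (pixel_size_um**2)
    labels = _remove_small(labels, min_px)
    return labels


def segment_vacuoles(
    cellmask_channel: np.ndarray,
    cells: np.ndarray,
    nuclei: np.ndarray,
    params: SegmentationParams,
    pixel_size_um: float,
) -> tuple[np.ndarray, dict[int, int]]:
    """Segment vacuoles as enclosed negative-stain regions within cells.

    Candidates are connected regions (8-connectivity) of pixels below
    ``vacuole_relative_threshold`` × the parent cell's median cytoplasm
    intensity.  The enclosure reference is the cell mask after a small
    morphological closing (radius 2 px) and hole filling: a vacuole hugging
    the membrane can pinch the thresholded cytoplasm strip apart, and the
    closing restores its enclosure, while a genuine boundary notch (open by
    more than ~4 px) stays open and is rejected.  Candidates overlapping
    the nucleus, lying mostly outside the cell proper, smaller than
    ``min_vacuole_area_um2`` or larger than ``max_vacuole_area_fraction``
    of the cell are rejected.  A candidate spanning two cells is split
    along the cell boundary and each part filtered independently.
    """
    image = _check_image(cellmask_channel)
    cells = np.asarray(cells)
    nuclei = np.asarray(nuclei)
    if cells.shape != image.shape or nuclei.shape != image.shape:
        raise ValueError("cells/nuclei labels must match the channel shape")

    vac = np.zeros(image.shape, dtype=np.int32)
    parent: dict[int, int] = {}
    if cells.max() == 0:
        return vac, parent

    smoothed = (
        gaussian(image, sigma=params.vacuole_smoothing_sigma_px, preserve_range=True)
        if params.vacuole_smoothing_sigma_px > 0
        else image
    )
    px2 = pixel_size_um**2
    min_px = params.min_vacuole_area_um2 / px2

    next_id = 0
    objects = ndi.find_objects(cells)
    for idx, sl in enumerate(objects):
        if sl is None:
            continue
        cell_id = idx + 1
        # pad by 3 px so closing and boundary adjacency see past the bbox
        sl = tuple(
            slice(max(0, s.start - 3), min(dim, s.stop + 3))
            for s, dim in zip(sl, image.shape)
        )
        cell_mask = cells[sl] == cell_id
        vals = smoothed[sl][cell_mask]
        median = float(np.median(vals))
        ref = ndi.binary_fill_holes(
            ndi.binary_closing(cell_mask, structure=_CLOSE_DISK)
        )
        cand = ref & (smoothed[sl] < params.vacuole_relative_threshold * median)
        if not cand.any():
            continue
        # enclosure: reject components adjacent (8-conn) to outside pixels
        rim = ndi.binary_dilation(~ref, structure=_STRUCT8)
        nuc_mask = nuclei[sl] > 0
        comp, n = ndi.label(cand, structure=_STRUCT8)
        if n == 0:
            continue
        areas = np.bincount(comp.ravel(), minlength=n + 1)
        inside = np.bincount(comp[cell_mask].ravel(), minlength=n + 1)
        touches_rim = np.zeros(n + 1, dtype=bool)
        touches_rim[np.unique(comp[rim & cand])] = True
        touches_nuc = np.zeros(n + 1, dtype=bool)
        touches_nuc[np.unique(comp[nuc_mask & cand])] = True
        max_px = params.max_vacuole_area_fraction * cell_mask.sum()
        for k in range(1, n + 1):
            if touches_rim[k] or touches_nuc[k]:
                continue
            # mostly within this cell proper (not annexed by the closing)
            if inside[k] < 0.5 * areas[k]:
                continue
            if areas[k] < min_px or areas[k] > max_px:
                continue
            next_id += 1
            vac[sl][comp == k] = next_id
            parent[next_id] = cell_id
    return vac, parent


def segment_field(
    image: MultiChannelImage, params: SegmentationParams | None = None
) -> LabelMasks:
    """Run the full protocol on one rendered field."""
    params = params or SegmentationParams()
    px = image.pixel_size_um
    nuclei = segment_nuclei(image.channels["nuclear"], params, px)
    cells = segment_cells(image.channels["cellmask"], nuclei, params, px)
    # drop nuclei whose cell was discarded, keep shared label ids
    keep = np.unique(cells)
    nuclei = np.where(np.isin(nuclei, keep[keep > 0]), nuclei, 0)
    vac, parent = segment_vacuoles(
        image.channels["cellmask"], cells, nuclei, params, px
    )
    return LabelMasks(nuclei=nuclei, cells=cells, vacuoles=vac, vacuole_parent=parent)
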