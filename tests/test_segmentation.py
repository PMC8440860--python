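"""Segmentation protocol: threshold/watershed oracles on constructed
phantoms, enclosure rules, scale and pixel-size invariances."""

import math

import numpy as np
import pytest

from famhci import (
    SegmentationParams,
    render_field,
    segment_cells,
    segment_field,
    segment_nuclei,
    segment_vacuoles,
)
from famhci.synthgen import FieldSpec

from conftest import disk_pixel_count, make_circle_cell

PX = 0.325
PARAMS = SegmentationParams()


def draw_disk(image, center, radius, value):
    yy, xx = np.mgrid[: image.shape[0], : image.shape[1]]
    mask = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    image[mask] = value
    return mask


def test_uniform_image_has_no_nuclei():
    image = np.full((128, 128), 500.0)
    labels = segment_nuclei(image, PARAMS, PX)
    assert labels.max() == 0


def test_two_disjoint_disks_segment_to_two_accurate_nuclei():
    image = np.full((160, 160), 200.0)
    draw_disk(image, (50, 50), 10, 4000.0)
    draw_disk(image, (110, 110), 10, 4000.0)
    labels = segment_nuclei(image, PARAMS, PX)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    assert len(ids) == 2
    expected = math.pi * 100.0
    for area in counts:
        assert abs(area - expected) / expected < 0.04  # 1-px rim after smoothing


def test_touching_nuclei_split_close_to_nearest_center_assignment():
    image = np.full((120, 120), 200.0)
    c1, c2 = (60, 45), (60, 60)
    draw_disk(image, c1, 10, 4000.0)
    draw_disk(image, c2, 10, 4000.0)
    labels = segment_nuclei(image, PARAMS, PX)
    assert labels.max() == 2
    yy, xx = np.mgrid[:120, :120]
    d1 = np.hypot(yy - c1[0], xx - c1[1])
    d2 = np.hypot(yy - c2[0], xx - c2[1])
    # ignore a 1-px band around the equidistant line
    off_band = np.abs(d1 - d2) > 1.0
    fg = labels > 0
    nearest = np.where(d1 < d2, labels[tuple(np.array(c1))], labels[tuple(np.array(c2))])
    check = fg & off_band
    assert np.array_equal(labels[check], nearest[check])


def test_no_nuclei_means_no_cells_whatever_the_cytoplasm_shows():
    cyto = np.full((100, 100), 200.0)
    draw_disk(cyto, (50, 50), 30, 5000.0)
    cells = segment_cells(cyto, np.zeros((100, 100), dtype=np.int32), PARAMS, PX)
    assert cells.max() == 0


def test_shape_mismatch_raises():
    with pytest.raises(ValueError, match="shape"):
        segment_cells(np.zeros((10, 10)), np.zeros((12, 12), dtype=int), PARAMS, PX)


def test_rendered_cell_area_recovered_within_two_percent(noise_free_spec):
    cell = make_circle_cell(1, (128.0, 128.0), 30.0, 12.0)
    image, _ = render_field([cell], noise_free_spec, seed=0)
    masks = segment_field(image, PARAMS)
    area = (masks.cells == 1).sum()
    truth = disk_pixel_count(30.0)
    assert abs(area - truth) / truth < 0.02
    nuc = (masks.nuclei == 1).sum()
    truth_nuc = disk_pixel_count(12.0)
    assert abs(nuc - truth_nuc) / truth_nuc < 0.05


def test_touching_cells_split_along_equidistant_line_between_nuclei():
    # symmetric phantom: one bright slab, two nuclei mirrored about x=80
    cyto = np.full((160, 160), 100.0)
    cyto[40:120, 20:140] = 5000.0
    nuclear = np.full((160, 160), 100.0)
    draw_disk(nuclear, (80, 50), 10, 4000.0)
    draw_disk(nuclear, (80, 110), 10, 4000.0)
    params = SegmentationParams(exclude_border_cells=False)
    nuclei = segment_nuclei(nuclear, params, PX)
    cells = segment_cells(cyto, nuclei, params, PX)
    assert set(np.unique(cells)) == {0, 1, 2}
    yy, xx = np.mgrid[:160, :160]
    d1 = np.hypot(yy - 80, xx - 50)
    d2 = np.hypot(yy - 80, xx - 110)
    off_band = np.abs(d1 - d2) > 2.0
    fg = cells > 0
    left_label = cells[80, 50]
    right_label = cells[80, 110]
    nearest = np.where(d1 < d2, left_label, right_label)
    sel = fg & off_band
    assert (cells[sel] == nearest[sel]).mean() > 0.999


def test_dark_disks_inside_cell_are_vacuoles_with_accurate_areas():
    cyto = np.full((200, 200), 150.0)
    cell_mask = draw_disk(cyto, (100, 100), 40, 5000.0)
    cells = np.zeros((200, 200), dtype=np.int32)
    cells[cell_mask] = 1
    nuclei = np.zeros_like(cells)
    nuclei[draw_disk(np.zeros((200, 200)), (100, 100), 10, 1) > 0] = 1
    centers = [(100, 70), (75, 100), (125, 115)]
    for (cy, cx), r in zip(centers, (3, 4, 5)):
        draw_disk(cyto, (cy, cx), r, 150.0)
    vac, parent = segment_vacuoles(cyto, cells, nuclei, PARAMS, PX)
    ids, counts = np.unique(vac[vac > 0], return_counts=True)
    assert len(ids) == 3
    assert all(parent[i] == 1 for i in ids)
    for area, r in zip(sorted(counts), (3, 4, 5)):
        assert abs(area - math.pi * r * r) / (math.pi * r * r) <= 0.11


def test_boundary_notch_is_not_a_vacuole():
    cyto = np.full((120, 120), 150.0)
    cell_mask = draw_disk(cyto, (60, 60), 30, 5000.0)
    draw_disk(cyto, (60, 90), 6, 150.0)  # dark notch straddling the outline
    cells = np.zeros((120, 120), dtype=np.int32)
    cells[cell_mask] = 1
    nuclei = np.zeros_like(cells)
    vac, parent = segment_vacuoles(cyto, cells, nuclei, PARAMS, PX)
    assert vac.max() == 0 and parent == {}


def test_candidate_overlapping_nucleus_is_rejected():
    cyto = np.full((120, 120), 150.0)
    cell_mask = draw_disk(cyto, (60, 60), 30, 5000.0)
    draw_disk(cyto, (60, 60), 5, 150.0)  # dark region on the nucleus
    cells = np.zeros((120, 120), dtype=np.int32)
    cells[cell_mask] = 1
    nuclei = np.zeros_like(cells)
    nuclei[draw_disk(np.zeros((120, 120)), (60, 60), 8, 1) > 0] = 1
    vac, _ = segment_vacuoles(cyto, cells, nuclei, PARAMS, PX)
    assert vac.max() == 0


def test_segmentation_invariant_to_global_intensity_gain(rendered_m1_field):
    image = rendered_m1_field["image"]
    masks = segment_field(image, PARAMS)
    scaled = type(image)(
        channels={k: v.astype(np.float64) * 3.7 for k, v in image.channels.items()},
        pixel_size_um=image.pixel_size_um,
    )
    masks_scaled = segment_field(scaled, PARAMS)
    assert np.array_equal(masks.cells, masks_scaled.cells)
    assert np.array_equal(masks.nuclei, masks_scaled.nuclei)
    assert np.array_equal(masks.vacuoles, masks_scaled.vacuoles)


def test_micron_areas_invariant_to_pixel_size():
    """The same physical phantom imaged at half the pixel size yields the
    same µm² areas within discretization tolerance."""
    areas = {}
    for px, scale in ((0.5, 1.0), (0.25, 2.0)):
        size = int(128 * scale)
        spec = FieldSpec(height_px=size, width_px=size, pixel_size_um=px,
                         poisson_noise=False, read_noise_sd=0.0, cells_per_field=1)
        cell = make_circle_cell(1, (size / 2, size / 2), 20.0 * scale, 8.0 * scale,
                                vacuoles=[(0.0, 12.0 * scale, 4.0 * scale)])
        image, _ = render_field([cell], spec, seed=0)
        masks = segment_field(image, PARAMS)
        areas[px] = {
            "cell": (masks.cells == 1).sum() * px * px,
            "vac": (masks.vacuoles > 0).sum() * px * px,
        }
    assert areas[0.5]["cell"] == pytest.approx(areas[0.25]["cell"], rel=0.03)
    assert areas[0.5]["vac"] == pytest.approx(areas[0.25]["vac"], rel=0.10)


def test_segmented_field_nesting_invariants(rendered_m1_field):
    """One nucleus per cell; vacuoles nested in their parent and disjoint
    from the nucleus — on a realistic noisy render."""
    masks = segment_field(rendered_m1_field["image"], PARAMS)
    cell_ids = set(np.unique(masks.cells)) - {0}
    assert cell_ids
    for cid in cell_ids:
        nuc_inside = set(np.unique(masks.nuclei[masks.cells == cid])) - {0}
        assert nuc_inside == {cid}
    for vlabel, parent in masks.vacuole_parent.items():
        pix = masks.vacuoles == vlabel
        assert parent in cell_ids
        assert np.all(masks.cells[pix] == parent)
        assert np.all(masks.nuclei[pix] == 0)
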