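"""Shared fixtures: noise-free field specs, simple geometric phantoms, and
a rendered field reused across segmentation/measurement tests."""

from __future__ import annotations

import math

import numpy as np
import pytest

from famhci import (
    CellGroundTruth,
    FieldSpec,
    builtin_preset,
    generate_field,
)


def make_circle_cell(
    cell_id: int,
    center: tuple[float, float],
    radius_px: float,
    nucleus_radius_px: float,
    vacuoles: list[tuple[float, float, float]] | None = None,
    phospholipid: float = 5e5,
    neutral: float = 4e5,
) -> CellGroundTruth:
    """Perfectly circular cell with a centered circular nucleus."""
    return CellGroundTruth(
        cell_id=cell_id,
        center_px=center,
        axes_px=(radius_px, radius_px),
        orientation_rad=0.0,
        boundary_amp=0.0,
        boundary_lobes=3,
        boundary_phase=0.0,
        nucleus_axes_px=(nucleus_radius_px, nucleus_radius_px),
        nucleus_orientation_rad=0.0,
        nucleus_offset_px=(0.0, 0.0),
        vacuoles=list(vacuoles or []),
        phospholipid_intensity=phospholipid,
        neutral_lipid_intensity=neutral,
        adhered=True,
    )


def disk_pixel_count(radius_px: float) -> int:
    """Brute-force rasterized-disk oracle: pixels with center inside radius."""
    r = int(math.ceil(radius_px)) + 1
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return int((yy * yy + xx * xx <= radius_px * radius_px).sum())


@pytest.fixture(scope="session")
def noise_free_spec() -> FieldSpec:
    return FieldSpec(
        height_px=256,
        width_px=256,
        poisson_noise=False,
        read_noise_sd=0.0,
        cells_per_field=4,
    )


@pytest.fixture(scope="session")
def rendered_m1_field():
    """One noisy m1 field with ground truth (shared, read-only)."""
    preset = builtin_preset("m1_lps_ifng")
    spec = FieldSpec()
    cells, image, truth_masks = generate_field(preset, spec, 20260927)
    return {"cells": cells, "image": image, "truth": truth_masks, "spec": spec}
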