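"""Synthetic generator: sampling determinism and bias, rendering geometry,
cytometry/assay simulators."""

import math

import numpy as np
import pandas as pd
import pytest

from famhci import (
    FieldSpec,
    builtin_preset,
    gate_debris,
    ground_truth_table,
    render_field,
    sample_population,
    simulate_assay_plate,
    simulate_cytometry_events,
)
from famhci.presets import LogNormalSpec, NegBinomialSpec, NormalSpec, PhenotypePreset
from famhci.synthgen import DEFAULT_FSC_MIN, DEFAULT_SSC_MIN

from conftest import disk_pixel_count, make_circle_cell

PX = 0.325


def test_zero_cells_gives_empty_population():
    assert sample_population(builtin_preset("m0"), 0, PX, seed=1) == []


def test_same_seed_reproduces_population_exactly():
    preset = builtin_preset("m1_lps_ifng")
    a = ground_truth_table(sample_population(preset, 50, PX, seed=11), PX)
    b = ground_truth_table(sample_population(preset, 50, PX, seed=11), PX)
    pd.testing.assert_frame_equal(a, b)


def test_invalid_preset_rejected_before_sampling():
    bad = PhenotypePreset(
        name="bad",
        cell_area_um2=NormalSpec(100.0, 5.0),
        nuclear_area_um2=NormalSpec(60.0, 5.0),
        vacuole_count=NegBinomialSpec(40.0),
        vacuole_area_um2=LogNormalSpec(2.0, 0.3),
    )
    with pytest.raises(ValueError):
        sample_population(bad, 10, PX, seed=0)


@pytest.mark.parametrize("name", ["m0", "m1_lps_ifng"])
def test_population_means_recover_preset_parameters(name):
    """Law-of-large-numbers round trip: >=5000 sampled cells reproduce the
    preset means of every geometric feature within 3 SEM."""
    preset = builtin_preset(name)
    cells = sample_population(preset, 6000, PX, seed=42, field_px=(93 * 78, 93 * 78))
    gt = ground_truth_table(cells, PX)
    checks = {
        "cell_area_um2": preset.cell_area_um2.mean,
        "nuclear_area_um2": preset.nuclear_area_um2.mean,
        "n_vacuoles": preset.vacuole_count.mean,
        "total_vacuole_area_um2": preset.vacuole_count.mean
        * preset.vacuole_area_um2.mean,
    }
    for feature, expected in checks.items():
        sem = gt[feature].std() / math.sqrt(len(gt))
        assert gt[feature].mean() == pytest.approx(expected, abs=3 * sem), feature
    single = gt.loc[gt.n_vacuoles > 0, "mean_vacuole_area_um2"]
    sem = single.std() / math.sqrt(len(single))
    assert single.mean() == pytest.approx(preset.vacuole_area_um2.mean, abs=3 * sem)
    adhered = gt["adhered"].mean()
    assert adhered == pytest.approx(preset.adhesion_prob, abs=0.02)


def test_ground_truth_cells_satisfy_structural_invariants():
    cells = sample_population(builtin_preset("m1_lps_ifng"), 200, PX, seed=3,
                              field_px=(93 * 15, 93 * 15))
    for cell in cells:
        nr, nc = cell.nucleus_offset_px
        an = max(cell.nucleus_axes_px)
        # nucleus entirely inside the cell outline
        for theta in np.linspace(0, 2 * math.pi, 32):
            edge = (nr + an * math.sin(theta), nc + an * math.cos(theta))
            rho = math.hypot(*edge)
            assert rho < cell.boundary_radius_at(math.atan2(edge[0], edge[1]))
        for i, (vr, vc, rv) in enumerate(cell.vacuoles):
            # vacuole inside the outline and clear of the nucleus
            rho = math.hypot(vr, vc)
            assert rho + rv < cell.boundary_radius_at(math.atan2(vr, vc))
            assert math.hypot(vr - nr, vc - nc) > min(cell.nucleus_axes_px) + rv
            for vr2, vc2, rv2 in cell.vacuoles[i + 1 :]:
                assert math.hypot(vr - vr2, vc - vc2) > rv + rv2  # disjoint


def test_empty_field_renders_background_only(noise_free_spec):
    image, masks = render_field([], noise_free_spec, seed=0)
    for channel in image.channels.values():
        assert np.all(channel == noise_free_spec.background_level)
    assert masks.nuclei.max() == 0 and masks.cells.max() == 0
    assert masks.vacuoles.max() == 0 and masks.vacuole_parent == {}


def test_rendered_circle_label_area_matches_rasterization_oracle(noise_free_spec):
    cell = make_circle_cell(1, (128.0, 128.0), 30.0, 12.0)
    _, masks = render_field([cell], noise_free_spec, seed=0)
    area = int((masks.cells == 1).sum())
    # a handful of pixels sit exactly on the rim (floating-point ties)
    assert abs(area - disk_pixel_count(30.0)) <= 4
    assert abs(area - math.pi * 30.0**2) / (math.pi * 30.0**2) < 0.02


def test_vacuole_renders_as_background_level_hole(noise_free_spec):
    cell = make_circle_cell(1, (128.0, 128.0), 30.0, 10.0,
                            vacuoles=[(0.0, 18.0, 5.0)])
    image, masks = render_field([cell], noise_free_spec, seed=0)
    hole = masks.vacuoles == 1
    assert hole.sum() == disk_pixel_count(5.0)
    assert np.all(
        image.channels["cellmask"][hole] <= noise_free_spec.background_level
    )
    assert masks.vacuole_parent == {1: 1}


def test_ground_truth_masks_do_not_depend_on_noise_seed():
    spec = FieldSpec(height_px=256, width_px=256, cells_per_field=4)
    cells = sample_population(builtin_preset("m0"), 4, PX, seed=5,
                              field_px=(256, 256))
    _, masks_a = render_field(cells, spec, seed=101)
    _, masks_b = render_field(cells, spec, seed=202)
    assert np.array_equal(masks_a.nuclei, masks_b.nuclei)
    assert np.array_equal(masks_a.cells, masks_b.cells)
    assert np.array_equal(masks_a.vacuoles, masks_b.vacuoles)


def test_cell_outside_field_raises_with_cell_id(noise_free_spec):
    cell = make_circle_cell(7, (10.0, 10.0), 30.0, 10.0)
    with pytest.raises(ValueError, match="cell 7"):
        render_field([cell], noise_free_spec, seed=0)


def test_non_adherent_cells_are_washed_off(noise_free_spec):
    adhered = make_circle_cell(1, (64.0, 64.0), 25.0, 10.0)
    washed = make_circle_cell(2, (190.0, 190.0), 25.0, 10.0)
    washed.adhered = False
    _, masks = render_field([adhered, washed], noise_free_spec, seed=0)
    assert set(np.unique(masks.cells)) == {0, 1}


# -- cytometry simulator -----------------------------------------------------


def test_zero_events_gives_empty_table():
    table = simulate_cytometry_events(builtin_preset("m0"), "beads", 0, seed=1)
    assert len(table) == 0
    assert set(table.columns) >= {"fsc", "ssc", "fl_green", "is_debris_truth"}


def test_debris_fraction_recovered_by_scatter_gate():
    table = simulate_cytometry_events(
        builtin_preset("m0"), "beads", 10000, debris_fraction=0.2, seed=4
    )
    gated = gate_debris(table, DEFAULT_FSC_MIN, DEFAULT_SSC_MIN)
    # binomial 4-sigma band around 8000 retained events
    sigma = math.sqrt(10000 * 0.2 * 0.8)
    assert abs(len(gated) - 8000) < 4 * sigma
    # gate recovers the generating debris labels almost perfectly
    assert not gated["is_debris_truth"].mean() > 0.01


def test_bead_positive_fraction_matches_preset():
    preset = builtin_preset("m0")
    table = simulate_cytometry_events(preset, "beads", 5000, debris_fraction=0.0,
                                      seed=8)
    frac = (table["fl_green"] > 1000).mean()  # beads are far above autofluor
    sigma = math.sqrt(0.51 * 0.49 / 5000)
    assert frac == pytest.approx(preset.bead_positive_fraction, abs=4 * sigma)


def test_mrc1_mode_scales_expression():
    low = simulate_cytometry_events(builtin_preset("m0"), "mrc1", 4000, 0.0, seed=9)
    il4 = simulate_cytometry_events(builtin_preset("m_il4"), "mrc1", 4000, 0.0, seed=9)
    assert il4["fl_green"].median() > low["fl_green"].median()


def test_bad_cytometry_arguments_rejected():
    preset = builtin_preset("m0")
    with pytest.raises(ValueError):
        simulate_cytometry_events(preset, "beads", -1)
    with pytest.raises(ValueError):
        simulate_cytometry_events(preset, "side_scatter", 10)
    with pytest.raises(ValueError):
        simulate_cytometry_events(preset, "beads", 10, debris_fraction=1.5)


# -- assay plate simulator ---------------------------------------------------


def test_assay_plate_requires_two_increasing_standards():
    preset = builtin_preset("m0")
    with pytest.raises(ValueError):
        simulate_assay_plate(preset, "griess", 4, standards=[10.0])
    with pytest.raises(ValueError):
        simulate_assay_plate(preset, "griess", 4, standards=[10.0, 5.0])


def test_noise_free_plate_is_exactly_linear():
    plate = simulate_assay_plate(
        builtin_preset("m1_lps_ifng"), "griess", 6,
        standards=[0, 25, 50, 100], seed=2, noise_sd=0.0
    )
    conc = plate["true_concentration"].to_numpy()
    ab = plate["absorbance"].to_numpy()
    assert np.allclose(ab, 0.01 + 0.005 * conc)
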