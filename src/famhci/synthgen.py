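"""Ground-truthed synthetic data generator.

Emulates four-channel stained macrophage fields (nuclear stain, whole-cell
cytoplasm stain with vacuoles as negative-stain holes, phospholipid stain,
neutral-lipid stain), flow-cytometry-like event tables, and colorimetric
assay plates — every output carries exact ground truth so the downstream
segmentation/measurement chain can be validated without real microscopy
data.

Rendering model
---------------
Cells are ellipses with a low-frequency radial boundary perturbation,
placed on a jittered grid so outlines never overlap or touch the field
border.  The nucleus is a smaller ellipse inside the cell; vacuoles are
disjoint disks in the cytoplasm, rendered as holes (background level) in
the cytoplasm channel.  The phospholipid channel concentrates each cell's
signal in rings around its vacuoles; the neutral-lipid channel deposits it
in punctate droplets.  Per-cell lipid flux is conserved exactly, so the
background-corrected integrated intensity over the true cell mask is an
unbiased readout of the generating intensity.  Noise is Poisson photon
noise on the signal plus additive Gaussian read noise; ground-truth label
masks are fixed before noise injection and do not depend on the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .presets import PhenotypePreset

__all__ = [
    "CellGroundTruth",
    "FieldSpec",
    "MultiChannelImage",
    "LabelMasks",
    "CHANNEL_ORDER",
    "sample_population",
    "render_field",
    "generate_field",
    "ground_truth_table",
    "simulate_cytometry_events",
    "unstained_control",
    "simulate_assay_plate",
]

CHANNEL_ORDER = ("nuclear", "cellmask", "phospholipid", "neutral_lipid")

# Shape limits: eccentricity and boundary-perturbation ranges are kept small
# enough that a cell always fits in its grid slot (see _grid_centers).
_MAX_AXIS_RATIO = 1.2
_MAX_BOUNDARY_AMP = 0.08
_AREA_TRUNC_SD = 2.5  # symmetric truncation keeps the mean unbiased
_GRID_JITTER_PX = 4.0

# Rendering amplitudes (counts on a 16-bit scale).
_NUCLEAR_AMP = 12000.0
_CYTOPLASM_AMP = 15000.0
_PHOSPHOLIPID_BASE_FLUX = 5.0e5  # per-cell integrated counts at scale 1.0
_NEUTRAL_BASE_FLUX = 4.0e5
_LIPID_SIGMA_LOG = 0.30  # per-cell lognormal spread of lipid flux


@dataclass
class CellGroundTruth:
    """Exact geometry and signal parameters of one synthetic cell.

    The cell outline in polar coordinates around ``center_px`` is the
    ellipse radius modulated by ``1 + amp*cos(lobes*(theta-phase))`` and
    rescaled so the enclosed area is exactly ``pi*a*b``.
    """

    cell_id: int
    center_px: tuple[float, float]  # (row, col)
    axes_px: tuple[float, float]  # (semi-major a, semi-minor b)
    orientation_rad: float
    boundary_amp: float
    boundary_lobes: int
    boundary_phase: float
    nucleus_axes_px: tuple[float, float]
    nucleus_orientation_rad: float
    nucleus_offset_px: tuple[float, float]
    vacuoles: list[tuple[float, float, float]]  # (d_row, d_col, radius)
    phospholipid_intensity: float
    neutral_lipid_intensity: float
    adhered: bool

    @property
    def max_radius_px(self) -> float:
        return self.axes_px[0] * (1.0 + self.boundary_amp) / self._area_norm

    @property
    def _area_norm(self) -> float:
        return math.sqrt(1.0 + 0.5 * self.boundary_amp**2)

    def boundary_radius(self, theta: np.ndarray) -> np.ndarray:
        """Outline radius at field-frame polar angle(s) ``theta``."""
        a, b = self.axes_px
        t = theta - self.orientation_rad
        r_ell = a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)
        mod = 1.0 + self.boundary_amp * np.cos(
            self.boundary_lobes * (t - self.boundary_phase)
        )
        return r_ell * mod / self._area_norm

    def boundary_radius_at(self, theta: float) -> float:
        """Scalar fast path of :meth:`boundary_radius` (sampling hot loop)."""
        a, b = self.axes_px
        t = theta - self.orientation_rad
        r_ell = a * b / math.hypot(b * math.cos(t), a * math.sin(t))
        mod = 1.0 + self.boundary_amp * math.cos(
            self.boundary_lobes * (t - self.boundary_phase)
        )
        return r_ell * mod / self._area_norm

    def min_boundary_radius(self) -> float:
        """Lower bound on the outline radius (for containment checks)."""
        a, b = self.axes_px
        return b * (1.0 - self.boundary_amp) / self._area_norm


@dataclass(frozen=True)
class FieldSpec:
    """Imaging-field geometry and noise model.

    Defaults emulate a 40x high-content imager: 0.325 µm pixels, 1024²
    16-bit fields, read noise 2% of the dynamic range, Poisson photon
    noise on.  ``cells_per_field`` = 121 so a 9-field well carries
    ~1000–2000 measurable cells.
    """

    height_px: int = 1024
    width_px: int = 1024
    pixel_size_um: float = 0.325
    bit_depth: int = 16
    background_level: float = 3000.0
    read_noise_sd: float = 0.02 * 65535.0
    poisson_noise: bool = True
    cells_per_field: int = 121

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("field dimensions must be positive")

    @property
    def max_intensity(self) -> float:
        return float(2**self.bit_depth - 1)


@dataclass
class MultiChannelImage:
    """Rendered field: channel name -> 2D intensity array."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class LabelMasks:
    """Integer label images (0 = background) plus vacuole->cell parent map."""

    nuclei: np.ndarray
    cells: np.ndarray
    vacuoles: np.ndarray
    vacuole_parent: dict[int, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# population sampling
# ---------------------------------------------------------------------------


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated symmetrically at ±_AREA_TRUNC_SD (unbiased)."""
    if sd == 0:
        return mean
    while True:
        x = rng.normal(mean, sd)
        if abs(x - mean) <= _AREA_TRUNC_SD * sd:
            return x


def _lognormal_mean(rng: np.random.Generator, mean: float, sigma: float, size=None):
    mu = math.log(mean) - 0.5 * sigma * sigma
    return rng.lognormal(mu, sigma, size=size)


def _neg_binomial(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _grid_centers(
    n_cells: int, height_px: int, width_px: int, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Jittered-grid centers; returns (centers, slot radius available)."""
    n_side = max(1, math.ceil(math.sqrt(n_cells)))
    pitch_r = height_px / n_side
    pitch_c = width_px / n_side
    slots = [
        ((i + 0.5) * pitch_r, (j + 0.5) * pitch_c)
        for i in range(n_side)
        for j in range(n_side)
    ]
    idx = rng.permutation(len(slots))[:n_cells]
    jitter = rng.uniform(-_GRID_JITTER_PX, _GRID_JITTER_PX, size=(n_cells, 2))
    centers = np.asarray([slots[i] for i in idx], dtype=float).reshape(-1, 2) + jitter
    # space guaranteed per slot after jitter; 1 px slack against neighbours
    avail = min(pitch_r, pitch_c) / 2.0 - _GRID_JITTER_PX - 1.0
    return centers, avail


def sample_population(
    preset: PhenotypePreset,
    n_cells: int,
    pixel_size_um: float,
    seed,
    field_px: tuple[int, int] | None = None,
) -> list[CellGroundTruth]:
    """Draw ``n_cells`` ground-truth cells from a phenotype preset.

    Cells are placed on a jittered grid inside ``field_px`` (defaults to
    the 1024² field of :class:`FieldSpec`).  Per-cell geometry realizes the
    preset distributions; rejection resampling enforces the structural
    invariants (nucleus inside the cell, vacuoles inside the cytoplasm,
    pairwise disjoint, clear of the nucleus).  The vacuole-count mean is
    proportional to the cell's sampled area, which pins the population mean
    of total-vacuole-area/cell-area at the preset ratio.

    A fixed ``seed`` reproduces the population bit-for-bit.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    preset.validate()
    if n_cells == 0:
        return []
    rng = np.random.default_rng(seed)
    if field_px is None:
        field_px = (FieldSpec.height_px, FieldSpec.width_px)
    centers, avail = _grid_centers(n_cells, field_px[0], field_px[1], rng)
    if avail <= 3.0:
        raise ValueError(
            f"field {field_px} too small for {n_cells} cells of this size"
        )

    px2 = pixel_size_um * pixel_size_um
    mean_area = preset.cell_area_um2.mean
    cells: list[CellGroundTruth] = []
    for i in range(n_cells):
        cell = _sample_cell(preset, rng, i + 1, tuple(centers[i]), avail,
                            pixel_size_um, px2, mean_area)
        cells.append(cell)
    return cells


def _sample_cell(
    preset: PhenotypePreset,
    rng: np.random.Generator,
    cell_id: int,
    center: tuple[float, float],
    avail_radius_px: float,
    pixel_size_um: float,
    px2: float,
    preset_area_mean: float,
) -> CellGroundTruth:
    for _ in range(200):
        area_um2 = _truncated_normal(
            rng, preset.cell_area_um2.mean, preset.cell_area_um2.sd
        )
        nuc_um2 = _truncated_normal(
            rng, preset.nuclear_area_um2.mean, preset.nuclear_area_um2.sd
        )
        if area_um2 <= nuc_um2 or nuc_um2 <= 0:
            continue
        r_eq = math.sqrt(area_um2 / math.pi) / pixel_size_um
        if r_eq + 2 > avail_radius_px:
            continue
        q = rng.uniform(1.0, _MAX_AXIS_RATIO)
        amp = rng.uniform(0.0, _MAX_BOUNDARY_AMP)
        # shrink eccentricity/perturbation (not area) if the slot is tight
        while r_eq * math.sqrt(q) * (1 + amp) + 2 > avail_radius_px and (
            q > 1.0 or amp > 0.0
        ):
            q = 1.0 + 0.5 * (q - 1.0)
            amp *= 0.5
            if q < 1.005 and amp < 0.005:
                q, amp = 1.0, 0.0
        if r_eq * math.sqrt(q) * (1 + amp) + 2 > avail_radius_px:
            continue
        a = r_eq * math.sqrt(q)
        b = r_eq / math.sqrt(q)
        lobes = int(rng.integers(3, 6))
        phase = rng.uniform(0, 2 * math.pi)
        orient = rng.uniform(0, math.pi)
        norm = math.sqrt(1.0 + 0.5 * amp * amp)
        min_rho = b * (1 - amp) / norm

        # nucleus: mild ellipse, offset kept fully inside the outline
        rn_eq = math.sqrt(nuc_um2 / math.pi) / pixel_size_um
        qn = rng.uniform(1.0, 1.1)
        an, bn = rn_eq * math.sqrt(qn), rn_eq / math.sqrt(qn)
        max_off = min_rho - an - 2.0
        if max_off < 0:
            continue  # resample the (area, nucleus) pair jointly
        off_r = max_off * math.sqrt(rng.uniform()) if max_off > 0 else 0.0
        off_t = rng.uniform(0, 2 * math.pi)
        nuc_off = (off_r * math.sin(off_t), off_r * math.cos(off_t))
        nuc_orient = rng.uniform(0, math.pi)

        cell = CellGroundTruth(
            cell_id=cell_id,
            center_px=center,
            axes_px=(a, b),
            orientation_rad=orient,
            boundary_amp=amp,
            boundary_lobes=lobes,
            boundary_phase=phase,
            nucleus_axes_px=(an, bn),
            nucleus_orientation_rad=nuc_orient,
            nucleus_offset_px=nuc_off,
            vacuoles=[],
            phospholipid_intensity=preset.phospholipid_scale
            * _lipid_flux(rng, _PHOSPHOLIPID_BASE_FLUX),
            neutral_lipid_intensity=preset.neutral_lipid_scale
            * _lipid_flux(rng, _NEUTRAL_BASE_FLUX),
            adhered=bool(rng.uniform() < preset.adhesion_prob),
        )
        _place_vacuoles(cell, preset, rng, area_um2, preset_area_mean,
                        pixel_size_um)
        return cell
    raise RuntimeError("could not sample a cell satisfying the invariants")


def _lipid_flux(rng: np.random.Generator, base: float) -> float:
    return float(_lognormal_mean(rng, base, _LIPID_SIGMA_LOG))


def _place_vacuoles(
    cell: CellGroundTruth,
    preset: PhenotypePreset,
    rng: np.random.Generator,
    area_um2: float,
    preset_area_mean: float,
    pixel_size_um: float,
) -> None:
    count_mean = preset.vacuole_count.mean * area_um2 / preset_area_mean
    k = _neg_binomial(rng, count_mean, preset.vacuole_count.dispersion)
    nr, nc = cell.nucleus_offset_px
    an, bn = cell.nucleus_axes_px
    n_orient = cell.nucleus_orientation_rad
    placed: list[tuple[float, float, float]] = []
    # draw the whole size multiset first, then place largest-first: big
    # vacuoles need contiguous space, small ones fill the remaining gaps,
    # so placement failures (which would bias the size distribution) are rare
    areas_um2 = _lognormal_mean(
        rng, preset.vacuole_area_um2.mean, preset.vacuole_area_um2.sigma_log, size=k
    )
    for v_um2 in sorted(np.atleast_1d(areas_um2), reverse=True):
        rv = math.sqrt(float(v_um2) / math.pi) / pixel_size_um
        ok = False
        for _attempt in range(300):
            theta = rng.uniform(0, 2 * math.pi)
            # clearance > √2 guarantees a cytoplasm strip pixel between the
            # vacuole and the background in every raster direction
            rho_max = cell.boundary_radius_at(theta) - rv - 1.6
            if rho_max <= 0:
                continue
            rho = rho_max * math.sqrt(rng.uniform())
            dr, dc = rho * math.sin(theta), rho * math.cos(theta)
            # clear of nucleus: ellipse radius along the ray from its center
            phi = math.atan2(dr - nr, dc - nc) - n_orient
            n_edge = an * bn / math.hypot(bn * math.cos(phi), an * math.sin(phi))
            if math.hypot(dr - nr, dc - nc) < n_edge + rv + 1.2:
                continue
            # center gap > sqrt(2) px of cytoplasm so 8-connected rasterized
            # disks can never merge
            if any(
                math.hypot(dr - pr, dc - pc) < prv + rv + 1.6
                for pr, pc, prv in placed
            ):
                continue
            placed.append((dr, dc, rv))
            ok = True
            break
        if not ok:
            # exhaustive polar-grid fallback: random rejection only misses
            # when the cytoplasm is nearly saturated, so scan for any pocket
            pos = _grid_position(cell, rv, placed, (nr, nc, an, bn, n_orient), rng)
            if pos is not None:
                placed.append((pos[0], pos[1], rv))
    cell.vacuoles = placed


def _grid_position(cell, rv, placed, nucleus, rng):
    nr, nc, an, bn, n_orient = nucleus
    theta = np.linspace(0, 2 * math.pi, 128, endpoint=False) + rng.uniform(
        0, 2 * math.pi / 128
    )
    rho_max = cell.boundary_radius(theta) - rv - 1.6
    keep = rho_max > 0
    if not keep.any():
        return None
    theta, rho_max = theta[keep], rho_max[keep]
    frac = np.linspace(0.0, 1.0, 24)[None, :]
    rho = rho_max[:, None] * frac
    dr = rho * np.sin(theta)[:, None]
    dc = rho * np.cos(theta)[:, None]
    phi = np.arctan2(dr - nr, dc - nc) - n_orient
    n_edge = an * bn / np.hypot(bn * np.cos(phi), an * np.sin(phi))
    feasible = np.hypot(dr - nr, dc - nc) >= n_edge + rv + 1.2
    for pr, pc, prv in placed:
        feasible &= np.hypot(dr - pr, dc - pc) >= prv + rv + 1.6
    idx = np.flatnonzero(feasible.ravel())
    if idx.size == 0:
        return None
    pick = idx[rng.integers(idx.size)]
    return float(dr.ravel()[pick]), float(dc.ravel()[pick])


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _cell_bbox(cell: CellGroundTruth, shape: tuple[int, int]):
    r0, c0 = cell.center_px
    rad = cell.max_radius_px + 2.0
    rmin = max(0, int(math.floor(r0 - rad)))
    rmax = min(shape[0], int(math.ceil(r0 + rad)) + 1)
    cmin = max(0, int(math.floor(c0 - rad)))
    cmax = min(shape[1], int(math.ceil(c0 + rad)) + 1)
    return rmin, rmax, cmin, cmax


def _inside_cell(cell: CellGroundTruth, dy: np.ndarray, dx: np.ndarray) -> np.ndarray:
    theta = np.arctan2(dy, dx)
    rho = np.hypot(dy, dx)
    return rho <= cell.boundary_radius(theta)


def _inside_ellipse(dy, dx, axes, orient) -> np.ndarray:
    a, b = axes
    ct, st = math.cos(orient), math.sin(orient)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def render_field(
    cells: Sequence[CellGroundTruth],
    spec: FieldSpec,
    seed,
) -> tuple[MultiChannelImage, LabelMasks]:
    """Render a population into a four-channel field plus ground-truth labels.

    Only ``adhered`` cells are rendered (non-adherent cells wash off during
    staining); label masks reflect pre-noise geometry exactly.  Raises if a
    cell's outline does not fit inside the field (error names the cell).
    """
    rng = np.random.default_rng(seed)
    shape = (spec.height_px, spec.width_px)

    nuclei = np.zeros(shape, dtype=np.int32)
    cell_lab = np.zeros(shape, dtype=np.int32)
    vac_lab = np.zeros(shape, dtype=np.int32)
    vac_parent: dict[int, int] = {}

    nuclear = np.full(shape, spec.background_level, dtype=np.float64)
    cellmask = np.full(shape, spec.background_level, dtype=np.float64)
    phospho = np.full(shape, spec.background_level, dtype=np.float64)
    neutral = np.full(shape, spec.background_level, dtype=np.float64)

    vac_id = 0
    for cell in cells:
        if not cell.adhered:
            continue
        r0, c0 = cell.center_px
        rad = cell.max_radius_px
        if (
            r0 - rad < 0
            or c0 - rad < 0
            or r0 + rad > spec.height_px - 1
            or c0 + rad > spec.width_px - 1
        ):
            raise ValueError(
                f"cell {cell.cell_id} does not fit in the "
                f"{spec.height_px}x{spec.width_px} field"
            )
        rmin, rmax, cmin, cmax = _cell_bbox(cell, shape)
        rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
        dy = rr - r0
        dx = cc - c0
        inside = _inside_cell(cell, dy, dx)

        box = (slice(rmin, rmax), slice(cmin, cmax))
        cell_lab[box][inside] = cell.cell_id

        ndy = dy - cell.nucleus_offset_px[0]
        ndx = dx - cell.nucleus_offset_px[1]
        nuc = inside & _inside_ellipse(
            ndy, ndx, cell.nucleus_axes_px, cell.nucleus_orientation_rad
        )
        nuclei[box][nuc] = cell.cell_id

        hole = np.zeros_like(inside)
        ring_weight = np.zeros(inside.shape, dtype=np.float64)
        for vr, vc, rv in cell.vacuoles:
            d2 = (dy - vr) ** 2 + (dx - vc) ** 2
            disk = d2 <= rv * rv
            if not disk.any():
                continue
            vac_id += 1
            vac_lab[box][disk & inside] = vac_id
            vac_parent[vac_id] = cell.cell_id
            hole |= disk
            ring = inside & ~disk & (d2 <= (rv + 2.0) ** 2)
            ring_weight[ring] += 1.0

        nuc_amp = _NUCLEAR_AMP * _lognormal_mean(rng, 1.0, 0.15)
        cyt_amp = _CYTOPLASM_AMP * _lognormal_mean(rng, 1.0, 0.10)
        nuclear[box][nuc] += nuc_amp
        cellmask[box][inside & ~hole] += cyt_amp  # vacuoles stay at background

        _deposit_phospholipid(
            phospho[box], inside, ring_weight, cell.phospholipid_intensity
        )
        _deposit_droplets(
            neutral[box], inside, cell.neutral_lipid_intensity, rng, dy, dx, cell
        )

    masks = LabelMasks(nuclei=nuclei, cells=cell_lab, vacuoles=vac_lab,
                       vacuole_parent=vac_parent)

    channels = {}
    for name, img in (
        ("nuclear", nuclear),
        ("cellmask", cellmask),
        ("phospholipid", phospho),
        ("neutral_lipid", neutral),
    ):
        noisy = img
        if spec.poisson_noise:
            noisy = rng.poisson(np.clip(noisy, 0, None)).astype(np.float64)
        if spec.read_noise_sd > 0:
            noisy = noisy + rng.normal(0.0, spec.read_noise_sd, size=img.shape)
        channels[name] = np.clip(noisy, 0, spec.max_intensity).astype(np.uint16)

    return MultiChannelImage(channels=channels, pixel_size_um=spec.pixel_size_um), masks


def _deposit_phospholipid(target, inside, ring_weight, flux) -> None:
    """70% of the cell's phospholipid flux in vacuole rings, 30% diffuse."""
    n_in = int(inside.sum())
    if n_in == 0:
        return
    ring_total = ring_weight.sum()
    ring_frac = 0.7 if ring_total > 0 else 0.0
    if ring_total > 0:
        target[...] += flux * ring_frac * ring_weight / ring_total
    target[inside] += flux * (1.0 - ring_frac) / n_in


def _deposit_droplets(target, inside, flux, rng, dy, dx, cell) -> None:
    """85% of neutral-lipid flux in Gaussian droplets, 15% diffuse.

    Droplet kernels are renormalized over the in-cell pixel set so the
    deposited flux equals ``flux`` exactly.
    """
    n_in = int(inside.sum())
    if n_in == 0:
        return
    n_drop = int(rng.integers(4, 10))
    droplet_flux = 0.85 * flux / n_drop
    sigma = 1.5
    for _ in range(n_drop):
        theta = rng.uniform(0, 2 * math.pi)
        rho_max = cell.boundary_radius_at(theta) - 2.0
        rho = max(0.0, rho_max) * math.sqrt(rng.uniform())
        pr, pc = rho * math.sin(theta), rho * math.cos(theta)
        w = np.exp(-((dy - pr) ** 2 + (dx - pc) ** 2) / (2 * sigma * sigma))
        w[~inside] = 0.0
        total = w.sum()
        if total > 0:
            target[...] += droplet_flux * w / total
    target[inside] += 0.15 * flux / n_in


def generate_field(
    preset: PhenotypePreset, spec: FieldSpec, seed
) -> tuple[list[CellGroundTruth], MultiChannelImage, LabelMasks]:
    """Sample one field's population from ``preset`` and render it."""
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_pop, s_render = ss.spawn(2)
    cells = sample_population(
        preset,
        spec.cells_per_field,
        spec.pixel_size_um,
        s_pop,
        field_px=(spec.height_px, spec.width_px),
    )
    image, masks = render_field(cells, spec, s_render)
    return cells, image, masks


def ground_truth_table(
    cells: Sequence[CellGroundTruth], pixel_size_um: float
) -> pd.DataFrame:
    """Per-cell ground-truth features (µm² areas from exact geometry)."""
    px2 = pixel_size_um * pixel_size_um
    rows = []
    for c in cells:
        vac_areas = [math.pi * rv * rv * px2 for _, _, rv in c.vacuoles]
        area = math.pi * c.axes_px[0] * c.axes_px[1] * px2
        total_v = float(sum(vac_areas))
        rows.append(
            {
                "cell_id": c.cell_id,
                "adhered": c.adhered,
                "cell_area_um2": area,
                "nuclear_area_um2": math.pi
                * c.nucleus_axes_px[0]
                * c.nucleus_axes_px[1]
                * px2,
                "n_vacuoles": len(vac_areas),
                "mean_vacuole_area_um2": float(np.mean(vac_areas)) if vac_areas else 0.0,
                "total_vacuole_area_um2": total_v,
                "pct_area_vacuoles": 100.0 * total_v / area,
                "phospholipid_intensity": c.phospholipid_intensity,
                "neutral_lipid_intensity": c.neutral_lipid_intensity,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cytometry and assay simulators
# ---------------------------------------------------------------------------

# Nominal scatter model: cells sit well inside the (fsc >= 2000, ssc >= 1200)
# gate; debris sits well below it.
CELL_FSC = (5000.0, 800.0)
CELL_SSC = (3000.0, 600.0)
DEBRIS_FSC = (800.0, 300.0)
DEBRIS_SSC = (500.0, 200.0)
DEFAULT_FSC_MIN = 2000.0
DEFAULT_SSC_MIN = 1200.0

_AUTOFLUOR_MEAN = 100.0
_AUTOFLUOR_SIGMA = 0.4
_BEAD_UNIT_INTENSITY = 2000.0
_MRC1_UNIT_INTENSITY = 500.0
_MRC1_SIGMA = 0.5


def simulate_cytometry_events(
    preset: PhenotypePreset,
    mode: str,
    n_events: int,
    debris_fraction: float = 0.1,
    seed=None,
) -> pd.DataFrame:
    """Simulate a flow-cytometry event table (fsc, ssc, fl_green).

    ``mode='beads'``: green fluorescence is autofluorescence plus
    bead_count × per-bead intensity, with bead counts drawn from the
    preset's zero-inflated distribution.  ``mode='mrc1'``: lognormal
    surface expression scaled by ``mrc1_scale``.  ``is_debris_truth``
    records the generating class of each event.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if not 0.0 <= debris_fraction <= 1.0:
        raise ValueError("debris_fraction must be in [0,1]")
    if mode not in ("beads", "mrc1"):
        raise ValueError(f"mode must be 'beads' or 'mrc1', got {mode!r}")
    rng = np.random.default_rng(seed)
    cols = ["event_id", "fsc", "ssc", "fl_green", "is_debris_truth"]
    if n_events == 0:
        return pd.DataFrame(columns=cols).astype(
            {"event_id": int, "is_debris_truth": bool}
        )

    is_debris = rng.uniform(size=n_events) < debris_fraction
    n_deb = int(is_debris.sum())
    n_cell = n_events - n_deb

    fsc = np.empty(n_events)
    ssc = np.empty(n_events)
    fsc[~is_debris] = rng.normal(*CELL_FSC, size=n_cell)
    ssc[~is_debris] = rng.normal(*CELL_SSC, size=n_cell)
    fsc[is_debris] = rng.normal(*DEBRIS_FSC, size=n_deb)
    ssc[is_debris] = rng.normal(*DEBRIS_SSC, size=n_deb)
    np.clip(fsc, 0, None, out=fsc)
    np.clip(ssc, 0, None, out=ssc)

    fl = _lognormal_mean(rng, _AUTOFLUOR_MEAN, _AUTOFLUOR_SIGMA, size=n_events)
    if mode == "beads":
        positive = rng.uniform(size=n_cell) < preset.bead_count.positive_fraction
        counts = np.zeros(n_cell)
        n_pos = int(positive.sum())
        counts[positive] = 1 + rng.poisson(preset.bead_count.extra_mean, size=n_pos)
        per_bead = _lognormal_mean(rng, _BEAD_UNIT_INTENSITY, 0.1, size=n_cell)
        fl[~is_debris] += counts * per_bead
    else:
        fl[~is_debris] += _lognormal_mean(
            rng, _MRC1_UNIT_INTENSITY * preset.mrc1_scale, _MRC1_SIGMA, size=n_cell
        )

    return pd.DataFrame(
        {
            "event_id": np.arange(n_events),
            "fsc": fsc,
            "ssc": ssc,
            "fl_green": fl,
            "is_debris_truth": is_debris,
        }
    )


def unstained_control(preset: PhenotypePreset) -> PhenotypePreset:
    """Control preset whose events carry only autofluorescence.

    Used to derive the positivity threshold: the bead-free (or
    secondary-only) control of the same population.
    """
    from dataclasses import replace

    from .presets import BeadCountSpec

    return replace(
        preset,
        name=preset.name + "_control",
        bead_count=BeadCountSpec(0.0, 0.0),
        mrc1_scale=0.0,
    )


# Assay standard-curve generating lines (AU vs concentration).
_ASSAY_LINES = {
    "griess": (0.005, 0.01),  # slope AU/µM, intercept AU
    "arginase": (0.008, 0.05),  # slope AU per U/L equivalent
}


def simulate_assay_plate(
    preset: PhenotypePreset,
    assay: str,
    n_wells: int,
    standards: Sequence[float],
    seed=None,
    noise_sd: float = 0.005,
) -> pd.DataFrame:
    """Simulate a colorimetric plate: standard wells plus sample wells.

    Standard-well absorbance = intercept + slope·concentration + noise;
    sample wells draw a true level from the preset (nitrite for Griess,
    arginase activity otherwise) and pass it through the same line.  The
    returned table keeps ``true_concentration`` for recovery checks.
    """
    standards = list(standards)
    if len(standards) < 2:
        raise ValueError("at least 2 standard concentrations required")
    if any(b <= a for a, b in zip(standards, standards[1:])):
        raise ValueError("standards must be strictly increasing")
    if assay not in _ASSAY_LINES:
        raise ValueError(f"assay must be one of {sorted(_ASSAY_LINES)}")
    rng = np.random.default_rng(seed)
    slope, intercept = _ASSAY_LINES[assay]
    level = preset.nitrite_um if assay == "griess" else preset.arginase_u_per_l

    rows = []
    for i, conc in enumerate(standards):
        ab = intercept + slope * conc + rng.normal(0.0, noise_sd)
        rows.append(
            {"well": f"S{i+1}", "role": "standard", "true_concentration": conc,
             "absorbance": ab}
        )
    for j in range(n_wells):
        conc = max(0.0, rng.normal(level.mean, level.sd))
        ab = intercept + slope * conc + rng.normal(0.0, noise_sd)
        rows.append(
            {"well": f"W{j+1}", "role": "sample", "true_concentration": conc,
             "absorbance": ab}
        )
    return pd.DataFrame(rows)
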