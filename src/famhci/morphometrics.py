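"""Per-cell morphometric features and population summaries.

Features per cell: nuclear and cellular area, vacuole count, mean and total
vacuole area, percent of the cell occupied by vacuoles, and
background-corrected integrated lipid intensities.  Population summaries
aggregate cell → well mean → experiment mean and report the mean ± SEM over
experiment means (the experiment, not the cell, is the unit of
replication); the pooled per-cell SD is also emitted for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .synthgen import LabelMasks, MultiChannelImage

__all__ = [
    "FEATURES",
    "PopulationSummary",
    "measure_cells",
    "summarize_population",
    "adherence_fraction",
]

FEATURES = (
    "nuclear_area_um2",
    "cell_area_um2",
    "n_vacuoles",
    "mean_vacuole_area_um2",
    "total_vacuole_area_um2",
    "pct_area_vacuoles",
    "phospholipid_intensity",
    "neutral_lipid_intensity",
)

_REQUIRED_CHANNELS = ("phospholipid", "neutral_lipid")


@dataclass
class PopulationSummary:
    """Mean ± SEM (over experiment means) of every feature for one condition."""

    condition: str
    n_cells: int
    n_experiments: int
    means: dict[str, float]
    sems: dict[str, float]  # NaN when only one experiment is available
    pooled_sd: dict[str, float] = field(default_factory=dict)
    adherent_pct_of_control: float | None = None


def _label_sums(values: np.ndarray, labels: np.ndarray, ids: np.ndarray) -> np.ndarray:
    return ndi.sum_labels(values, labels=labels, index=ids)


def measure_cells(
    masks: LabelMasks,
    image: MultiChannelImage,
    well_id: str = "",
    field_id: str = "",
    exclude_vacuole_free_from_mean: bool = False,
) -> pd.DataFrame:
    """Measure the per-cell feature table for one field.

    Areas are pixel counts × ``pixel_size_um**2`` (pixel counts are kept
    alongside).  Lipid intensities are Σ(channel − background) over the
    cell's filled mask, clipped at 0, with the background estimated as the
    median intensity outside all cells.  ``mean_vacuole_area_um2`` of a
    vacuole-free cell is 0 by default so population averages stay defined;
    set ``exclude_vacuole_free_from_mean`` to report NaN instead.
    """
    for name in _REQUIRED_CHANNELS:
        if name not in image.channels:
            raise ValueError(f"missing channel {name!r}")
    cells = masks.cells
    if cells.shape != image.shape:
        raise ValueError("masks and image must share one shape")

    px2 = image.pixel_size_um**2
    ids = np.unique(cells)
    ids = ids[ids > 0]
    if ids.size == 0:
        return pd.DataFrame(
            columns=["well_id", "field_id", "cell_id", "cell_area_px2",
                     "nuclear_area_px2", *FEATURES]
        )

    cell_px = np.bincount(cells.ravel())[ids]
    nuc_counts = np.bincount(masks.nuclei.ravel(), minlength=cells.max() + 1)
    nuc_px = nuc_counts[ids]

    # vacuole stats keyed by parent cell
    n_vac = {int(i): 0 for i in ids}
    vac_area_px = {int(i): 0.0 for i in ids}
    if masks.vacuoles.max() > 0:
        vac_counts = np.bincount(masks.vacuoles.ravel())
        for vlabel, parent in masks.vacuole_parent.items():
            if parent in n_vac and vlabel < len(vac_counts):
                area = float(vac_counts[vlabel])
                if area > 0:
                    n_vac[parent] += 1
                    vac_area_px[parent] += area

    outside = cells == 0
    records = []
    intensities = {}
    for name in _REQUIRED_CHANNELS:
        channel = image.channels[name].astype(np.float64)
        background = float(np.median(channel[outside])) if outside.any() else 0.0
        sums = _label_sums(channel, cells, ids)
        intensities[name] = np.clip(sums - background * cell_px, 0.0, None)

    for k, cid in enumerate(ids):
        cid = int(cid)
        nv = n_vac[cid]
        total_v = vac_area_px[cid] * px2
        if nv > 0:
            mean_v = total_v / nv
        else:
            mean_v = np.nan if exclude_vacuole_free_from_mean else 0.0
        area = float(cell_px[k]) * px2
        records.append(
            {
                "well_id": well_id,
                "field_id": field_id,
                "cell_id": cid,
                "cell_area_px2": int(cell_px[k]),
                "nuclear_area_px2": int(nuc_px[k]),
                "nuclear_area_um2": float(nuc_px[k]) * px2,
                "cell_area_um2": area,
                "n_vacuoles": nv,
                "mean_vacuole_area_um2": mean_v,
                "total_vacuole_area_um2": total_v,
                "pct_area_vacuoles": 100.0 * total_v / area,
                "phospholipid_intensity": float(intensities["phospholipid"][k]),
                "neutral_lipid_intensity": float(intensities["neutral_lipid"][k]),
            }
        )
    return pd.DataFrame(records)


def summarize_population(
    experiments: Mapping[str, Sequence[pd.DataFrame]],
    condition: str,
    features: Sequence[str] = FEATURES,
) -> PopulationSummary:
    """Aggregate per-well feature tables into a condition summary.

    ``experiments`` maps experiment id → list of per-well feature tables.
    Aggregation is nested (cell → well mean → experiment mean); the
    reported mean is the mean of experiment means and the SEM is the SD of
    experiment means / √(#experiments).  With a single experiment the SEM
    is NaN (unavailable).
    """
    if not experiments:
        raise ValueError("at least one experiment is required")
    exp_means: list[pd.Series] = []
    all_cells: list[pd.DataFrame] = []
    for exp_id, wells in experiments.items():
        if not wells:
            raise ValueError(f"experiment {exp_id!r} has no wells")
        well_means = pd.DataFrame(
            [w[list(features)].mean() for w in wells if len(w)]
        )
        if well_means.empty:
            raise ValueError(f"experiment {exp_id!r} has no cells")
        exp_means.append(well_means.mean())
        all_cells.extend(w for w in wells if len(w))
    em = pd.DataFrame(exp_means)
    pooled = pd.concat(all_cells, ignore_index=True)
    n_exp = len(exp_means)
    means = em.mean()
    sems = (
        em.std(ddof=1) / np.sqrt(n_exp)
        if n_exp > 1
        else pd.Series(np.nan, index=em.columns)
    )
    return PopulationSummary(
        condition=condition,
        n_cells=int(len(pooled)),
        n_experiments=n_exp,
        means={f: float(means[f]) for f in features},
        sems={f: float(sems[f]) for f in features},
        pooled_sd={f: float(pooled[f].std(ddof=1)) for f in features},
    )


def adherence_fraction(treated_cell_count: float, control_cell_count: float) -> float:
    """Adhered cells in the treated condition as percent of the control count."""
    if control_cell_count <= 0:
        raise ValueError("control_cell_count must be > 0")
    return 100.0 * treated_cell_count / control_cell_count
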