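"""End-to-end orchestration: generate → segment → measure → compare → profile.

A :class:`RunConfig` (YAML-serializable) fully determines a run; re-running
the same config reproduces every output bit-for-bit except timestamps.
The simulated study layout mirrors the standard design of this assay:
independent experiments × replicate wells per condition × imaging fields
per well, with ~1000–2000 cells measured per well.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .morphometrics import FEATURES, PopulationSummary, adherence_fraction, \
    measure_cells, summarize_population
from .presets import BUILTIN_PRESET_NAMES, builtin_preset
from .segmentation import SegmentationParams, segment_field
from .stats import bonferroni_posthoc, fold_change, response_profile
from .synthgen import FieldSpec, generate_field, ground_truth_table

__all__ = [
    "PlateLayout",
    "RunConfig",
    "ConditionResult",
    "simulate_condition",
    "run_pipeline",
]

log = logging.getLogger("famhci.pipeline")


@dataclass(frozen=True)
class PlateLayout:
    """Map well id → (condition label, experiment id) on a 96/24-well plate."""

    wells: Mapping[str, tuple[str, str]]
    plate_format: int = 96

    def __post_init__(self) -> None:
        if self.plate_format not in (24, 96):
            raise ValueError("plate_format must be 24 or 96")
        if len(self.wells) > self.plate_format:
            raise ValueError("more wells than the plate format allows")
        if not self.wells:
            raise ValueError("layout has no wells")

    def conditions(self) -> list[str]:
        return sorted({cond for cond, _ in self.wells.values()})


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    seed: int = 0
    conditions: list[str] = dc_field(default_factory=lambda: ["m0", "m1_lps_ifng"])
    control: str = "m0"
    n_experiments: int = 3
    wells_per_condition: int = 3
    fields_per_well: int = 9
    field: dict = dc_field(default_factory=dict)  # FieldSpec overrides
    segmentation: dict = dc_field(default_factory=dict)  # SegmentationParams overrides
    k_sd: float = 2.0
    alpha: float = 0.05
    outdir: str = "famhci_run"

    def validate(self) -> None:
        if not self.conditions:
            raise ValueError("config error at 'conditions': empty list")
        for name in self.conditions:
            if name not in BUILTIN_PRESET_NAMES:
                raise ValueError(f"config error at 'conditions': unknown preset {name!r}")
        if self.control not in self.conditions:
            raise ValueError("config error at 'control': not among conditions")
        for key in ("n_experiments", "wells_per_condition", "fields_per_well"):
            if getattr(self, key) < 1:
                raise ValueError(f"config error at '{key}': must be >= 1")
        self.field_spec()  # raises on bad field keys/values
        self.segmentation_params()

    def field_spec(self) -> FieldSpec:
        try:
            return FieldSpec(**self.field)
        except TypeError as exc:
            raise ValueError(f"config error at 'field': {exc}") from None

    def segmentation_params(self) -> SegmentationParams:
        try:
            return SegmentationParams(**self.segmentation)
        except TypeError as exc:
            raise ValueError(f"config error at 'segmentation': {exc}") from None

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"config error at {sorted(unknown)}: unknown keys")
        return cls(**data)

    def digest(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        data = dataclasses.asdict(self)
        data.pop("outdir")
        text = yaml.safe_dump(data, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class ConditionResult:
    """Simulation + measurement output for one condition."""

    condition: str
    experiments: dict[str, list[pd.DataFrame]]  # exp id -> per-well tables
    cell_counts: dict[str, list[int]]  # measured (adhered) cells per well
    truth: pd.DataFrame  # pooled ground-truth table (all sampled cells)
    summary: PopulationSummary

    def pooled(self) -> pd.DataFrame:
        return pd.concat(
            [w for wells in self.experiments.values() for w in wells],
            ignore_index=True,
        )

    def experiment_means(self, feature: str) -> list[float]:
        out = []
        for wells in self.experiments.values():
            well_means = [w[feature].mean() for w in wells if len(w)]
            out.append(float(np.mean(well_means)))
        return out


def simulate_condition(
    preset_name: str,
    seed,
    n_experiments: int = 3,
    wells_per_experiment: int = 3,
    fields_per_well: int = 9,
    field_spec: FieldSpec | None = None,
    seg_params: SegmentationParams | None = None,
) -> ConditionResult:
    """Simulate, segment and measure one condition.

    Every well seeds the same number of cells; the preset's adhesion model
    drops non-adherent cells before rendering, so measured cell counts per
    well reflect the adherent fraction.
    """
    preset = builtin_preset(preset_name)
    spec = field_spec or FieldSpec()
    params = seg_params or SegmentationParams()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)

    experiments: dict[str, list[pd.DataFrame]] = {}
    counts: dict[str, list[int]] = {}
    truth_tables = []
    field_seeds = iter(ss.spawn(n_experiments * wells_per_experiment * fields_per_well))
    for e in range(n_experiments):
        exp_id = f"exp{e + 1}"
        experiments[exp_id] = []
        counts[exp_id] = []
        for w in range(wells_per_experiment):
            well_id = f"{exp_id}_well{w + 1}"
            well_tables = []
            n_cells = 0
            for f_idx in range(fields_per_well):
                cells, image, _truth_masks = generate_field(
                    preset, spec, next(field_seeds)
                )
                masks = segment_field(image, params)
                table = measure_cells(
                    masks, image, well_id=well_id, field_id=f"f{f_idx + 1}"
                )
                well_tables.append(table)
                n_cells += len(table)
                gt = ground_truth_table(cells, spec.pixel_size_um)
                gt.insert(0, "well_id", well_id)
                truth_tables.append(gt)
            experiments[exp_id].append(
                pd.concat(well_tables, ignore_index=True)
                if well_tables
                else pd.DataFrame()
            )
            counts[exp_id].append(n_cells)
        log.info("condition %s %s: %d cells", preset_name, exp_id,
                 sum(counts[exp_id]))
    summary = summarize_population(experiments, preset_name)
    return ConditionResult(
        condition=preset_name,
        experiments=experiments,
        cell_counts=counts,
        truth=pd.concat(truth_tables, ignore_index=True),
        summary=summary,
    )


def _comparison_table(
    results: Mapping[str, ConditionResult], control: str
) -> pd.DataFrame:
    rows = []
    labels = list(results)
    for feature in FEATURES:
        groups = {lab: results[lab].experiment_means(feature) for lab in labels}
        cmp = bonferroni_posthoc(groups, "vs_control", control)
        for pc in cmp.pairwise:
            rows.append(
                {
                    "feature": feature,
                    "condition": pc.pair[0],
                    "control": pc.pair[1],
                    "condition_mean": float(np.mean(groups[pc.pair[0]])),
                    "control_mean": float(np.mean(groups[pc.pair[1]])),
                    "difference": pc.difference,
                    "F": cmp.F,
                    "p_anova": cmp.p_anova,
                    "raw_p": pc.raw_p,
                    "adjusted_p": pc.adjusted_p,
                    "stars": pc.stars,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and write a run directory.

    Outputs: per-cell CSV, population summary CSV, Bonferroni comparison
    CSV with stars, response-profile CSV (+ heatmap PNG), and a JSON
    manifest with versions, seed and config hash.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = config.field_spec()
    params = config.segmentation_params()

    ss = np.random.SeedSequence(config.seed)
    cond_seeds = dict(zip(config.conditions, ss.spawn(len(config.conditions))))

    results: dict[str, ConditionResult] = {}
    for name in config.conditions:
        log.info("simulating condition %s", name)
        results[name] = simulate_condition(
            name,
            cond_seeds[name],
            n_experiments=config.n_experiments,
            wells_per_experiment=config.wells_per_condition,
            fields_per_well=config.fields_per_well,
            field_spec=spec,
            seg_params=params,
        )

    log.info("writing tables to %s", outdir)
    per_cell = []
    for name, res in results.items():
        pooled = res.pooled()
        pooled.insert(0, "condition", name)
        per_cell.append(pooled)
    pd.concat(per_cell, ignore_index=True).to_csv(outdir / "cells.csv", index=False)

    control_count = sum(sum(v) for v in results[config.control].cell_counts.values())
    summary_rows = []
    for name, res in results.items():
        treated_count = sum(sum(v) for v in res.cell_counts.values())
        row = {"condition": name, "n_cells": res.summary.n_cells,
               "adherent_pct_of_control": adherence_fraction(
                   treated_count, control_count)}
        for feat in FEATURES:
            row[f"{feat}_mean"] = res.summary.means[feat]
            row[f"{feat}_sem"] = res.summary.sems[feat]
        summary_rows.append(row)
    pd.DataFrame(summary_rows).to_csv(outdir / "summary.csv", index=False)

    comparisons = _comparison_table(results, config.control)
    comparisons.to_csv(outdir / "comparisons.csv", index=False)

    control_cells = results[config.control].pooled()
    profiles = []
    for name, res in results.items():
        if name == config.control:
            continue
        prof = response_profile(
            res.pooled(), control_cells, k_sd=config.k_sd, features=list(FEATURES)
        )
        frame = prof.to_frame()
        frame.insert(0, "condition", name)
        profiles.append(frame.rename_axis("feature").reset_index())
    if profiles:
        profile_table = pd.concat(profiles, ignore_index=True)
        profile_table.to_csv(outdir / "response_profile.csv", index=False)
        _write_heatmap(outdir / "response_profile.png", profile_table)

    folds = []
    for name, res in results.items():
        if name == config.control:
            continue
        for feat in ("phospholipid_intensity", "neutral_lipid_intensity"):
            folds.append(
                {
                    "condition": name,
                    "feature": feat,
                    "fold_change": fold_change(
                        res.summary, results[config.control].summary, feat
                    ),
                }
            )
    pd.DataFrame(folds).to_csv(outdir / "fold_changes.csv", index=False)

    manifest = {
        "famhci_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "conditions": config.conditions,
        "cells_measured": {n: r.summary.n_cells for n, r in results.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (outdir / "config.yaml").write_text(config.to_yaml())
    log.info("run complete: %s", outdir)
    return outdir


def _write_heatmap(path: Path, profile_table: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = profile_table.pivot_table(
        index="feature", columns="condition",
        values="pct_increased", aggfunc="first"
    ) - profile_table.pivot_table(
        index="feature", columns="condition",
        values="pct_decreased", aggfunc="first"
    )
    fig, ax = plt.subplots(figsize=(2 + pivot.shape[1], 0.5 * pivot.shape[0] + 2))
    im = ax.imshow(pivot.to_numpy(), cmap="RdBu_r", vmin=-100, vmax=100, aspect="auto")
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    fig.colorbar(im, ax=ax, label="% increased − % decreased")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
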