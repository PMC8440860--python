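"""Flow-cytometry analysis: scatter-based debris exclusion and
percent-positive quantification against a control population.

The positivity threshold is a high quantile (default 0.99) of the control's
green fluorescence, taken as an order statistic so the result is invariant
under any strictly monotone transform applied to both sample and control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GateResult", "gate_debris", "percent_positive"]


@dataclass(frozen=True)
class GateResult:
    """Outcome of percent-positive gating against a control."""

    n_total: int
    n_gated: int  # events above threshold
    percent_positive: float
    threshold_value: float
    control_label: str = ""


def gate_debris(
    events: pd.DataFrame, fsc_min: float, ssc_min: float
) -> pd.DataFrame:
    """Retain events with ``fsc >= fsc_min`` and ``ssc >= ssc_min``."""
    if fsc_min < 0 or ssc_min < 0:
        raise ValueError("scatter thresholds must be >= 0")
    if events.empty:
        return events.copy()
    keep = (events["fsc"] >= fsc_min) & (events["ssc"] >= ssc_min)
    return events.loc[keep].reset_index(drop=True)


def percent_positive(
    sample: pd.DataFrame,
    control: pd.DataFrame,
    control_quantile: float = 0.99,
    control_label: str = "",
) -> GateResult:
    """Fraction of sample events whose green fluorescence exceeds the
    control's ``control_quantile`` order statistic."""
    if not 0.0 < control_quantile < 1.0:
        raise ValueError("control_quantile must be in (0,1)")
    if control.empty:
        raise ValueError("control table is empty")
    if sample.empty:
        raise ValueError("sample table is empty")
    threshold = float(
        np.quantile(control["fl_green"].to_numpy(), control_quantile, method="lower")
    )
    fl = sample["fl_green"].to_numpy()
    n_pos = int((fl > threshold).sum())
    return GateResult(
        n_total=len(fl),
        n_gated=n_pos,
        percent_positive=100.0 * n_pos / len(fl),
        threshold_value=threshold,
        control_label=control_label,
    )
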