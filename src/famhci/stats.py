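"""Statistical layer: normalization to viable cell count, normality
testing, one-way ANOVA with Bonferroni post-hoc star annotation, fold
changes, and population response profiles.

The ANOVA is computed from explicit between/within sums of squares.  The
post-hoc follows the classical "Bonferroni multiple comparison test":
pairwise t statistics built on the ANOVA pooled mean-square error (with its
degrees of freedom), two-tailed raw p, and adjusted p = min(1, m·p) over
the m comparisons performed; Welch two-sample p-values are reported
alongside for transparency.  Group-level statistics are intended for
experiment-level means (the experiment is the replicate); testing on
per-cell values pseudoreplicates and is only available with an explicit
warning downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairwiseComparison",
    "ComparisonResult",
    "ResponseProfile",
    "normalize_to_cell_count",
    "shapiro_wilk",
    "one_way_anova",
    "bonferroni_posthoc",
    "fold_change",
    "response_profile",
    "stars_for_p",
]

_STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars_for_p(p: float) -> str:
    """Significance stars: p<0.05 '*', p<0.01 '**', p<0.001 '***', else 'ns'."""
    for threshold, stars in _STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    difference: float
    t_statistic: float
    raw_p: float
    adjusted_p: float
    stars: str
    welch_p: float


@dataclass(frozen=True)
class ComparisonResult:
    groups: tuple[str, ...]
    F: float
    p_anova: float
    pairwise: list[PairwiseComparison]
    m_comparisons: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group_a": c.pair[0],
                    "group_b": c.pair[1],
                    "difference": c.difference,
                    "t": c.t_statistic,
                    "raw_p": c.raw_p,
                    "adjusted_p": c.adjusted_p,
                    "stars": c.stars,
                    "welch_p": c.welch_p,
                }
                for c in self.pairwise
            ]
        )


@dataclass(frozen=True)
class ResponseProfile:
    """Per-feature percent of the treated population outside the control band."""

    pct_increased: dict[str, float]
    pct_decreased: dict[str, float]
    rule: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pct_increased": pd.Series(self.pct_increased),
                "pct_decreased": pd.Series(self.pct_decreased),
            }
        )


def normalize_to_cell_count(raw_value, viable_cell_count):
    """Express an assay measure per viable cell (raw / count)."""
    if np.any(np.asarray(viable_cell_count) <= 0):
        raise ValueError("viable_cell_count must be > 0")
    return raw_value / viable_cell_count


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro–Wilk normality test (W, p), n in 3..5000.

    Backed by the Royston approximation; constant samples are rejected up
    front because W is undefined.
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need a 1D sample with n >= 3")
    if len(x) > 5000:
        raise ValueError("n must be <= 5000 for a calibrated p-value")
    if np.ptp(x) == 0:
        raise ValueError("sample is constant; W is undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _check_groups(groups: Sequence[np.ndarray]) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for g in arrays:
        if g.ndim != 1 or len(g) < 2:
            raise ValueError("every group needs at least 2 values")
    return arrays


def one_way_anova(groups: Sequence) -> tuple[float, float]:
    """Classical one-way ANOVA from explicit sums of squares.

    Returns (F, p).  Identical group means give F = 0, p = 1; a zero
    within-group mean square with distinct means gives F = inf, p = 0.
    """
    arrays = _check_groups(groups)
    n_total = sum(len(g) for g in arrays)
    grand = sum(g.sum() for g in arrays) / n_total
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df_b = len(arrays) - 1
    df_w = n_total - len(arrays)
    if ssb == 0:
        return 0.0, 1.0
    if ssw == 0:
        return float("inf"), 0.0
    f = (ssb / df_b) / (ssw / df_w)
    return float(f), float(sps.f.sf(f, df_b, df_w))


def bonferroni_posthoc(
    groups: Mapping[str, Sequence[float]],
    comparisons: str = "vs_control",
    control_label: str | None = None,
) -> ComparisonResult:
    """Bonferroni multiple-comparison post-hoc after one-way ANOVA.

    Pairwise t statistics use the ANOVA pooled MSE with N-k degrees of
    freedom; ``adjusted_p = min(1, m * raw_p)`` where m is the number of
    comparisons performed.  ``comparisons`` is ``vs_control`` (every group
    against ``control_label``) or ``all_pairs``.
    """
    labels = list(groups)
    arrays = _check_groups([groups[k] for k in labels])
    data = dict(zip(labels, arrays))
    f, p_anova = one_way_anova(arrays)

    n_total = sum(len(g) for g in arrays)
    k = len(arrays)
    df_w = n_total - k
    mse = sum(((g - g.mean()) ** 2).sum() for g in arrays) / df_w

    if comparisons == "vs_control":
        if control_label not in data:
            raise ValueError(
                f"unknown control label {control_label!r}; groups: {labels}"
            )
        pairs = [(lab, control_label) for lab in labels if lab != control_label]
    elif comparisons == "all_pairs":
        pairs = [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
    else:
        raise ValueError("comparisons must be 'vs_control' or 'all_pairs'")

    m = len(pairs)
    results = []
    for a, b in pairs:
        ga, gb = data[a], data[b]
        diff = float(ga.mean() - gb.mean())
        se = np.sqrt(mse * (1.0 / len(ga) + 1.0 / len(gb)))
        if se == 0:
            t = 0.0 if diff == 0 else float("inf") * np.sign(diff)
            raw = 1.0 if diff == 0 else 0.0
        else:
            t = diff / se
            raw = float(2.0 * sps.t.sf(abs(t), df_w))
        adj = min(1.0, m * raw)
        welch = float(sps.ttest_ind(ga, gb, equal_var=False).pvalue)
        results.append(
            PairwiseComparison(
                pair=(a, b),
                difference=diff,
                t_statistic=float(t),
                raw_p=raw,
                adjusted_p=adj,
                stars=stars_for_p(adj),
                welch_p=welch,
            )
        )
    return ComparisonResult(
        groups=tuple(labels), F=f, p_anova=p_anova, pairwise=results, m_comparisons=m
    )


def fold_change(treated_summary, control_summary, feature: str) -> float:
    """Treated mean / control mean for one feature.

    Accepts :class:`~famhci.morphometrics.PopulationSummary` objects or
    plain feature→mean mappings.
    """

    def _mean(summary):
        means = getattr(summary, "means", summary)
        return float(means[feature])

    control = _mean(control_summary)
    if control <= 0:
        raise ValueError("control mean must be > 0")
    return _mean(treated_summary) / control


def response_profile(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    k_sd: float = 2.0,
    features: Sequence[str] | None = None,
) -> ResponseProfile:
    """Percent of treated cells above/below the control mean ± k·SD band.

    This is the package's explicit population-response rule for
    increased/decreased-feature heatmaps.  Requires >= 30 control cells and
    a nonzero control SD per feature.
    """
    if features is None:
        features = [
            c
            for c in treated.columns
            if c in control.columns and pd.api.types.is_numeric_dtype(treated[c])
            and c not in ("cell_id",)
        ]
    if len(control) < 30:
        raise ValueError("control must have at least 30 cells")
    inc: dict[str, float] = {}
    dec: dict[str, float] = {}
    for feat in features:
        c = control[feat].to_numpy(dtype=float)
        t = treated[feat].to_numpy(dtype=float)
        c, t = c[~np.isnan(c)], t[~np.isnan(t)]
        sd = c.std(ddof=1)
        if sd == 0:
            raise ValueError(f"control SD of {feat!r} is zero")
        lo, hi = c.mean() - k_sd * sd, c.mean() + k_sd * sd
        inc[feat] = 100.0 * float((t > hi).mean())
        dec[feat] = 100.0 * float((t < lo).mean())
    return ResponseProfile(
        pct_increased=inc,
        pct_decreased=dec,
        rule=f"control mean ± {k_sd:g}·SD band",
    )
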