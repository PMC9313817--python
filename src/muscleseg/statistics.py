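"""Metric summaries, observer baseline, and Dunnett many-to-one tests.

The inter-observer study provides the human-performance baseline: per test
image, observer masks are scored against the expert mask and averaged; the
baseline is the across-image mean with its standard error. Model cells
(pretext x training-set size) are then compared against the observer control
with Dunnett's test, which controls the family-wise error rate for several
simultaneous comparisons against one control group.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import dsc, rms_dta, sma, smd
from .types import BinaryMask, CTSlice, MetricRecord

__all__ = [
    "GroupSummary",
    "DunnettResult",
    "ObserverBaseline",
    "observer_baseline",
    "dunnett_test",
    "summarize_grid",
]


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    se: float
    ci_low: float
    ci_high: float
    degenerate: bool = False  # single observation: CI collapses to the mean

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("SE must be >= 0")
        if not (self.ci_low - 1e-12 <= self.mean <= self.ci_high + 1e-12):
            raise ValueError("CI must contain the mean")


def _summary(label: str, values: np.ndarray) -> GroupSummary:
    values = np.asarray(values, dtype=float)
    n = len(values)
    m = float(values.mean())
    if n < 2:
        return GroupSummary(label, n, m, 0.0, m, m, degenerate=True)
    se = float(values.std(ddof=1) / np.sqrt(n))
    half = 1.959963984540054 * se  # normal-approximation 95% CI
    return GroupSummary(label, n, m, se, m - half, m + half)


@dataclass
class ObserverBaseline:
    """Aggregate observer-vs-expert agreement over the test set."""

    dsc_mean: float
    dsc_se: float
    rms_dta_mean_cm: float
    rms_dta_se_cm: float
    delta_smd_mean_hu: float | None = None
    delta_smd_sd_hu: float | None = None
    delta_sma_mean_cm2: float | None = None
    delta_sma_sd_cm2: float | None = None
    n_images: int = 0

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def observer_baseline(
    observer_masks: dict[str, list[BinaryMask]],
    expert_masks: dict[str, BinaryMask],
    ct_slices: dict[str, CTSlice] | None = None,
) -> ObserverBaseline:
    """Mean DSC/RMS-DTA of observers vs expert, and muscle-characteristic deltas.

    For every image the observer scores are first averaged, then the
    per-image means are aggregated across the test set (mean ± SE). With CT
    slices supplied, per-delineation differences in SMD and SMA (signed
    observer − expert) are aggregated as mean ± SD.
    """
    per_image_dsc, per_image_dta = [], []
    d_smd, d_sma = [], []
    for slice_id, obs_list in observer_masks.items():
        if slice_id not in expert_masks:
            raise KeyError(f"missing expert mask for {slice_id}")
        if not obs_list:
            raise ValueError(f"no observer masks for {slice_id}")
        expert = expert_masks[slice_id]
        per_image_dsc.append(np.mean([dsc(o, expert) for o in obs_list]))
        per_image_dta.append(np.mean([rms_dta(o, expert) for o in obs_list]))
        if ct_slices is not None:
            ct = ct_slices[slice_id]
            smd_e, sma_e = smd(ct, expert), sma(expert)
            for o in obs_list:
                d_smd.append(smd(ct, o) - smd_e)
                d_sma.append(sma(o) - sma_e)

    sd = _summary("dsc", np.array(per_image_dsc))
    st = _summary("rms_dta", np.array(per_image_dta))
    out = ObserverBaseline(
        dsc_mean=sd.mean,
        dsc_se=sd.se,
        rms_dta_mean_cm=st.mean,
        rms_dta_se_cm=st.se,
        n_images=len(per_image_dsc),
    )
    if ct_slices is not None:
        out.delta_smd_mean_hu = float(np.mean(d_smd))
        out.delta_smd_sd_hu = float(np.std(d_smd, ddof=1)) if len(d_smd) > 1 else 0.0
        out.delta_sma_mean_cm2 = float(np.mean(d_sma))
        out.delta_sma_sd_cm2 = float(np.std(d_sma, ddof=1)) if len(d_sma) > 1 else 0.0
    return out


@dataclass
class DunnettResult:
    control_label: str
    p_values: dict[str, float]
    directions: dict[str, int]  # sign of (group mean - control mean)
    family_size: int
    alpha: float

    def significant(self) -> dict[str, bool]:
        return {k: p < self.alpha for k, p in self.p_values.items()}


def dunnett_test(
    groups: dict[str, np.ndarray], control: np.ndarray, alpha: float = 0.05
) -> DunnettResult:
    """Dunnett's many-to-one comparisons against a control.

    Adjusted two-sided p-values from the multivariate-t reference
    distribution (pooled-variance model). A family of one reduces to the
    two-sample pooled t-test. Degenerate all-identical data returns p = 1
    for every comparison by convention.
    """
    labels = list(groups)
    control = np.asarray(control, dtype=float)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(control) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("every group (and the control) needs n >= 2")

    all_vals = np.concatenate(samples + [control])
    if np.allclose(all_vals, all_vals[0]):
        pvals = {k: 1.0 for k in labels}
        dirs = {k: 0 for k in labels}
        return DunnettResult(
            control_label="control",
            p_values=pvals,
            directions=dirs,
            family_size=len(labels),
            alpha=alpha,
        )

    res = stats.dunnett(*samples, control=control)
    pvals = {}
    dirs = {}
    cmean = control.mean()
    for k, p, s in zip(labels, res.pvalue, samples):
        pvals[k] = float(1.0 if np.isnan(p) else np.clip(p, 0.0, 1.0))
        dirs[k] = int(np.sign(s.mean() - cmean))
    return DunnettResult(
        control_label="control",
        p_values=pvals,
        directions=dirs,
        family_size=len(labels),
        alpha=alpha,
    )


def summarize_grid(
    records: list[MetricRecord] | pd.DataFrame,
    metric: str = "dsc",
    plateau_from: int = 100,
) -> tuple[pd.DataFrame, dict]:
    """Per-(pretext, size) mean and 95% CI, plus the large-n plateau check.

    The plateau check compares, per pretext, the metric at each size >=
    ``plateau_from`` with the largest size (two-sample t-test): large
    p-values indicate that performance has stopped improving with n.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    if metric not in df.columns:
        raise KeyError(f"unknown metric column {metric!r}")

    rows = []
    for (pretext, size), grp in df.groupby(["pretext", "size"], sort=True):
        s = _summary(f"{pretext}/n={size}", grp[metric].to_numpy())
        rows.append(
            {
                "pretext": pretext,
                "size": size,
                "n_records": s.n,
                "mean": s.mean,
                "se": s.se,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "degenerate": s.degenerate,
            }
        )
    table = pd.DataFrame(rows)

    plateau: dict[str, dict[int, float]] = {}
    for pretext, grp in df.groupby("pretext"):
        sizes = sorted(grp["size"].unique())
        big = [s for s in sizes if s >= plateau_from]
        if len(big) < 2:
            continue
        ref = grp.loc[grp["size"] == big[-1], metric].to_numpy()
        plateau[pretext] = {}
        for s in big[:-1]:
            vals = grp.loc[grp["size"] == s, metric].to_numpy()
            if len(vals) >= 2 and len(ref) >= 2:
                plateau[pretext][int(s)] = float(
                    stats.ttest_ind(vals, ref, equal_var=True).pvalue
                )
    return table, plateau
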