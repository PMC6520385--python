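"""Array normalization and the three-step probe filter.

Each array (one line x replicate) is globally scaled so its trimmed mean hits
a target intensity; probes are then kept if (1) called present in at least
``min_present`` replicates of at least one line, (2) one-way ANOVA across
lines is significant at ``alpha``, and (3) the max/min ratio of line-mean
intensities is at least ``min_ratio``.  Survivor sets are nested by
construction and reported per step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import PRESENT, ExpressionDataset
from .errors import AnalysisError

logger = logging.getLogger(__name__)

__all__ = [
    "global_scale",
    "present_filter",
    "anova_filter",
    "fold_filter",
    "filter_probes",
    "FilterReport",
]


def global_scale(
    data: ExpressionDataset, target: float = 500.0, trim: float = 0.02
) -> ExpressionDataset:
    """Scale each array so its trimmed mean equals ``target``.

    Per array, the highest and lowest ``trim`` fractions of probe values
    (counts rounded down, per tail) are excluded and all intensities on that
    array are multiplied by a single factor bringing the remaining mean to
    ``target``.  Applying the operation twice is a no-op (all factors 1 on
    the second pass), so renormalizing is allowed.
    """
    if not 0 <= trim < 0.5:
        raise AnalysisError(f"trim must be in [0, 0.5), got {trim}")
    if target <= 0:
        raise AnalysisError("target intensity must be positive")
    n_probes = data.n_probes
    k = int(trim * n_probes)  # per-tail exclusion count, rounded down
    flat = data.intensity.reshape(n_probes, -1)
    scaled = np.empty_like(flat)
    for a in range(flat.shape[1]):
        col = np.sort(flat[:, a])
        trimmed = col[k : n_probes - k] if k else col
        m = trimmed.mean() if trimmed.size else 0.0
        if m <= 0:
            raise AnalysisError(f"array index {a}: trimmed mean is zero, scale undefined")
        scaled[:, a] = flat[:, a] * (target / m)
    out = data.copy()
    out.intensity = scaled.reshape(data.intensity.shape)
    out.normalized = True
    return out


def present_filter(data: ExpressionDataset, min_present: int = 4) -> list[str]:
    """Probes with >= ``min_present`` "P" calls among the replicates of >= 1 line.

    Depends only on the call matrix; marginal ("M") calls do not count as
    present.
    """
    if min_present < 1:
        raise AnalysisError("min_present must be >= 1")
    p_counts = (data.calls == PRESENT).sum(axis=2)  # (n_probes, n_lines)
    keep = (p_counts >= min_present).any(axis=1)
    return [p for p, k in zip(data.probe_ids, keep) if k]


def _anova_pvalues(data: ExpressionDataset, probes, log2: bool) -> pd.Series:
    """Vectorized one-way fixed-effects ANOVA across lines, one P per probe."""
    idx = data.probe_index(probes)
    x = data.intensity[idx]  # (m, k, r)
    if log2:
        x = np.log2(np.maximum(x, 1e-12))
    m, k, r = x.shape
    if k < 2 or r < 2:
        raise AnalysisError("ANOVA requires >= 2 lines and >= 2 replicates per line")
    grand = x.mean(axis=(1, 2), keepdims=True)
    group = x.mean(axis=2, keepdims=True)
    ssb = (r * (group - grand) ** 2).sum(axis=(1, 2))
    ssw = ((x - group) ** 2).sum(axis=(1, 2))
    dfb, dfw = k - 1, k * (r - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
        p = stats.f.sf(f, dfb, dfw)
    # degenerate: zero within-group variance everywhere
    zero_w = ssw <= 0
    if zero_w.any():
        sep = zero_w & (ssb > 0)
        flat = zero_w & (ssb <= 0)
        p[sep] = 0.0  # perfectly separated groups
        if flat.any():
            logger.warning(
                "%d probe(s) with zero variance and equal means: ANOVA P undefined, "
                "treated as not significant",
                int(flat.sum()),
            )
            p[flat] = 1.0
    return pd.Series(p, index=list(probes), name="anova_p")


def anova_filter(
    data: ExpressionDataset, probes, alpha: float = 0.05, log2: bool = False
) -> list[str]:
    """Keep probes whose one-way ANOVA across lines gives P < alpha.

    Runs on linear normalized intensities by default (``log2=True`` for the
    log-scale variant).
    """
    if not 0 < alpha < 1:
        raise AnalysisError(f"alpha must be in (0, 1), got {alpha}")
    p = _anova_pvalues(data, probes, log2=log2)
    return list(p.index[p < alpha])


def _fold_ranges(data: ExpressionDataset, probes) -> pd.Series:
    means = data.line_means(probes)
    mx = means.max(axis=1)
    mn = means.min(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mx / mn
    nonpos = mn <= 0
    if nonpos.any():
        logger.warning(
            "%d probe(s) with non-positive minimum line mean: ratio treated as +inf "
            "where the maximum is positive",
            int(nonpos.sum()),
        )
        ratio[nonpos & (mx > 0)] = np.inf
        ratio[nonpos & (mx <= 0)] = 1.0
    return ratio.rename("fold_range")


def fold_filter(data: ExpressionDataset, probes, min_ratio: float = 5.0) -> list[str]:
    """Keep probes whose max/min line-mean intensity ratio is >= ``min_ratio``.

    The boundary is inclusive: a probe spanning exactly ``min_ratio`` stays.
    """
    if min_ratio < 1:
        raise AnalysisError("min_ratio must be >= 1")
    ratio = _fold_ranges(data, probes)
    return list(ratio.index[ratio >= min_ratio])


@dataclass
class FilterReport:
    """Nested survivor sets and per-probe statistics for the three filters."""

    steps: list[str]
    survivors: dict[str, list[str]]
    counts: dict[str, int] = field(default_factory=dict)
    anova_p: pd.Series | None = None
    fold_range: pd.Series | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = {s: len(self.survivors[s]) for s in self.steps}
        prev: set[str] | None = None
        for s in self.steps:
            cur = set(self.survivors[s])
            if prev is not None and not cur <= prev:
                raise AnalysisError(f"filter step {s!r} survivors not nested")
            prev = cur

    @property
    def final(self) -> list[str]:
        return self.survivors[self.steps[-1]] if self.steps else []

    def to_dict(self) -> dict:
        return {
            "steps": self.steps,
            "counts": self.counts,
            "params": self.params,
            "n_final": len(self.final),
        }


def filter_probes(
    data: ExpressionDataset,
    min_present: int = 4,
    alpha: float = 0.05,
    min_ratio: float = 5.0,
    anova_log2: bool = False,
) -> FilterReport:
    """Apply present -> ANOVA -> fold-range filters in order."""
    if not data.normalized:
        logger.warning("filtering un-normalized data; run global_scale first")
    step1 = present_filter(data, min_present=min_present)
    if step1:
        anova_p = _anova_pvalues(data, step1, log2=anova_log2)
        step2 = list(anova_p.index[anova_p < alpha])
    else:
        anova_p = pd.Series(dtype=float, name="anova_p")
        step2 = []
    if step2:
        fold = _fold_ranges(data, step2)
        step3 = list(fold.index[fold >= min_ratio])
    else:
        fold = pd.Series(dtype=float, name="fold_range")
        step3 = []
    return FilterReport(
        steps=["present", "anova", "fold"],
        survivors={"present": step1, "anova": step2, "fold": step3},
        anova_p=anova_p,
        fold_range=fold,
        params={
            "min_present": min_present,
            "alpha": alpha,
            "min_ratio": min_ratio,
            "anova_log2": anova_log2,
        },
    )
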