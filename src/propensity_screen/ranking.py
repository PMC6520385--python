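"""Trilineage propensity ranking from a qPCR marker panel.

Pipeline: comparative-Ct quantification against a housekeeping gene and a
reference line, per-gene z-scoring of the line-mean fold changes, PCA per
germ-layer panel, and descending-PC1 ranking of the cell lines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError

logger = logging.getLogger(__name__)

__all__ = [
    "CtTable",
    "PropensityRanking",
    "comparative_ct",
    "zscore_per_gene",
    "pca_pc1",
    "rank_lines",
    "build_ranking",
    "interlineage_rank_correlation",
]


@dataclass
class CtTable:
    """Long-format qPCR cycle-threshold table.

    ``data`` columns: line, replicate, gene, well, ct.  Duplicate wells are
    averaged on the Ct scale before any delta is taken.
    """

    data: pd.DataFrame
    housekeeping: str = "GAPDH"
    reference_line: str = "201B7"

    REQUIRED = ("line", "replicate", "gene", "well", "ct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise AnalysisError(f"CtTable missing columns: {missing}")
        if (self.data["ct"] <= 0).any():
            raise AnalysisError("Ct values must be positive")
        if self.reference_line not in set(self.data["line"]):
            raise AnalysisError(f"reference line {self.reference_line!r} not in table")
        if self.housekeeping not in set(self.data["gene"]):
            raise AnalysisError(f"housekeeping gene {self.housekeeping!r} not in table")


def comparative_ct(table: CtTable) -> pd.DataFrame:
    """Fold changes 2^-ddCt per (line, replicate) x gene.

    dCt = Ct(gene) - Ct(housekeeping) within each (line, replicate), after
    averaging duplicate wells; the per-sample quantity 2^-dCt is then
    normalized to the average of the reference line's replicates on the
    linear scale, so the reference line's mean fold change is exactly 1 for
    every gene (averaging dCt on the cycle scale instead would violate that
    anchor whenever replicates are noisy).  Replicates lacking a
    housekeeping Ct are dropped with a log message.
    """
    df = table.data
    mean_ct = (
        df.groupby(["line", "replicate", "gene"], sort=True)["ct"].mean().unstack("gene")
    )
    hk = mean_ct[table.housekeeping]
    missing_hk = hk.isna()
    if missing_hk.any():
        for line, rep in mean_ct.index[missing_hk]:
            logger.warning("dropping replicate (%s, %s): missing housekeeping Ct", line, rep)
        mean_ct = mean_ct[~missing_hk.values]
        hk = hk[~missing_hk.values]
    dct = mean_ct.drop(columns=[table.housekeeping]).sub(hk, axis=0)
    rel = np.power(2.0, -dct)
    ref = rel.xs(table.reference_line, level="line")
    return rel.div(ref.mean(axis=0), axis=1)


def line_mean_folds(folds: pd.DataFrame) -> pd.DataFrame:
    """Average fold changes over replicates: rows = lines, cols = genes."""
    return folds.groupby(level="line", sort=True).mean()


def zscore_per_gene(values: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Standardize each gene (column) across lines to mean 0, SD 1.

    Population SD (ddof=0) by default; the downstream ranking is invariant
    to the convention.  Zero-variance genes are excluded with a warning
    because their z-score is undefined.
    """
    if len(values) < 2:
        raise AnalysisError("z-scoring requires at least 2 lines")
    sd = values.std(axis=0, ddof=ddof)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} zero-variance gene(s) from PCA: "
            f"{list(values.columns[zero])[:5]}",
            stacklevel=2,
        )
        values = values.loc[:, ~zero]
        sd = sd[~zero]
    return (values - values.mean(axis=0)) / sd


def pca_pc1(z: pd.DataFrame) -> tuple[pd.Series, float]:
    """First principal component score per line, plus explained variance.

    PC1 is the projection onto the first right-singular vector of the
    column-centered matrix.  The sign is oriented so PC1 correlates
    non-negatively with the per-line mean of the standardized panel, making
    "descending PC1" mean "higher panel expression first"; ties in the
    orientation rule fall back to requiring a positive loading sum, then a
    positive first loading.
    """
    if z.shape[0] < 2 or z.shape[1] < 1:
        raise AnalysisError("PCA requires >= 2 lines and >= 1 gene")
    x = z.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    if s[0] <= 0:
        raise AnalysisError("degenerate panel matrix: rank 0")
    scores = u[:, 0] * s[0]
    panel_mean = x.mean(axis=1)
    c = float(scores @ panel_mean)
    if c == 0:
        c = float(vt[0].sum()) or float(vt[0][np.nonzero(vt[0])[0][0]])
    if c < 0:
        scores = -scores
    explained = float(s[0] ** 2 / np.sum(s**2))
    return pd.Series(scores, index=z.index, name="pc1"), explained


def rank_lines(pc1: pd.Series) -> pd.Series:
    """Descending-order ranks: 1 = highest PC1, average ranks on exact ties."""
    return pd.Series(
        stats.rankdata(-pc1.to_numpy(dtype=float)), index=pc1.index, name="rank"
    )


@dataclass
class PropensityRanking:
    """Per-lineage PC1 scores and descending ranks for each cell line."""

    lineages: list[str]
    lines: list[str]
    pc1: dict[str, pd.Series]
    rank: dict[str, pd.Series]
    explained_variance: dict[str, float]
    panels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.lines)
        for lineage in self.lineages:
            r = self.rank[lineage]
            if sorted(r.index) != sorted(self.lines):
                raise AnalysisError(f"rank index mismatch for {lineage}")
            if abs(r.sum() - n * (n + 1) / 2) > 1e-9:
                raise AnalysisError(f"ranks for {lineage} are not a valid permutation")

    def rank_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({l: self.rank[l] for l in self.lineages})
        out.index.name = "line"
        return out

    def pc1_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({l: self.pc1[l] for l in self.lineages})
        out.index.name = "line"
        return out


def build_ranking(
    table: CtTable,
    panels: dict[str, list[str]],
    ddof: int = 0,
    replicate_level: bool = False,
) -> PropensityRanking:
    """Comparative Ct -> z-score -> PCA -> descending-PC1 ranking per lineage.

    ``panels`` maps lineage name to its marker gene list; genes shared
    between panels contribute to every panel listing them.  By default PCA
    runs on the line-mean fold-change matrix (one row per line); with
    ``replicate_level=True`` scores are computed per sample then averaged
    per line.
    """
    folds = comparative_ct(table)
    pc1: dict[str, pd.Series] = {}
    rank: dict[str, pd.Series] = {}
    explained: dict[str, float] = {}
    lines: list[str] | None = None
    for lineage, genes in panels.items():
        present = [g for g in genes if g in folds.columns]
        missing = set(genes) - set(present)
        if missing:
            logger.warning("panel %s: %d gene(s) absent from Ct table", lineage, len(missing))
        if not present:
            raise AnalysisError(f"panel {lineage!r} has no genes in the Ct table")
        if replicate_level:
            z = zscore_per_gene(folds[present], ddof=ddof)
            scores, ev = pca_pc1(z)
            scores = scores.groupby(level="line").mean()
        else:
            z = zscore_per_gene(line_mean_folds(folds[present]), ddof=ddof)
            scores, ev = pca_pc1(z)
        pc1[lineage] = scores
        rank[lineage] = rank_lines(scores)
        explained[lineage] = ev
        lines = list(scores.index)
    assert lines is not None
    return PropensityRanking(
        lineages=list(panels),
        lines=lines,
        pc1=pc1,
        rank=rank,
        explained_variance=explained,
        panels={k: list(v) for k, v in panels.items()},
    )


def interlineage_rank_correlation(ranking: PropensityRanking) -> pd.DataFrame:
    """Spearman r_s with exact two-sided permutation P for each lineage pair."""
    from .exact_null import MAX_EXACT_N, exact_null, exact_pvalue_tied

    lineages = ranking.lineages
    if len(lineages) < 2:
        raise AnalysisError("need at least two lineages")
    n = len(ranking.lines)
    null = exact_null(n) if 3 <= n <= MAX_EXACT_N else None
    rows = []
    for i, a in enumerate(lineages):
        for b in lineages[i + 1 :]:
            ra = ranking.rank[a].loc[ranking.lines].to_numpy(float)
            rb = ranking.rank[b].loc[ranking.lines].to_numpy(float)
            rx, ry = stats.rankdata(ra), stats.rankdata(rb)
            rxc, ryc = rx - rx.mean(), ry - ry.mean()
            denom = np.sqrt((rxc @ rxc) * (ryc @ ryc))
            r = float(rxc @ ryc / denom) if denom > 0 else float("nan")
            tied = np.unique(rx).size != n or np.unique(ry).size != n
            if not np.isfinite(r):
                p = float("nan")
            elif tied or null is None:
                p = exact_pvalue_tied(rx, ry) if n >= 3 else float("nan")
            else:
                p = null.pvalue(r)
            rows.append({"lineage_a": a, "lineage_b": b, "r_s": r, "exact_p": p})
    return pd.DataFrame(rows)
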