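"""Rank-correlation screen of filtered probes against lineage propensity ranks.

Each probe's per-line expression summary (mean over replicates by default) is
rank-correlated with each lineage's propensity rank.  Significance is decided
against the exact permutation null at the number of lines (|r_s| >= c(alpha);
with tied ranks, the exact P is recomputed by enumeration over the observed
rank multiset).  Signed candidate sets are intersected at the gene level to
find "switch" markers positively tracking one lineage and negatively tracking
the others.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import ExpressionDataset
from .errors import AnalysisError
from .exact_null import MAX_EXACT_N, ExactNull, approx_critical_value, exact_null, exact_pvalue_tied
from .ranking import PropensityRanking

logger = logging.getLogger(__name__)

__all__ = [
    "spearman_rho",
    "MarkerScreenResult",
    "screen_markers",
    "inverse_correlation_intersection",
    "top_k_table",
]


def spearman_rho(x, y) -> float:
    """Spearman's r_s: Pearson correlation of the average-ranked vectors.

    Returns NaN (with a warning) when either vector has zero rank variance;
    callers treat NaN as not significant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise AnalysisError("spearman_rho requires equal-length 1-D vectors, n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warnings.warn("zero variance in rank vector: r_s undefined", stacklevel=2)
        return float("nan")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


@dataclass
class MarkerScreenResult:
    """Per-(probe, lineage) screen statistics and derived candidate sets.

    ``table`` has one row per (probe, lineage) with columns
    ``r_s, exact_p, q_bh, significant, sign``; positive sign means higher
    expression in lines with stronger propensity for that lineage.  BH
    q-values are reported for transparency only — selection uses the raw
    exact P < alpha via the critical value, as in the screen's design.
    """

    table: pd.DataFrame
    null: ExactNull
    alpha: float
    lineages: list[str]
    probe_to_gene: dict[str, str] = field(default_factory=dict)
    n_unannotated: int = 0

    def candidate_probes(self, lineage: str, sign: int) -> set[str]:
        t = self.table
        mask = (t["lineage"] == lineage) & t["significant"] & (t["sign"] == sign)
        return set(t.loc[mask, "probe_id"])

    def candidate_genes(self, lineage: str, sign: int) -> set[str]:
        probes = self.candidate_probes(lineage, sign)
        return {self.probe_to_gene[p] for p in probes if self.probe_to_gene.get(p)}

    def candidate_counts(self) -> pd.DataFrame:
        """Probe- and gene-level candidate counts per (lineage, sign)."""
        rows = []
        for lineage in self.lineages:
            for sign, label in ((1, "positive"), (-1, "negative")):
                rows.append(
                    {
                        "lineage": lineage,
                        "sign": label,
                        "n_probes": len(self.candidate_probes(lineage, sign)),
                        "n_genes": len(self.candidate_genes(lineage, sign)),
                    }
                )
        return pd.DataFrame(rows)


def screen_markers(
    expression: ExpressionDataset,
    probes,
    ranking: PropensityRanking,
    alpha: float = 0.05,
    probe_to_gene: dict[str, str] | None = None,
    summary: str = "mean",
) -> MarkerScreenResult:
    """Correlate each probe's per-line expression rank with each lineage rank.

    ``probes`` is the (filtered) probe subset to screen; ``summary`` chooses
    the replicate summary statistic ("mean" or "median").  Expression is
    correlated against propensity orientation (higher = stronger propensity),
    so r_s > 0 reads "expressed more in lines that differentiate better".
    """
    if list(ranking.lines) != list(expression.lines):
        if set(ranking.lines) != set(expression.lines):
            raise AnalysisError("expression and ranking cover different line sets")
        order = [list(expression.lines).index(l) for l in ranking.lines]
    else:
        order = list(range(expression.n_lines))
    probes = list(probes)
    n = len(ranking.lines)
    if n <= MAX_EXACT_N:
        null = exact_null(n, alpha)
    else:
        warnings.warn(
            f"n = {n} exceeds exact-enumeration limit {MAX_EXACT_N}; "
            "using normal approximation for the critical value",
            stacklevel=2,
        )
        crit = approx_critical_value(n, alpha)
        base = exact_null(MAX_EXACT_N, alpha)
        null = ExactNull(
            n=n,
            alpha=alpha,
            abs_values=base.abs_values,
            tail=base.tail,
            values=base.values,
            pmf=base.pmf,
            critical_value=crit,
        )

    idx = expression.probe_index(probes)
    if summary == "mean":
        line_vals = expression.intensity[idx].mean(axis=2)
    elif summary == "median":
        line_vals = np.median(expression.intensity[idx], axis=2)
    else:
        raise AnalysisError(f"unknown replicate summary {summary!r}")
    line_vals = line_vals[:, order]

    # rank each probe's line summary; average ranks on ties
    expr_ranks = stats.rankdata(line_vals, axis=1)
    tied = np.array([np.unique(r).size != n for r in expr_ranks])
    constant = np.ptp(expr_ranks, axis=1) == 0

    rows = []
    for lineage in ranking.lineages:
        # orientation value: higher = stronger propensity (rank 1 = strongest)
        prop_rank = np.asarray([ranking.rank[lineage][l] for l in ranking.lines], float)
        orient = stats.rankdata(-prop_rank)
        oc = orient - orient.mean()
        ovar = oc @ oc
        prop_tied = np.unique(orient).size != n
        rc = expr_ranks - expr_ranks.mean(axis=1, keepdims=True)
        rvar = np.einsum("ij,ij->i", rc, rc)
        with np.errstate(invalid="ignore", divide="ignore"):
            r_s = (rc @ oc) / np.sqrt(rvar * ovar)
        r_s[constant] = np.nan

        for k, probe in enumerate(probes):
            r = r_s[k]
            if not np.isfinite(r):
                p = float("nan")
                sig = False
            elif tied[k] or prop_tied:
                # exact-P fallback by enumeration over the tied rank multiset
                p = exact_pvalue_tied(expr_ranks[k], orient)
                sig = p < alpha
            else:
                p = null.pvalue(r)
                sig = null.is_significant(r)
            rows.append(
                {
                    "probe_id": probe,
                    "lineage": lineage,
                    "r_s": r,
                    "exact_p": p,
                    "significant": bool(sig),
                    "sign": int(np.sign(r)) if (sig and np.isfinite(r)) else 0,
                }
            )
    table = pd.DataFrame(rows)
    # BH q-values per lineage, reported but not used for selection
    table["q_bh"] = np.nan
    for lineage in ranking.lineages:
        m = (table["lineage"] == lineage) & table["exact_p"].notna()
        if m.any():
            table.loc[m, "q_bh"] = multipletests(table.loc[m, "exact_p"], method="fdr_bh")[1]

    probe_to_gene = dict(probe_to_gene or {})
    n_unannot = sum(1 for p in probes if not probe_to_gene.get(p))
    return MarkerScreenResult(
        table=table,
        null=null,
        alpha=alpha,
        lineages=list(ranking.lineages),
        probe_to_gene=probe_to_gene,
        n_unannotated=n_unannot,
    )


def inverse_correlation_intersection(
    result: MarkerScreenResult, positive_lineage: str | None = None
) -> dict[str, set[str]]:
    """Gene-level switch-marker sets for the two orientations.

    Orientation A: genes positively correlated with ``positive_lineage``
    (first lineage by default) and negatively with every other lineage;
    orientation B is the mirror image.  Probes without gene annotation are
    excluded before intersecting (counted in ``result.n_unannotated``).
    """
    lineages = result.lineages
    if positive_lineage is None:
        positive_lineage = lineages[0]
    if positive_lineage not in lineages:
        raise AnalysisError(f"unknown lineage {positive_lineage!r}")
    others = [l for l in lineages if l != positive_lineage]

    a = result.candidate_genes(positive_lineage, +1)
    for l in others:
        a &= result.candidate_genes(l, -1)
    b = result.candidate_genes(positive_lineage, -1)
    for l in others:
        b &= result.candidate_genes(l, +1)
    return {"orientation_a": a, "orientation_b": b}


def top_k_table(result: MarkerScreenResult, k: int = 5) -> pd.DataFrame:
    """Top-k candidate genes by |r_s| per (lineage, sign).

    Probes are collapsed to genes keeping the largest |r_s|; ties break by
    gene id lexicographically so the table is deterministic.  Fewer than k
    candidates yields a short list, no padding.
    """
    if k < 0:
        raise AnalysisError("k must be >= 0")
    rows = []
    t = result.table
    for lineage in result.lineages:
        for sign, label in ((1, "positive"), (-1, "negative")):
            m = (t["lineage"] == lineage) & t["significant"] & (t["sign"] == sign)
            sub = t.loc[m, ["probe_id", "r_s"]].copy()
            sub["gene"] = [
                result.probe_to_gene.get(p) or "" for p in sub["probe_id"]
            ]
            sub = sub[sub["gene"] != ""]
            if sub.empty:
                continue
            sub["abs_r"] = sub["r_s"].abs()
            best = (
                sub.sort_values(["abs_r", "gene"], ascending=[False, True])
                .drop_duplicates("gene", keep="first")
                .sort_values(["abs_r", "gene"], ascending=[False, True])
                .head(k)
            )
            for rank_i, (_, row) in enumerate(best.iterrows(), start=1):
                rows.append(
                    {
                        "lineage": lineage,
                        "sign": label,
                        "rank": rank_i,
                        "gene": row["gene"],
                        "r_s": row["r_s"],
                    }
                )
    return pd.DataFrame(rows, columns=["lineage", "sign", "rank", "gene", "r_s"])
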