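"""Two-group differential methylation on beta values with region breakdown.

Probes failing detection (P >= threshold in any sample) or lacking
chromosome/locus annotation are excluded; the rest get a two-sample t-test,
Benjamini-Hochberg q-values, and a hyper/hypo/unchanged class from the joint
q and |log2 fold-change| thresholds.  Hyper (or hypo) probes are broken down
into seven genomic-region categories, and per-gene tracks expose probe-level
island/shore context with raw-P significance flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import REGION_CATEGORIES, REGION_PRIORITY, MethylationDataset
from .errors import AnalysisError

logger = logging.getLogger(__name__)

__all__ = [
    "detection_filter",
    "annotation_filter",
    "differential_methylation",
    "classify_probe",
    "DifferentialMethylationResult",
    "summarize_fractions",
    "region_distribution",
    "gene_track",
    "assign_region_category",
]

LFC_EPSILON = 1e-6  # floor on group-mean betas before the log ratio


def classify_probe(
    q: float, log2_fc: float, q_threshold: float = 0.05, lfc_threshold: float = 0.6
) -> str:
    """Class from the joint thresholds; both strict, so boundaries are unchanged."""
    if q < q_threshold and log2_fc > lfc_threshold:
        return "hyper"
    if q < q_threshold and log2_fc < -lfc_threshold:
        return "hypo"
    return "unchanged"


def detection_filter(data: MethylationDataset, threshold: float = 0.01) -> list[str]:
    """Probes with detection P < threshold in *every* sample (boundary excluded)."""
    ok = (data.detection_p < threshold).all(axis=(1, 2))
    return [p for p, k in zip(data.probe_ids, ok) if k]


def _has_locus(manifest: pd.DataFrame) -> pd.Series:
    chrom = manifest["CHR"].astype(object)
    pos = manifest["MAPINFO"]
    chrom_ok = chrom.notna() & (chrom.astype(str).str.strip() != "")
    pos_ok = pos.notna()
    if pos.dtype == object:
        pos_ok &= pos.astype(str).str.strip() != ""
    return chrom_ok & pos_ok


def annotation_filter(probes, manifest: pd.DataFrame) -> tuple[list[str], int]:
    """Keep probes with both chromosome and position annotated.

    Returns (retained probes, count of probes absent from the manifest);
    absent probes are removed and counted separately from unannotated ones.
    """
    ok = _has_locus(manifest)
    retained, n_missing = [], 0
    for p in probes:
        if p not in ok.index:
            n_missing += 1
        elif ok.loc[p]:
            retained.append(p)
    if n_missing:
        logger.warning("%d probe(s) absent from the manifest were removed", n_missing)
    return retained, n_missing


@dataclass
class DifferentialMethylationResult:
    """Per-probe differential statistics plus the class partition.

    ``table`` is indexed by probe id with columns mean_g1, mean_g2, log2_fc,
    t_stat, p_value, q_bh and ``cls`` in {hyper, hypo, unchanged, excluded};
    the four classes partition the full probe set of the input dataset.
    """

    table: pd.DataFrame
    q_threshold: float
    lfc_threshold: float
    groups: list[str]
    n_zero_variance: int = 0
    params: dict = field(default_factory=dict)

    def class_counts(self) -> dict[str, int]:
        c = self.table["cls"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in ("hyper", "hypo", "unchanged", "excluded")}

    @property
    def assessed(self) -> pd.DataFrame:
        return self.table[self.table["cls"] != "excluded"]


def differential_methylation(
    data: MethylationDataset,
    retained_probes,
    q_threshold: float = 0.05,
    lfc_threshold: float = 0.6,
    ttest: str = "student",
    m_values: bool = False,
) -> DifferentialMethylationResult:
    """Two-sided two-sample t-tests with BH correction and class assignment.

    ``hyper`` requires q < q_threshold AND log2FC > lfc_threshold (both
    strict, so boundary cases are unchanged); ``hypo`` is the mirror.  Probes
    outside ``retained_probes`` are classed ``excluded``.  ``ttest`` selects
    pooled-variance Student's ("student") or Welch's ("welch") variant;
    ``m_values`` switches the fold-change scale from beta to M-values.
    """
    if ttest not in ("student", "welch"):
        raise AnalysisError(f"unknown t-test variant {ttest!r}")
    if data.beta.shape[1] != 2:
        raise AnalysisError("differential methylation requires exactly two groups")
    if data.n_replicates < 2:
        raise AnalysisError("need >= 2 replicates per group")
    retained = list(retained_probes)
    idx = {p: i for i, p in enumerate(data.probe_ids)}
    rows = np.array([idx[p] for p in retained], dtype=int)

    g1 = data.beta[rows, 0, :]
    g2 = data.beta[rows, 1, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(g2, g1, axis=1, equal_var=(ttest == "student"))
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    nan_p = ~np.isfinite(p)
    n_zero = int(nan_p.sum())
    if n_zero:
        logger.warning(
            "%d probe(s) with zero variance in both groups and equal means: p = 1", n_zero
        )
        p = np.where(nan_p, 1.0, p)
        t = np.where(np.isfinite(t), t, 0.0)
    q = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])

    if m_values:
        eps = LFC_EPSILON
        mv1 = np.log2(np.clip(m1, eps, 1 - eps) / (1 - np.clip(m1, eps, 1 - eps)))
        mv2 = np.log2(np.clip(m2, eps, 1 - eps) / (1 - np.clip(m2, eps, 1 - eps)))
        lfc = mv2 - mv1
    else:
        lfc = np.log2(np.maximum(m2, LFC_EPSILON) / np.maximum(m1, LFC_EPSILON))

    cls = np.array(
        [classify_probe(qi, li, q_threshold, lfc_threshold) for qi, li in zip(q, lfc)],
        dtype=object,
    )

    table = pd.DataFrame(
        {
            "mean_g1": m1,
            "mean_g2": m2,
            "log2_fc": lfc,
            "t_stat": t,
            "p_value": p,
            "q_bh": q,
            "cls": cls,
        },
        index=pd.Index(retained, name="probe_id"),
    )
    excluded = [p_ for p_ in data.probe_ids if p_ not in set(retained)]
    if excluded:
        table = pd.concat(
            [
                table,
                pd.DataFrame(
                    {
                        "mean_g1": np.nan,
                        "mean_g2": np.nan,
                        "log2_fc": np.nan,
                        "t_stat": np.nan,
                        "p_value": np.nan,
                        "q_bh": np.nan,
                        "cls": "excluded",
                    },
                    index=pd.Index(excluded, name="probe_id"),
                ),
            ]
        )
    table = table.loc[data.probe_ids]
    return DifferentialMethylationResult(
        table=table,
        q_threshold=q_threshold,
        lfc_threshold=lfc_threshold,
        groups=list(data.groups),
        n_zero_variance=n_zero,
        params={"ttest": ttest, "m_values": m_values},
    )


def summarize_fractions(result: DifferentialMethylationResult) -> dict:
    """Percent differential among assessed probes; percent hyper among differential."""
    assessed = result.assessed
    n_assessed = len(assessed)
    if n_assessed == 0:
        raise AnalysisError("no assessed probes to summarize")
    counts = result.class_counts()
    n_diff = counts["hyper"] + counts["hypo"]
    out = {
        "n_assessed": n_assessed,
        "n_differential": n_diff,
        "pct_differential_of_assessed": 100.0 * n_diff / n_assessed,
        "denominators": {
            "pct_differential_of_assessed": "assessed probes (detection+annotation retained)",
            "pct_hyper_of_differential": "differentially methylated probes",
        },
    }
    if n_diff:
        out["pct_hyper_of_differential"] = 100.0 * counts["hyper"] / n_diff
    return out


def assign_region_category(group_annotation) -> str:
    """Collapse a (possibly multi-gene) UCSC_RefGene_Group field to one category.

    The field may hold a semicolon-separated list; the highest-priority
    association wins (TSS200 > TSS1500 > 5'UTR > 1stExon > Body > 3'UTR) and
    probes with no gene association are "intergenic".
    """
    if group_annotation is None or (isinstance(group_annotation, float) and np.isnan(group_annotation)):
        return "intergenic"
    parts = [p.strip() for p in str(group_annotation).split(";") if p.strip()]
    if not parts:
        return "intergenic"
    for cat in REGION_PRIORITY:
        if cat in parts:
            return cat
    return "intergenic"


def region_distribution(
    result: DifferentialMethylationResult,
    manifest: pd.DataFrame,
    cls: str = "hyper",
) -> pd.Series:
    """Percent distribution of ``cls`` probes over the seven region categories."""
    probes = result.table.index[result.table["cls"] == cls]
    if len(probes) == 0:
        raise AnalysisError(f"no probes in class {cls!r}")
    cats = [
        assign_region_category(manifest["UCSC_RefGene_Group"].get(p)) if p in manifest.index else "intergenic"
        for p in probes
    ]
    counts = pd.Series(cats).value_counts()
    pct = pd.Series(
        [100.0 * counts.get(c, 0) / len(probes) for c in REGION_CATEGORIES],
        index=list(REGION_CATEGORIES),
        name=f"pct_{cls}",
    )
    return pct


def gene_track(
    gene: str,
    data: MethylationDataset,
    result: DifferentialMethylationResult,
    manifest: pd.DataFrame,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Ordered per-probe methylation track for one gene.

    Rows are the gene's probes sorted by genomic position, with the CpG
    island relation, group mean betas, and a significance flag from the raw
    per-probe t-test P < ``p_threshold`` (deliberately independent of the
    genome-wide hyper/hypo classification).
    """
    names = manifest["UCSC_RefGene_Name"].fillna("").astype(str)
    hit = names.str.split(";").apply(lambda gs: gene in [g.strip() for g in gs])
    probes = manifest.index[hit]
    if len(probes) == 0:
        raise AnalysisError(f"gene {gene!r} not found in the manifest")
    sub = manifest.loc[probes]
    track = pd.DataFrame(
        {
            "probe_id": probes,
            "position": pd.to_numeric(sub["MAPINFO"], errors="coerce"),
            "island_relation": sub["Relation_to_UCSC_CpG_Island"].fillna("OpenSea"),
            "region": [assign_region_category(v) for v in sub["UCSC_RefGene_Group"]],
        }
    ).set_index("probe_id")
    stats_cols = result.table.reindex(track.index)
    track["mean_g1"] = stats_cols["mean_g1"]
    track["mean_g2"] = stats_cols["mean_g2"]
    track["p_value"] = stats_cols["p_value"]
    track["significant"] = stats_cols["p_value"] < p_threshold
    track = track.sort_values("position", kind="mergesort")
    return track.reset_index()
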