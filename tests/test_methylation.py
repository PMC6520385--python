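"""Differential methylation, BH correction, region categorization, tracks."""

import numpy as np
import pandas as pd
import pytest

from propensity_screen.datasets import MethylationDataset, REGION_CATEGORIES
from propensity_screen.errors import AnalysisError
from propensity_screen.methylation import (
    annotation_filter,
    assign_region_category,
    classify_probe,
    detection_filter,
    differential_methylation,
    gene_track,
    region_distribution,
    summarize_fractions,
)
from propensity_screen.synthetic import make_methylation_manifest


def brute_force_bh(p):
    """q_i = min over j >= i of p_(j) * m / j, mapped back to input order."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        q_sorted[i] = running
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def make_manifest(rows: dict) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "IlmnID"
    for col in ("CHR", "UCSC_RefGene_Name", "UCSC_RefGene_Group", "Relation_to_UCSC_CpG_Island"):
        if col not in df:
            df[col] = ""
    if "MAPINFO" not in df:
        df["MAPINFO"] = np.nan
    return df


def make_dataset(beta, detp=None, manifest=None, groups=("control", "knockdown")):
    beta = np.asarray(beta, dtype=float)
    if detp is None:
        detp = np.full(beta.shape, 1e-4)
    n = beta.shape[0]
    ids = [f"cg{i:06d}" for i in range(n)]
    if manifest is None:
        manifest = make_manifest(
            {pid: {"CHR": "1", "MAPINFO": float(i)} for i, pid in enumerate(ids)}
        )
    return MethylationDataset(
        beta=beta,
        detection_p=np.asarray(detp, dtype=float),
        manifest=manifest,
        probe_ids=ids,
        groups=list(groups),
    )


class TestDetectionFilter:
    def test_all_good_retained(self):
        data = make_dataset(np.full((3, 2, 3), 0.5), np.full((3, 2, 3), 0.001))
        assert len(detection_filter(data)) == 3

    def test_boundary_p_001_excluded(self):
        detp = np.full((1, 2, 3), 0.001)
        detp[0, 1, 2] = 0.01  # exactly at the threshold: >= excluded
        data = make_dataset(np.full((1, 2, 3), 0.5), detp)
        assert detection_filter(data) == []

    def test_planted_failure_fraction(self, sim):
        data = sim.methylation
        retained = detection_filter(data)
        expected_failed = round(
            sim.config.meth_detect_fail_fraction * sim.config.meth_n_probes
        )
        assert len(retained) == data.n_probes - expected_failed


class TestAnnotationFilter:
    def test_full_scale_counts(self):
        # 48 unannotated probes out of 485,577 leave 485,529
        manifest = make_methylation_manifest(485_577, n_unannotated=48)
        retained, missing = annotation_filter(list(manifest.index), manifest)
        assert len(retained) == 485_529
        assert missing == 0

    def test_identity_when_all_annotated(self):
        manifest = make_methylation_manifest(100, n_unannotated=0)
        retained, _ = annotation_filter(list(manifest.index), manifest)
        assert retained == list(manifest.index)

    def test_empty_manifest(self):
        manifest = make_manifest({})
        assert annotation_filter([], manifest) == ([], 0)

    def test_probe_absent_from_manifest_counted(self):
        manifest = make_methylation_manifest(10, n_unannotated=0)
        retained, missing = annotation_filter(["cg99999999"], manifest)
        assert retained == [] and missing == 1

    def test_commutes_with_detection_filter(self, sim):
        data = sim.methylation
        a = annotation_filter(detection_filter(data), data.manifest)[0]
        detected = set(detection_filter(data))
        b = [p for p in annotation_filter(data.probe_ids, data.manifest)[0] if p in detected]
        assert a == b


class TestClassification:
    def test_doubling_is_hyper(self):
        assert classify_probe(q=0.01, log2_fc=1.0) == "hyper"

    def test_small_ratio_unchanged(self):
        # 0.30 -> 0.40: |log2(4/3)| ~ 0.415 < 0.6
        assert classify_probe(q=0.01, log2_fc=np.log2(0.4 / 0.3)) == "unchanged"

    def test_boundaries_excluded(self):
        assert classify_probe(q=0.05, log2_fc=1.0) == "unchanged"
        assert classify_probe(q=0.01, log2_fc=0.6) == "unchanged"
        assert classify_probe(q=0.01, log2_fc=-0.6) == "unchanged"
        assert classify_probe(q=0.049999, log2_fc=0.600001) == "hyper"
        assert classify_probe(q=0.049999, log2_fc=-0.600001) == "hypo"


class TestDifferentialMethylation:
    def test_planted_doubling_flagged_hyper(self):
        beta = np.empty((40, 2, 3))
        beta[:, 0, :] = 0.2
        beta[:, 1, :] = 0.2
        beta[0, 0, :] = [0.19, 0.20, 0.21]
        beta[0, 1, :] = [0.39, 0.40, 0.41]
        beta[1:, :, :] += np.random.default_rng(0).normal(0, 0.01, size=(39, 2, 3))
        data = make_dataset(np.clip(beta, 0.01, 0.99))
        res = differential_methylation(data, data.probe_ids)
        row = res.table.iloc[0]
        assert row["log2_fc"] == pytest.approx(1.0, abs=0.01)
        assert row["cls"] == "hyper"

    def test_bh_matches_brute_force(self, rng):
        beta = np.clip(0.5 + rng.normal(0, 0.05, size=(200, 2, 3)), 0.01, 0.99)
        data = make_dataset(beta)
        res = differential_methylation(data, data.probe_ids)
        assessed = res.assessed
        q = brute_force_bh(assessed["p_value"].to_numpy())
        assert np.allclose(assessed["q_bh"].to_numpy(), q, atol=1e-12)

    def test_bh_monotone_and_dominates_p(self, rng):
        beta = np.clip(0.4 + rng.normal(0, 0.05, size=(150, 2, 3)), 0.01, 0.99)
        res = differential_methylation(make_dataset(beta), [f"cg{i:06d}" for i in range(150)])
        t = res.assessed.sort_values("p_value")
        assert (np.diff(t["q_bh"].to_numpy()) >= -1e-12).all()
        assert (t["q_bh"] >= t["p_value"] - 1e-12).all()

    def test_class_partition_identity(self, sim):
        data = sim.methylation
        retained = detection_filter(data)
        res = differential_methylation(data, retained)
        counts = res.class_counts()
        assert sum(counts.values()) == data.n_probes
        assert counts["excluded"] == data.n_probes - len(retained)

    def test_null_differential_fraction_near_zero(self, rng):
        beta = np.clip(0.5 + rng.normal(0, 0.03, size=(500, 2, 3)), 0.01, 0.99)
        data = make_dataset(beta)
        res = differential_methylation(data, data.probe_ids)
        counts = res.class_counts()
        assert (counts["hyper"] + counts["hypo"]) / 500 < 0.01

    def test_zero_variance_equal_means_p_one(self):
        beta = np.full((1, 2, 3), 0.5)
        res = differential_methylation(make_dataset(beta), ["cg000000"])
        assert res.table["p_value"].iloc[0] == 1.0
        assert res.n_zero_variance == 1

    def test_welch_variant_runs(self, rng):
        beta = np.clip(0.5 + rng.normal(0, 0.05, size=(30, 2, 3)), 0.01, 0.99)
        data = make_dataset(beta)
        res = differential_methylation(data, data.probe_ids, ttest="welch")
        assert res.params["ttest"] == "welch"


class TestSummaries:
    def test_fraction_arithmetic(self):
        beta = np.empty((100, 2, 3))
        beta[:, :, :] = 0.5
        # plant 3 hyper (0.2 -> 0.4) and 1 hypo (0.4 -> 0.2) with tiny jitter
        jit = np.array([-0.005, 0.0, 0.005])
        for i in range(3):
            beta[i, 0, :] = 0.2 + jit
            beta[i, 1, :] = 0.4 + jit
        beta[3, 0, :] = 0.4 + jit
        beta[3, 1, :] = 0.2 + jit
        beta[4:, :, :] += np.random.default_rng(1).normal(0, 0.01, size=(96, 2, 3))
        data = make_dataset(np.clip(beta, 0.01, 0.99))
        res = differential_methylation(data, data.probe_ids)
        summary = summarize_fractions(res)
        assert summary["pct_differential_of_assessed"] == pytest.approx(4.0)
        assert summary["pct_hyper_of_differential"] == pytest.approx(75.0)

    def test_all_unchanged(self):
        beta = np.clip(
            0.5 + np.random.default_rng(2).normal(0, 0.01, size=(50, 2, 3)), 0.01, 0.99
        )
        res = differential_methylation(make_dataset(beta), [f"cg{i:06d}" for i in range(50)])
        summary = summarize_fractions(res)
        if summary["n_differential"] == 0:
            assert "pct_hyper_of_differential" not in summary
        assert summary["pct_differential_of_assessed"] <= 2.0


class TestRegions:
    def test_category_priority(self):
        assert assign_region_category("Body") == "Body"
        assert assign_region_category("Body;TSS200") == "TSS200"
        assert assign_region_category("TSS1500;TSS200") == "TSS200"
        assert assign_region_category("5'UTR;1stExon;Body") == "5'UTR"
        assert assign_region_category("") == "intergenic"
        assert assign_region_category(None) == "intergenic"
        assert assign_region_category(np.nan) == "intergenic"

    def test_all_body_hundred_percent(self):
        beta = np.empty((5, 2, 3))
        jit = np.array([-0.005, 0.0, 0.005])
        beta[:, 0, :] = 0.2 + jit
        beta[:, 1, :] = 0.4 + jit
        ids = [f"cg{i:06d}" for i in range(5)]
        manifest = make_manifest(
            {pid: {"CHR": "1", "MAPINFO": float(i), "UCSC_RefGene_Group": "Body",
                   "UCSC_RefGene_Name": "G1"} for i, pid in enumerate(ids)}
        )
        data = make_dataset(beta, manifest=manifest)
        res = differential_methylation(data, ids)
        pct = region_distribution(res, manifest, cls="hyper")
        assert pct["Body"] == pytest.approx(100.0)
        assert pct.sum() == pytest.approx(100.0, abs=0.01)

    def test_percentages_sum_to_100(self, sim):
        data = sim.methylation
        retained = annotation_filter(detection_filter(data), data.manifest)[0]
        res = differential_methylation(data, retained)
        pct = region_distribution(res, data.manifest, cls="hyper")
        assert set(pct.index) == set(REGION_CATEGORIES)
        assert pct.sum() == pytest.approx(100.0, abs=0.01)

    def test_no_class_members_errors(self):
        beta = np.full((3, 2, 3), 0.5)
        res = differential_methylation(make_dataset(beta), [f"cg{i:06d}" for i in range(3)])
        with pytest.raises(AnalysisError):
            region_distribution(res, make_methylation_manifest(3), cls="hyper")


class TestGeneTrack:
    def test_single_probe_gene(self):
        beta = np.full((2, 2, 3), 0.5)
        ids = ["cg000000", "cg000001"]
        manifest = make_manifest(
            {
                "cg000000": {"CHR": "1", "MAPINFO": 100.0, "UCSC_RefGene_Name": "SOLO",
                             "UCSC_RefGene_Group": "Body",
                             "Relation_to_UCSC_CpG_Island": "Island"},
                "cg000001": {"CHR": "1", "MAPINFO": 200.0, "UCSC_RefGene_Name": "OTHER",
                             "UCSC_RefGene_Group": "Body"},
            }
        )
        data = make_dataset(beta, manifest=manifest)
        res = differential_methylation(data, ids)
        track = gene_track("SOLO", data, res, manifest)
        assert len(track) == 1
        assert track["island_relation"].iloc[0] == "Island"

    def test_positions_sorted(self, sim):
        data = sim.methylation
        retained = detection_filter(data)
        res = differential_methylation(data, retained)
        gene = sim.config.meth_hyper_genes[0]
        track = gene_track(gene, data, res, data.manifest)
        pos = track["position"].to_numpy()
        assert (np.diff(pos) >= 0).all()

    def test_planted_hyper_probes_flagged(self, sim):
        data = sim.methylation
        retained = detection_filter(data)
        res = differential_methylation(data, retained)
        gene = sim.config.meth_hyper_genes[0]
        track = gene_track(gene, data, res, data.manifest)
        body = track[track["region"] == "Body"]
        retained_set = set(retained)
        expected = body[body["probe_id"].isin(retained_set)]
        assert expected["significant"].all()

    def test_missing_gene_errors(self, sim):
        data = sim.methylation
        res = differential_methylation(data, data.probe_ids[:10])
        with pytest.raises(AnalysisError, match="NO_SUCH_GENE"):
            gene_track("NO_SUCH_GENE", data, res, data.manifest)
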