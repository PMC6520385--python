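"""Synthetic inputs with the statistical structure the analysis assumes.

The generator plants (i) latent per-line differentiation propensities for
three lineages with configurable rank-correlation coupling, (ii) expression
probes whose line-mean ranks track those propensities at specified Spearman
targets, (iii) a trilineage qPCR panel whose Ct values invert the planted
fold changes under comparative-Ct quantification, and (iv) a two-group
beta-value methylation dataset with gene-body hypermethylation planted in
named genes.

Rank-level planting: propensity coupling goes through a latent trivariate
Gaussian whose Pearson matrix is the sin-transform of the target Spearman
matrix (infeasible triples are rejected, not repaired); marker probes get
their per-line rank pattern from a pairwise-swap hill climb that minimizes
the squared distance between realized and target rank correlations, which
hits the closest attainable values exactly in the noiseless limit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ExpressionDataset, MethylationDataset
from .errors import ConfigError
from .ranking import CtTable

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedMarkerSpec",
    "SimulationConfig",
    "default_switch_marker",
    "simulate_propensities",
    "simulate_expression",
    "simulate_panel_cts",
    "simulate_methylation",
    "simulate_inputs",
    "make_panels",
    "make_methylation_manifest",
    "probe_gene_map",
]

LINEAGES = ("ectoderm", "mesoderm", "endoderm")
BETA_EPS = 1e-4  # betas are clipped strictly inside (0, 1) by this margin


@dataclass(frozen=True)
class PlantedMarkerSpec:
    """A probe planted at signed Spearman targets against lineage propensities."""

    probe_id: str
    targets: dict  # lineage -> target rank correlation in [-1, 1]
    gene: str | None = None

    def __post_init__(self) -> None:
        for lineage, t in self.targets.items():
            if not -1.0 <= t <= 1.0:
                raise ConfigError(
                    f"planted target for {lineage!r} must be in [-1, 1], got {t}"
                )


def default_switch_marker() -> PlantedMarkerSpec:
    """A switch-marker spec: positive with ectoderm, negative with the others."""
    return PlantedMarkerSpec(
        probe_id="PSW00001_at",
        targets={"ectoderm": 0.9, "mesoderm": -0.9, "endoderm": -0.9},
        gene="SWM1",
    )


@dataclass
class SimulationConfig:
    # layout
    n_lines: int = 10
    n_replicates: int = 6
    n_probes: int = 5000
    lineages: tuple = LINEAGES
    # propensity coupling (target Spearman correlations between lineage pairs)
    coupling_ecto_meso: float = -0.66
    coupling_meso_endo: float = 0.79
    coupling_ecto_endo: float = -0.52
    # expression
    planted_markers: list = field(default_factory=lambda: [default_switch_marker()])
    n_variable_null: int = 10
    absent_fraction: float = 0.4
    noise_sd: float = 0.05  # relative replicate noise (lognormal scale)
    expressed_base: float = 500.0
    planted_spread: float = 8.0  # max/min ratio of the planted line-mean ladder
    annotation_missing_rate: int = 97  # every k-th flat probe lacks a gene
    # qPCR panel
    panel_sizes: tuple = (45, 56, 27)
    panel_overlaps: tuple = (12, 13, 6)  # ecto&meso, meso&endo, ecto&endo
    shared_gene_primary_weight: float = 0.8  # dominant-lineage weight of shared genes
    housekeeping: str = "GAPDH"
    housekeeping_ct: float = 20.0
    panel_effect: float = 1.5  # log2-expression slope per propensity z-unit
    panel_noise_sd: float = 0.05  # cycles, per well
    # methylation
    meth_n_probes: int = 3000
    meth_n_replicates: int = 3
    meth_unannotated: int = 10
    meth_detect_fail_fraction: float = 0.001
    meth_beta_sd: float = 0.01
    meth_hyper_genes: tuple = ("WNTL3A", "WNTL5A")
    meth_hypo_genes: tuple = ("HPO1",)
    meth_hyper_effect: float = 0.2  # beta shift planted in group 2 body probes
    probes_per_gene: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lines", "n_replicates", "n_probes", "meth_n_probes", "meth_n_replicates"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in (
            "coupling_ecto_meso",
            "coupling_meso_endo",
            "coupling_ecto_endo",
        ):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [-1, 1], got {v}")
        for name in ("absent_fraction", "meth_detect_fail_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0 or self.panel_noise_sd < 0 or self.meth_beta_sd < 0:
            raise ConfigError("noise scales must be non-negative")
        ids = [m.probe_id for m in self.planted_markers]
        if len(set(ids)) != len(ids):
            raise ConfigError("planted marker probe ids must be unique")
        for m in self.planted_markers:
            if isinstance(m.probe_id, int) and not 0 <= m.probe_id < self.n_probes:
                raise ConfigError(f"planted probe index {m.probe_id} out of range")
            for lineage in m.targets:
                if lineage not in self.lineages:
                    raise ConfigError(f"planted marker targets unknown lineage {lineage!r}")
        if len(self.panel_sizes) != len(self.lineages):
            raise ConfigError("panel_sizes must have one entry per lineage")
        self._validate_panels()
        n_special = len(self.planted_markers) + self.n_variable_null
        if n_special + int(self.absent_fraction * self.n_probes) > self.n_probes:
            raise ConfigError("planted + variable-null + absent probes exceed n_probes")
        if self.meth_unannotated >= self.meth_n_probes:
            raise ConfigError("meth_unannotated must be < meth_n_probes")

    def _validate_panels(self) -> None:
        s1, s2, s3 = self.panel_sizes
        o12, o23, o13 = self.panel_overlaps
        uniques = (s1 - o12 - o13, s2 - o12 - o23, s3 - o23 - o13)
        if any(u < 0 for u in uniques):
            raise ConfigError("panel overlaps exceed panel sizes")

    @property
    def lines(self) -> list[str]:
        # first line doubles as the comparative-Ct reference
        return ["201B7"] + [f"L{i:02d}" for i in range(2, self.n_lines + 1)]

    @property
    def reference_line(self) -> str:
        return self.lines[0]

    @property
    def panel_total(self) -> int:
        return sum(self.panel_sizes) - sum(self.panel_overlaps)


def _coupling_matrix(config: SimulationConfig) -> np.ndarray:
    rho = np.array(
        [
            [1.0, config.coupling_ecto_meso, config.coupling_ecto_endo],
            [config.coupling_ecto_meso, 1.0, config.coupling_meso_endo],
            [config.coupling_ecto_endo, config.coupling_meso_endo, 1.0],
        ]
    )
    # Spearman target -> Pearson correlation of the latent Gaussian
    pearson = 2.0 * np.sin(np.pi * rho / 6.0)
    np.fill_diagonal(pearson, 1.0)
    return pearson


def simulate_propensities(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Latent propensity per (lineage, line) with rank-coupled construction.

    Samples a trivariate Gaussian whose Pearson matrix is the sin-transform
    of the target Spearman matrix, then rank-polishes the second and third
    lineage vectors — permuting their values across lines — so that each
    seed's realized pairwise rank correlations sit at the closest attainable
    values to the coupling targets (at n = 10 lines the raw Gaussian draw
    scatters pairwise rank correlations by more than +-0.2 around the
    target, which is far too loose to carry planted-marker structure).  A
    non-positive-semidefinite coupling triple raises ConfigError.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    pearson = _coupling_matrix(config)
    w, v = np.linalg.eigh(pearson)
    if np.min(w) < -1e-9:
        raise ConfigError(
            "infeasible propensity coupling: target rank-correlation matrix is "
            f"not positive semidefinite (min eigenvalue {np.min(w):.4f})"
        )
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = root @ rng.standard_normal((3, config.n_lines))

    def orientation(vals: np.ndarray) -> np.ndarray:
        r = stats.rankdata(vals)
        c = r - r.mean()
        sd = np.sqrt((c**2).mean())
        return c / sd if sd > 0 else c

    # rank-polish lineages 2 and 3 against the already-fixed ones
    targets_vs_prev = [
        ([0], [config.coupling_ecto_meso]),
        ([0, 1], [config.coupling_ecto_endo, config.coupling_meso_endo]),
    ]
    for li, (prev_idx, targets) in zip((1, 2), targets_vs_prev):
        prev = np.asarray([orientation(z[i]) for i in prev_idx])
        if np.allclose(prev.std(axis=1), 0.0):
            continue
        desired = _plant_rank_vector(prev, list(range(len(prev_idx))), np.asarray(targets, float), rng)
        # reassign this lineage's sampled values across lines to match ranks
        order = np.argsort(np.argsort(desired))
        z[li] = np.sort(z[li])[order]
    return pd.DataFrame(z, index=list(config.lineages), columns=config.lines)


def _propensity_orientations(propensities: pd.DataFrame) -> np.ndarray:
    """Z-scored rank vectors, higher = stronger propensity; rows = lineages."""
    vals = propensities.to_numpy(dtype=float)
    ranks = stats.rankdata(vals, axis=1)
    c = ranks - ranks.mean(axis=1, keepdims=True)
    sd = np.sqrt((c**2).mean(axis=1, keepdims=True))
    return c / sd


def _panel_gene_signals(
    config: SimulationConfig, propensities: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Per-gene propensity z-signal driving its expression across lines.

    Genes in a single panel follow that lineage's propensity z-score; genes
    shared between panels follow a weighted mix dominated by a primary
    lineage (``shared_gene_primary_weight``), with primaries alternating
    across the shared genes so both panels keep lineage-dominant members.
    """
    panels = make_panels(config)
    z = {
        lineage: stats.zscore(propensities.loc[lineage].to_numpy(float))
        if propensities.loc[lineage].std() > 0
        else np.zeros(config.n_lines)
        for lineage in config.lineages
    }
    gene_lineages: dict[str, list[str]] = {}
    for lineage in config.lineages:  # fixed lineage order, not dict order
        for g in panels[lineage]:
            gene_lineages.setdefault(g, []).append(lineage)

    w = config.shared_gene_primary_weight
    signals: dict[str, np.ndarray] = {}
    for gi, (g, ls) in enumerate(sorted(gene_lineages.items())):
        if len(ls) == 1:
            signals[g] = z[ls[0]]
            continue
        primary = ls[gi % len(ls)]
        others = [l for l in ls if l != primary]
        rest = np.mean([z[l] for l in others], axis=0)
        signals[g] = w * z[primary] + (1.0 - w) * rest
    return signals


def effective_panel_orientations(
    config: SimulationConfig, propensities: pd.DataFrame
) -> np.ndarray:
    """Panel-implied propensity orientation per lineage (z-scored ranks).

    Genes shared between panels respond to the mean of their lineages'
    propensities, so the PC1 a panel yields is a deterministic mixture of the
    latent propensities rather than the pure latent vector.  Markers are
    planted against this noiseless panel-implied orientation — what the
    ranking stage can actually recover.  With zero panel overlap it
    coincides with the latent propensity ranks.
    """
    from .ranking import pca_pc1, zscore_per_gene

    panels = make_panels(config)
    signals = _panel_gene_signals(config, propensities)

    rows = []
    for lineage in config.lineages:
        # noiseless comparative-Ct fold change: per-gene multiplicative
        # constants (baselines, reference shift) cancel in the z-scores
        cols = {
            g: np.exp2(config.panel_effect * signals[g]) for g in panels[lineage]
        }
        mat = pd.DataFrame(cols, index=config.lines)
        if np.allclose(mat.to_numpy().std(axis=0), 0.0):
            rows.append(np.zeros(config.n_lines))
            continue
        scores, _ = pca_pc1(zscore_per_gene(mat))
        ranks = stats.rankdata(scores.to_numpy())
        c = ranks - ranks.mean()
        rows.append(c / np.sqrt((c**2).mean()))
    return np.asarray(rows)


def _plant_rank_vector(
    orientations: np.ndarray,
    lineage_index: list[int],
    targets: np.ndarray,
    rng: np.random.Generator,
    n_restarts: int = 16,
) -> np.ndarray:
    """Permutation of 1..n whose rank correlations best match the targets.

    Pairwise-swap hill climb on sum((r_g - t_g)^2); warm starts come from
    the least-squares latent combination of the propensity orientations (for
    both the raw and the feasibility-rescaled target vector), the rest are
    random restarts.
    """
    o = orientations[lineage_index]  # (g, n)
    n = o.shape[1]

    def realized(y_ranks: np.ndarray) -> np.ndarray:
        c = y_ranks - y_ranks.mean()
        sd = math.sqrt(float((c**2).mean()))
        if sd == 0.0:  # fully tied warm start (e.g. all-zero targets)
            return np.zeros(len(targets))
        return (o @ c) / (n * sd)

    def objective(y_ranks: np.ndarray) -> float:
        return float(np.sum((realized(y_ranks) - targets) ** 2))

    # least-squares warm starts on the latent scale
    gram = (o @ o.T) / n
    starts = []
    try:
        w = np.linalg.solve(gram + 1e-9 * np.eye(len(targets)), targets)
        starts.append(stats.rankdata(w @ o))
        q = float(targets @ w)
        if q > 1.0:  # infeasible triple: also start from the rescaled target
            starts.append(stats.rankdata((w / math.sqrt(q)) @ o))
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        pass
    while len(starts) < n_restarts:
        starts.append(rng.permutation(n) + 1.0)

    best, best_obj = None, np.inf
    for y in starts:
        y = np.asarray(y, dtype=float)
        improved = True
        obj = objective(y)
        while improved:
            improved = False
            for i in range(n - 1):
                for j in range(i + 1, n):
                    y[i], y[j] = y[j], y[i]
                    o2 = objective(y)
                    if o2 < obj - 1e-15:
                        obj = o2
                        improved = True
                    else:
                        y[i], y[j] = y[j], y[i]
        if obj < best_obj:
            best, best_obj = y.copy(), obj
    assert best is not None
    return best


def _ladder(ranks: np.ndarray, base: float, spread: float) -> np.ndarray:
    """Monotone map from ranks (1..n) to positive line means spanning ``spread``-fold."""
    n = len(ranks)
    expo = (ranks - 1.0) / max(n - 1.0, 1.0)
    return base * spread**expo


def simulate_expression(
    config: SimulationConfig,
    propensities: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> ExpressionDataset:
    """Expression intensities and P/A calls with planted rank structure.

    Probe layout (ids in this order): planted markers, variable null probes
    (line-structured but independent of the propensities), flat expressed
    probes, absent probes.  Replicate noise is multiplicative lognormal with
    relative scale ``noise_sd``; at ``noise_sd = 0`` every replicate equals
    its line mean, so planted rank patterns are recovered exactly.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 2])
    n, reps = config.n_lines, config.n_replicates
    orientations = effective_panel_orientations(config, propensities)
    lineage_pos = {l: i for i, l in enumerate(config.lineages)}

    n_planted = len(config.planted_markers)
    n_var = config.n_variable_null
    n_absent = int(round(config.absent_fraction * config.n_probes))
    n_flat = config.n_probes - n_planted - n_var - n_absent
    if n_flat < 0:
        raise ConfigError("probe budget exhausted: reduce absent_fraction or specials")

    probe_ids: list[str] = []
    line_means = np.empty((config.n_probes, n), dtype=float)
    expressed = np.zeros(config.n_probes, dtype=bool)
    k = 0
    for marker in config.planted_markers:
        pid = (
            marker.probe_id
            if isinstance(marker.probe_id, str)
            else f"PS{int(marker.probe_id):05d}_at"
        )
        probe_ids.append(pid)
        lidx = [lineage_pos[l] for l in marker.targets]
        targets = np.array([marker.targets[l] for l in marker.targets], dtype=float)
        ranks = _plant_rank_vector(orientations, lidx, targets, rng)
        line_means[k] = _ladder(ranks, config.expressed_base, config.planted_spread)
        expressed[k] = True
        k += 1
    for i in range(n_var):
        probe_ids.append(f"PVN{i:05d}_at")
        ranks = rng.permutation(n) + 1.0
        line_means[k] = _ladder(ranks, config.expressed_base, config.planted_spread)
        expressed[k] = True
        k += 1
    flat_base = config.expressed_base * np.exp(rng.normal(0.0, 0.5, size=n_flat))
    for i in range(n_flat):
        probe_ids.append(f"PFL{i:05d}_at")
        line_means[k] = flat_base[i]
        expressed[k] = True
        k += 1
    for i in range(n_absent):
        probe_ids.append(f"PAB{i:05d}_at")
        line_means[k] = rng.uniform(1.0, 20.0, size=n)
        k += 1

    noise = rng.standard_normal((config.n_probes, n, reps))
    if config.noise_sd > 0:
        factor = np.exp(config.noise_sd * noise - 0.5 * config.noise_sd**2)
    else:
        factor = np.ones_like(noise)
    intensity = line_means[:, :, None] * factor
    calls = np.broadcast_to(
        np.where(expressed[:, None, None], "P", "A"), intensity.shape
    ).astype("U1")
    return ExpressionDataset(
        intensity=intensity,
        calls=calls,
        probe_ids=probe_ids,
        lines=config.lines,
        normalized=False,
    )


def probe_gene_map(config: SimulationConfig, probe_ids) -> dict[str, str]:
    """Deterministic probe -> gene annotation for the simulated universe.

    Planted markers carry their configured gene symbol; every
    ``annotation_missing_rate``-th flat probe is deliberately left without a
    gene so the unannotated-probe paths are exercised downstream.
    """
    planted_genes = {
        (m.probe_id if isinstance(m.probe_id, str) else f"PS{int(m.probe_id):05d}_at"): (
            m.gene or f"GENE_{m.probe_id}"
        )
        for m in config.planted_markers
    }
    out: dict[str, str] = {}
    flat_seen = 0
    for pid in probe_ids:
        if pid in planted_genes:
            out[pid] = planted_genes[pid]
            continue
        if pid.startswith("PFL"):
            flat_seen += 1
            if config.annotation_missing_rate and flat_seen % config.annotation_missing_rate == 0:
                out[pid] = ""
                continue
        out[pid] = "G_" + pid.rsplit("_", 1)[0]
    return out


def make_panels(config: SimulationConfig) -> dict[str, list[str]]:
    """Overlapping marker-gene panels per lineage (default 45/56/27, 97 total)."""
    s1, s2, s3 = config.panel_sizes
    o12, o23, o13 = config.panel_overlaps
    em = [f"EM{i:03d}" for i in range(o12)]
    me = [f"ME{i:03d}" for i in range(o23)]
    ee = [f"EE{i:03d}" for i in range(o13)]
    ecto = [f"ECT{i:03d}" for i in range(s1 - o12 - o13)] + em + ee
    meso = [f"MES{i:03d}" for i in range(s2 - o12 - o23)] + em + me
    endo = [f"END{i:03d}" for i in range(s3 - o23 - o13)] + me + ee
    return {
        config.lineages[0]: ecto,
        config.lineages[1]: meso,
        config.lineages[2]: endo,
    }


def simulate_panel_cts(
    config: SimulationConfig,
    propensities: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> CtTable:
    """Duplicate-well Ct table for the trilineage panel plus housekeeping.

    A panel gene's log2 expression rises with its lineage's propensity
    (genes shared between panels follow the mean of their lineages'
    propensity z-scores), so its Ct falls as propensity rises.  The
    housekeeping gene is constant up to noise, and duplicate wells differ
    only by noise.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 3])
    signals = _panel_gene_signals(config, propensities)

    rows = []
    genes = sorted(signals)
    baselines = {g: 5.0 + 5.0 * rng.random() for g in genes}
    for line_i, line in enumerate(config.lines):
        for rep in range(1, config.n_replicates + 1):
            for well in (1, 2):
                hk_noise = config.panel_noise_sd * rng.standard_normal()
                rows.append(
                    {
                        "line": line,
                        "replicate": rep,
                        "gene": config.housekeeping,
                        "well": well,
                        "ct": config.housekeeping_ct + hk_noise,
                    }
                )
                for g in genes:
                    dct_true = baselines[g] - config.panel_effect * float(signals[g][line_i])
                    noise = config.panel_noise_sd * rng.standard_normal()
                    rows.append(
                        {
                            "line": line,
                            "replicate": rep,
                            "gene": g,
                            "well": well,
                            "ct": config.housekeeping_ct + dct_true + noise,
                        }
                    )
    return CtTable(
        data=pd.DataFrame(rows),
        housekeeping=config.housekeeping,
        reference_line=config.reference_line,
    )


def make_methylation_manifest(
    n_probes: int,
    n_unannotated: int = 0,
    probes_per_gene: int = 8,
    special_genes: tuple = (),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """HM450-style manifest: CHR, MAPINFO, gene, region group, island relation.

    ``special_genes`` get dedicated probe blocks rich in island/shore
    gene-body probes (used for planted hypermethylation and gene tracks).
    ``n_unannotated`` probes are left without chromosome and locus.
    """
    if rng is None:
        rng = np.random.default_rng(7)
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    region_choices = np.array(["TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", ""])
    region_probs = np.array([0.15, 0.12, 0.08, 0.05, 0.35, 0.05, 0.20])
    relation_choices = np.array(["Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"])
    relation_probs = np.array([0.31, 0.12, 0.12, 0.05, 0.05, 0.35])

    regions = rng.choice(region_choices, size=n_probes, p=region_probs)
    relations = rng.choice(relation_choices, size=n_probes, p=relation_probs)
    chroms = rng.integers(1, 23, size=n_probes).astype(str)
    positions = rng.integers(10_000, 200_000_000, size=n_probes)

    gene_idx = np.arange(n_probes) // max(probes_per_gene, 1)
    genes = np.where(regions == "", "", np.char.add("MG", np.char.zfill(gene_idx.astype(str), 6)))

    # dedicated blocks for the special genes: one promoter-to-body stretch each
    special_layout = ["TSS1500", "TSS200", "5'UTR", "1stExon"] + ["Body"] * 7 + ["3'UTR"]
    special_relation = (
        ["N_Shelf", "N_Shore", "Island", "Island"]
        + ["Island", "Island", "S_Shore", "Island", "Island", "N_Shore", "Island"]
        + ["S_Shelf"]
    )
    cursor = 0
    for gi, gene in enumerate(special_genes):
        block = slice(cursor, cursor + len(special_layout))
        regions[block] = special_layout
        relations[block] = special_relation
        genes[block] = gene
        chroms[block] = str(1 + gi % 22)
        positions[block] = 1_000_000 * (gi + 1) + 500 * np.arange(len(special_layout))
        cursor += len(special_layout)

    manifest = pd.DataFrame(
        {
            "CHR": chroms,
            "MAPINFO": positions.astype(float),
            "UCSC_RefGene_Name": genes,
            "UCSC_RefGene_Group": regions,
            "Relation_to_UCSC_CpG_Island": relations,
        },
        index=pd.Index(probe_ids, name="IlmnID"),
    )
    if n_unannotated:
        # strip locus annotation from probes spread across the tail
        drop = np.linspace(cursor, n_probes - 1, n_unannotated).astype(int)
        manifest.iloc[drop, manifest.columns.get_loc("CHR")] = ""
        manifest.iloc[drop, manifest.columns.get_loc("MAPINFO")] = np.nan
        manifest.iloc[drop, manifest.columns.get_loc("UCSC_RefGene_Name")] = ""
        manifest.iloc[drop, manifest.columns.get_loc("UCSC_RefGene_Group")] = ""
    return manifest


def simulate_methylation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> MethylationDataset:
    """Two-group beta matrix with planted gene-body hyper/hypomethylation.

    Body probes of ``meth_hyper_genes`` are shifted up by
    ``meth_hyper_effect`` in group 2 (and ``meth_hypo_genes`` down); a
    ``meth_detect_fail_fraction`` of probes fails detection in one sample and
    ``meth_unannotated`` probes lack chromosome/locus.  Draws falling outside
    (0, 1) are clipped and counted in ``clip_count``.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 4])
    special = tuple(config.meth_hyper_genes) + tuple(config.meth_hypo_genes)
    manifest = make_methylation_manifest(
        config.meth_n_probes,
        n_unannotated=config.meth_unannotated,
        probes_per_gene=config.probes_per_gene,
        special_genes=special,
        rng=rng,
    )
    n_probes = config.meth_n_probes
    reps = config.meth_n_replicates
    probe_ids = list(manifest.index)

    base = 0.05 + 0.9 * rng.beta(0.5, 0.5, size=n_probes)
    is_body = (manifest["UCSC_RefGene_Group"] == "Body").to_numpy()
    hyper_mask = is_body & manifest["UCSC_RefGene_Name"].isin(config.meth_hyper_genes).to_numpy()
    hypo_mask = is_body & manifest["UCSC_RefGene_Name"].isin(config.meth_hypo_genes).to_numpy()
    # anchor planted baselines so the shift lands inside (0, 1) with margin
    base[hyper_mask] = 0.2
    base[hypo_mask] = 0.2 + config.meth_hyper_effect

    mean = np.repeat(base[:, None], 2, axis=1)  # (probes, groups)
    mean[hyper_mask, 1] += config.meth_hyper_effect
    mean[hypo_mask, 1] -= config.meth_hyper_effect

    draws = mean[:, :, None] + config.meth_beta_sd * rng.standard_normal((n_probes, 2, reps))
    lo, hi = BETA_EPS, 1.0 - BETA_EPS
    clip_count = int(np.sum((draws < lo) | (draws > hi)))
    if clip_count:
        logger.warning("clipped %d beta draw(s) back into (0, 1)", clip_count)
    beta = np.clip(draws, lo, hi)

    detection_p = rng.uniform(0.0, 0.002, size=(n_probes, 2, reps))
    n_fail = int(round(config.meth_detect_fail_fraction * n_probes))
    if n_fail:
        fail_probes = rng.choice(n_probes, size=n_fail, replace=False)
        gsel = rng.integers(0, 2, size=n_fail)
        rsel = rng.integers(0, reps, size=n_fail)
        detection_p[fail_probes, gsel, rsel] = rng.uniform(0.01, 0.5, size=n_fail)

    return MethylationDataset(
        beta=beta,
        detection_p=detection_p,
        manifest=manifest,
        probe_ids=probe_ids,
        groups=["control", "knockdown"],
        clip_count=clip_count,
    )


@dataclass
class SimulatedInputs:
    """Bundle of every synthetic input the pipeline consumes."""

    config: SimulationConfig
    propensities: pd.DataFrame
    expression: ExpressionDataset
    gene_map: dict[str, str]
    ct_table: CtTable
    panels: dict[str, list[str]]
    methylation: MethylationDataset


def simulate_inputs(config: SimulationConfig) -> SimulatedInputs:
    """Generate all inputs with a single seeded generator threaded through."""
    rng = np.random.default_rng(config.seed)
    propensities = simulate_propensities(config, rng)
    expression = simulate_expression(config, propensities, rng)
    gene_map = probe_gene_map(config, expression.probe_ids)
    ct_table = simulate_panel_cts(config, propensities, rng)
    methylation = simulate_methylation(config, rng)
    return SimulatedInputs(
        config=config,
        propensities=propensities,
        expression=expression,
        gene_map=gene_map,
        ct_table=ct_table,
        panels=make_panels(config),
        methylation=methylation,
    )
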