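"""Synthetic-data generator: determinism, planted structure, call consistency."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from propensity_screen.errors import ConfigError
from propensity_screen.filtering import present_filter
from propensity_screen.synthetic import (
    BETA_EPS,
    PlantedMarkerSpec,
    SimulationConfig,
    default_switch_marker,
    make_panels,
    probe_gene_map,
    simulate_expression,
    simulate_inputs,
    simulate_methylation,
    simulate_panel_cts,
    simulate_propensities,
)


class TestConfig:
    def test_defaults_valid(self):
        cfg = SimulationConfig()
        assert cfg.n_lines == 10 and cfg.n_replicates == 6
        assert cfg.panel_sizes == (45, 56, 27)
        assert cfg.panel_total == 97

    def test_bad_counts_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_lines=0)

    def test_bad_coupling_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(coupling_ecto_meso=-1.5)

    def test_duplicate_planted_ids_rejected(self):
        m = default_switch_marker()
        with pytest.raises(ConfigError):
            SimulationConfig(planted_markers=[m, m])

    def test_planted_index_out_of_range_rejected(self):
        bad = PlantedMarkerSpec(probe_id=10_000, targets={"ectoderm": 0.5})
        with pytest.raises(ConfigError):
            SimulationConfig(n_probes=100, planted_markers=[bad])

    def test_planted_target_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            PlantedMarkerSpec(probe_id="x", targets={"ectoderm": 1.2})


class TestPropensities:
    def test_infeasible_coupling_rejected(self):
        with pytest.raises(ConfigError, match="not positive semidefinite"):
            cfg = SimulationConfig(
                coupling_ecto_meso=0.95,
                coupling_meso_endo=0.95,
                coupling_ecto_endo=-0.95,
            )
            simulate_propensities(cfg)

    def test_realized_coupling_near_targets_over_seeds(self):
        realized = []
        for seed in range(25):
            p = simulate_propensities(SimulationConfig(n_probes=50, seed=seed))
            realized.append(
                [
                    stats.spearmanr(p.iloc[0], p.iloc[1]).statistic,
                    stats.spearmanr(p.iloc[1], p.iloc[2]).statistic,
                ]
            )
        mean = np.mean(realized, axis=0)
        assert mean[0] == pytest.approx(-0.66, abs=0.15)
        assert mean[1] == pytest.approx(0.79, abs=0.15)

    def test_zero_coupling_centered_at_zero(self):
        realized = []
        for seed in range(40):
            cfg = SimulationConfig(
                n_probes=50,
                seed=seed,
                coupling_ecto_meso=0.0,
                coupling_meso_endo=0.0,
                coupling_ecto_endo=0.0,
            )
            p = simulate_propensities(cfg)
            realized.append(stats.spearmanr(p.iloc[0], p.iloc[1]).statistic)
        assert abs(float(np.mean(realized))) < 0.12

    def test_perfect_dependence_identical_ranks(self):
        cfg = SimulationConfig(
            n_probes=50,
            coupling_ecto_meso=1.0,
            coupling_meso_endo=1.0,
            coupling_ecto_endo=1.0,
        )
        p = simulate_propensities(cfg)
        r = stats.rankdata(p.to_numpy(), axis=1)
        assert np.array_equal(r[0], r[1]) and np.array_equal(r[1], r[2])

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_probes=50, seed=9)
        a = simulate_propensities(cfg)
        b = simulate_propensities(cfg)
        assert a.equals(b)


class TestExpression:
    def test_noiseless_planting_exact(self):
        from propensity_screen.synthetic import effective_panel_orientations

        marker = PlantedMarkerSpec(probe_id="PM_at", targets={"ectoderm": 1.0})
        cfg = SimulationConfig(
            n_probes=50, noise_sd=0.0, planted_markers=[marker], seed=3
        )
        rng = np.random.default_rng(0)
        prop = simulate_propensities(cfg, rng)
        data = simulate_expression(cfg, prop, rng)
        means = data.line_means(["PM_at"]).to_numpy()[0]
        orient = effective_panel_orientations(cfg, prop)[0]
        assert np.array_equal(stats.rankdata(means), stats.rankdata(orient))

    def test_call_matrix_consistency(self, sim):
        data = sim.expression
        retained = set(present_filter(data))
        for pid in data.probe_ids:
            if pid.startswith("PAB"):
                assert pid not in retained
            else:
                assert pid in retained

    def test_absent_probes_low_intensity(self, sim):
        data = sim.expression
        absent = [p for p in data.probe_ids if p.startswith("PAB")]
        assert data.line_means(absent).to_numpy().max() < 50

    def test_byte_identical_outputs(self, small_config):
        a = simulate_inputs(small_config)
        b = simulate_inputs(small_config)
        assert np.array_equal(a.expression.intensity, b.expression.intensity)
        assert np.array_equal(a.expression.calls, b.expression.calls)
        assert a.ct_table.data.equals(b.ct_table.data)
        assert np.array_equal(a.methylation.beta, b.methylation.beta)
        assert a.methylation.manifest.equals(b.methylation.manifest)

    def test_null_flag_rate_bounded(self, rng):
        # 2000 variable-null probes, no planted markers: flag rate at the
        # exact two-sided tail mass, within binomial tolerance
        from conftest import ranking_from_scores
        from propensity_screen.exact_null import exact_null
        from propensity_screen.screen import screen_markers

        cfg = SimulationConfig(
            n_probes=2000,
            planted_markers=[],
            n_variable_null=2000,
            absent_fraction=0.0,
            seed=17,
        )
        prop = simulate_propensities(cfg)
        data = simulate_expression(cfg, prop)
        ranking = ranking_from_scores(
            {"ectoderm": prop.loc["ectoderm"].to_numpy()}, cfg.lines
        )
        res = screen_markers(data, data.probe_ids, ranking)
        null = exact_null(10)
        tail = null.pvalue(null.critical_value)
        se = np.sqrt(tail * (1 - tail) / 2000)
        assert res.table["significant"].mean() <= tail + 3 * se


class TestPanelCts:
    def test_panel_sizes_and_total(self):
        panels = make_panels(SimulationConfig())
        sizes = [len(v) for v in panels.values()]
        assert sizes == [45, 56, 27]
        assert len(set().union(*map(set, panels.values()))) == 97

    def test_constant_propensity_identical_ct(self):
        import pandas as pd

        cfg = SimulationConfig(n_probes=50, panel_noise_sd=0.0, n_lines=4)
        prop = pd.DataFrame(
            np.zeros((3, 4)), index=list(cfg.lineages), columns=cfg.lines
        )
        table = simulate_panel_cts(cfg, prop)
        per_line = table.data.groupby(["gene", "line"])["ct"].mean().unstack("line")
        assert np.allclose(per_line.to_numpy(), per_line.to_numpy()[:, [0]])

    def test_duplicate_wells_identical_at_zero_noise(self):
        cfg = SimulationConfig(n_probes=50, panel_noise_sd=0.0, n_lines=3)
        prop = simulate_propensities(cfg)
        table = simulate_panel_cts(cfg, prop)
        wide = table.data.pivot_table(
            index=["line", "replicate", "gene"], columns="well", values="ct"
        )
        assert np.allclose(wide[1], wide[2])

    def test_ddct_inversion_recovers_planted_fold(self):
        # a 2x expression difference appears as ddCt = -1, fold 2
        from propensity_screen.ranking import comparative_ct

        cfg = SimulationConfig(n_probes=50, panel_noise_sd=0.0, n_lines=2, panel_effect=1.0)
        import pandas as pd

        # propensity z will be (-1, +1): one log2 unit apart under zscore
        prop = pd.DataFrame(
            [[-1.0, 1.0]] * 3, index=list(cfg.lineages), columns=cfg.lines
        )
        table = simulate_panel_cts(cfg, prop)
        folds = comparative_ct(table)
        pure_ecto = [g for g in folds.columns if g.startswith("ECT")][0]
        ratio = (
            folds[pure_ecto].xs(cfg.lines[1], level="line").mean()
            / folds[pure_ecto].xs(cfg.lines[0], level="line").mean()
        )
        assert ratio == pytest.approx(4.0)  # 2 z-units * effect 1.0 = 2 doublings


class TestMethylationSim:
    def test_betas_strictly_inside_unit_interval(self, sim):
        b = sim.methylation.beta
        assert b.min() >= BETA_EPS and b.max() <= 1 - BETA_EPS

    def test_clip_count_matches_out_of_range_draws(self):
        cfg = SimulationConfig(
            n_probes=50, meth_n_probes=400, meth_beta_sd=0.3, seed=2
        )
        data = simulate_methylation(cfg)
        assert data.clip_count > 0
        at_bounds = int(
            np.sum((data.beta == BETA_EPS) | (data.beta == 1 - BETA_EPS))
        )
        assert at_bounds == data.clip_count

    def test_planted_hypermethylation_effect(self, sim):
        data = sim.methylation
        hyper = data.manifest[
            (data.manifest["UCSC_RefGene_Group"] == "Body")
            & data.manifest["UCSC_RefGene_Name"].isin(sim.config.meth_hyper_genes)
        ].index
        rows = [data.probe_ids.index(p) for p in hyper]
        diff = data.beta[rows, 1, :].mean() - data.beta[rows, 0, :].mean()
        assert diff == pytest.approx(sim.config.meth_hyper_effect, abs=0.02)

    def test_unannotated_count(self, sim):
        m = sim.methylation.manifest
        n_unannot = int((m["CHR"] == "").sum())
        assert n_unannot == sim.config.meth_unannotated


class TestGeneMap:
    def test_planted_marker_gene_name(self, sim):
        assert sim.gene_map["PSW00001_at"] == "SWM1"

    def test_some_flat_probes_unannotated(self, sim):
        flat = [p for p in sim.expression.probe_ids if p.startswith("PFL")]
        missing = [p for p in flat if sim.gene_map[p] == ""]
        assert len(missing) == len(flat) // sim.config.annotation_missing_rate
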