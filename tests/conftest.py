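import numpy as np
import pytest

from propensity_screen.ranking import PropensityRanking
from propensity_screen.synthetic import SimulationConfig, simulate_inputs


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_probes=600, meth_n_probes=800, seed=11)


@pytest.fixture(scope="session")
def sim(small_config):
    return simulate_inputs(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


def ranking_from_scores(scores: dict[str, np.ndarray], lines) -> PropensityRanking:
    """Build a PropensityRanking directly from per-lineage score vectors."""
    import pandas as pd
    from scipy import stats

    pc1 = {k: pd.Series(v, index=lines) for k, v in scores.items()}
    rank = {
        k: pd.Series(stats.rankdata(-np.asarray(v, float)), index=lines)
        for k, v in scores.items()
    }
    return PropensityRanking(
        lineages=list(scores),
        lines=list(lines),
        pc1=pc1,
        rank=rank,
        explained_variance={k: 1.0 for k in scores},
    )
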