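import numpy as np
import pandas as pd
import pytest

from ilqtl.simulate import SimulationRecipe, simulate_experiment
from ilqtl.types import AnalysisConfig


@pytest.fixture(scope="session")
def small_recipe() -> SimulationRecipe:
    """A reduced library that keeps whole-pipeline tests fast."""
    return SimulationRecipe(n_lines=12, n_planted_qtl=4, rng_seed=11)


@pytest.fixture(scope="session")
def small_experiment(small_recipe):
    return simulate_experiment(small_recipe)


@pytest.fixture(scope="session")
def default_config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def balanced_table(values_by_line: dict[str, dict[str, list[float]]],
                   trait: str = "Y") -> pd.DataFrame:
    """Build a long-format table from {line: {treatment: [rep values]}}."""
    rows = []
    for line_id, by_trt in values_by_line.items():
        for trt, vals in by_trt.items():
            for rep, v in enumerate(vals, start=1):
                rows.append({"line_id": line_id, "treatment": trt,
                             "replicate": rep, "trait": trait, "value": v})
    return pd.DataFrame(rows)
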