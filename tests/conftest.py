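import numpy as np
import pandas as pd
import pytest

from lymphoscape import ExpressionMatrix, generate_cohort, run_landscape
from lymphoscape.simulate import CohortSpec, ModuleDef


def make_mini_spec(sigma_act: float = 0.15, sigma_noise: float = 0.5,
                   seed: int = 7, n_per_group: int = 30) -> CohortSpec:
    """Two anti-correlated planted modules over two subtypes, plus a third
    module private to Y — small enough for fast SOM training."""
    activation = pd.DataFrame(
        {"M": [1.0, -1.0], "N": [-1.0, 1.0], "P": [0.0, 1.0]},
        index=["X", "Y"],
    )
    return CohortSpec(
        strata={"X": n_per_group, "Y": n_per_group},
        modules=[ModuleDef("M", 40), ModuleDef("N", 40), ModuleDef("P", 30)],
        activation=activation,
        sigma_act=sigma_act,
        sigma_noise=sigma_noise,
        background_genes=290,
        seed=seed,
    )


@pytest.fixture(scope="session")
def mini_spec():
    return make_mini_spec()


@pytest.fixture(scope="session")
def mini_cohort(mini_spec):
    return generate_cohort(mini_spec)


@pytest.fixture(scope="session")
def mini_landscape(mini_cohort):
    em, truth = mini_cohort
    result = run_landscape(em, rows=8, cols=8, epochs=10, seed=7,
                           spot_quantile=0.6, min_spot_size=2)
    result.truth = truth
    from lymphoscape.pipeline import match_spots_to_modules
    result.spot_of_module = match_spots_to_modules(result.spots, truth)
    return result


@pytest.fixture()
def small_matrix():
    rng = np.random.default_rng(11)
    values = rng.normal(8.0, 1.0, size=(100, 20))
    return ExpressionMatrix([f"g{i}" for i in range(100)],
                            [f"s{j}" for j in range(20)], values)
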