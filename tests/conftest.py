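import numpy as np
import pandas as pd
import pytest

from timeuse_coda import CohortConfig, OutcomeEffects, generate_cohort


@pytest.fixture(scope="session")
def null_cohort() -> pd.DataFrame:
    """A 384-participant cohort with no composition or covariate effects."""
    return generate_cohort(CohortConfig(n=384, seed=11))


@pytest.fixture(scope="session")
def effect_cohort() -> pd.DataFrame:
    """A cohort where only processing speed depends on the composition."""
    cfg = CohortConfig(
        n=384,
        seed=12,
        outcomes={
            "global_cognition": OutcomeEffects(intercept=95.1, noise_sd=3.6),
            "ltm": OutcomeEffects(),
            "stm": OutcomeEffects(),
            "exec": OutcomeEffects(),
            "speed": OutcomeEffects(beta_composition=(0.8, -0.5, 0.4), noise_sd=1.0),
        },
    )
    return generate_cohort(cfg)


def random_positive_composition(rng: np.random.Generator) -> np.ndarray:
    """A strictly positive random 4-part composition closed to 1440."""
    x = rng.lognormal(mean=np.log([500, 650, 180, 90]), sigma=0.4)
    return x * (1440.0 / x.sum())
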