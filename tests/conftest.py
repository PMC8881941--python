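import numpy as np
import pandas as pd
import pytest

from metabosense.synthetic import simulate_response


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def comparison_factory():
    """Factory for simulated comparison tables with known true JND.

    Reference rates A are uniform over the study's 1.5-6.6 W/kg range;
    stimulus differences x are uniform over the requested span; responses are
    Bernoulli draws from the psychometric function at the true JND.
    """

    def make(
        true_jnd: float,
        n: int = 99,
        seed: int = 0,
        lapse: float = 0.02,
        x_span: tuple[float, float] = (-40.0, 60.0),
        participant_id: str = "P01",
    ) -> pd.DataFrame:
        gen = np.random.default_rng(seed)
        a = gen.uniform(1.5, 6.6, n)
        x = gen.uniform(*x_span, n)
        r = [simulate_response(xi, true_jnd, lapse, gen) for xi in x]
        return pd.DataFrame(
            {
                "participant_id": participant_id,
                "block": 1,
                "pair_index": np.arange(1, n + 1),
                "A_w_per_kg": a,
                "B_w_per_kg": a * (1 + x / 100.0),
                "x_percent": x,
                "response": r,
            }
        )

    return make
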