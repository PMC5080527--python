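import numpy as np
import pytest

import raschval as rv

# the 7-item core scale (labels and difficulties after elimination) and the
# planted 10-item scenario used by pipeline tests
CORE7 = [
    ("sad", 0.06),
    ("no_interest", 1.57),
    ("sleep", 0.18),
    ("cognition", 0.39),
    ("suicidal_ideas", 1.13),
    ("mood_instability", 2.29),
    ("irritability", -0.75),
]


def planted_scenario(seed: int):
    """7 Rasch items + 2 low-slope noise items + 1 near-duplicate of cognition."""
    labels = [l for l, _ in CORE7] + ["noisy1", "noisy2", "dup"]
    betas = [b for _, b in CORE7] + [0.5, 1.0, 0.39]
    slopes = [1.0] * 7 + [0.3, 0.3, 1.0]
    cfg = rv.SyntheticConfig(
        n_persons=1000,
        item_labels=labels,
        item_difficulties=betas,
        misfit_slopes=slopes,
        dependence_spec=[rv.DependenceSpec("cognition", "dup", 0.9)],
        seed=seed,
    )
    return rv.generate_responses(cfg)


@pytest.fixture(scope="session")
def default_data():
    """One default 11-item sample with its truth record (n=1000, seed 7)."""
    return rv.generate_responses(rv.SyntheticConfig(n_persons=1000, seed=7))


@pytest.fixture(scope="session")
def default_fit(default_data):
    data, truth = default_data
    items = rv.fit_cml(data)
    persons = rv.estimate_abilities(data, items)
    return data, truth, items, persons


@pytest.fixture
def tiny_matrix():
    x = np.array([[1, 0, 0], [1, 1, 0], [0, 1, 1], [1, 1, 1], [0, 0, 1], [1, 0, 1]])
    return rv.ResponseMatrix(x, ["a", "b", "c"])
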