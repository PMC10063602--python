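import numpy as np
import pytest

from nmm import Person, ResponseMatrix, rasch_probability


def simulate_flat(
    seed: int,
    n_persons: int = 500,
    deltas=None,
    theta_mean: float = 0.0,
    theta_sd: float = 1.5,
    groups=("HC", "AD"),
):
    """Model-true single-pattern cohort used across the diagnostic tests.

    Returns (ResponseMatrix, true deltas, true thetas); group labels are
    assigned alternately so the two groups have the same ability law.
    """
    rng = np.random.default_rng(seed)
    d = np.asarray(deltas if deltas is not None else np.linspace(-3, 3, 20))
    theta = rng.normal(theta_mean, theta_sd, n_persons)
    prob = rasch_probability(theta[:, None], d[None, :])
    values = (rng.random(prob.shape) < prob).astype(float)
    persons = [
        Person(f"p{i:04d}", groups[i % len(groups)], ("F", "M")[i % 2])
        for i in range(n_persons)
    ]
    rm = ResponseMatrix(persons, [f"i{j:02d}" for j in range(d.size)], values)
    return rm, d, theta


@pytest.fixture(scope="session")
def flat_cohort():
    """One model-true 500 x 20 cohort shared by deterministic checks."""
    return simulate_flat(seed=42)
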