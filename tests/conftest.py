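import numpy as np
import pytest

from adheresim import TrialData, get_scenario, replicate_rng, simulate_trial


@pytest.fixture(scope="session")
def s1_trial():
    """A moderate-size trial from the logistic-link setting (fixed seed)."""
    return simulate_trial(get_scenario("S1", 3), 2000, 20220216)


@pytest.fixture(scope="session")
def s2_trial():
    """A trial from the linear-link unmeasured-confounding setting."""
    return simulate_trial(get_scenario("S2", 9), 2000, 20220216)


@pytest.fixture()
def toy_trial():
    """Small covariate-free trial with two-sided nonadherence."""
    rng = np.random.default_rng(5)
    n = 400
    Z = rng.binomial(1, 0.5, n).astype(np.int8)
    A = np.where(rng.random(n) < 0.8, Z, 1 - Z).astype(np.int8)
    Y = rng.binomial(1, 0.2 + 0.3 * A).astype(np.int8)
    return TrialData(Z=Z, A=A, Y=Y)


def small_trial_from_counts(counts):
    """Expand {(z, a, y): count} into a TrialData (deterministic order)."""
    Z, A, Y = [], [], []
    for (z, a, y), k in sorted(counts.items()):
        Z += [z] * k
        A += [a] * k
        Y += [y] * k
    return TrialData(Z=np.array(Z, np.int8), A=np.array(A, np.int8),
                     Y=np.array(Y, np.int8))
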