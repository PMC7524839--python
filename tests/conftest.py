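import numpy as np
import pytest

from dyndisc.fixtures import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def small_store():
    """Six-stimulus ramp-tuned synthetic store, 5 repeats, deterministic."""
    return generate_fixture(
        FixtureSpec(n_stimuli=6, trials_per_stimulus=5, seed=7)
    )


@pytest.fixture(scope="session")
def clean_lorenz_states():
    """Fully sampled clean Lorenz state trajectory (sigma=10, beta=8/3,
    rho=28), dt = 1e-3 time units."""
    from scipy.integrate import solve_ivp

    dt = 1e-3
    t = np.arange(0, 20, dt)
    sol = solve_ivp(
        lambda t, s: [10 * (s[1] - s[0]), s[0] * (28 - s[2]) - s[1],
                      s[0] * s[1] - 8 / 3 * s[2]],
        (0, t[-1]), [1.0, 1.0, 1.0], t_eval=t, rtol=1e-10, atol=1e-12,
    )
    return sol.y.T, dt
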