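import numpy as np
import pandas as pd
import pytest

from metadyn import kinetics, steady_state, synthetic


def rk4_trajectory(params, n_steps):
    """Independent fixed-step RK4 integration of the CoA state equations,
    used as the oracle for the adaptive solver."""
    model = kinetics.CoAKineticModel(params)
    h = params.t_end / n_steps
    y = np.array([params.coa_0, params.biomass_0])
    ts = [0.0]
    ys = [y.copy()]
    f = lambda t, y: np.asarray(model._rhs(t, y))
    for i in range(n_steps):
        t = i * h
        k1 = f(t, y)
        k2 = f(t + h / 2, y + h / 2 * k1)
        k3 = f(t + h / 2, y + h / 2 * k2)
        k4 = f(t + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        ts.append((i + 1) * h)
        ys.append(y.copy())
    return np.asarray(ts), np.asarray(ys)


@pytest.fixture(scope="session")
def rk4_oracle():
    return rk4_trajectory


@pytest.fixture(scope="session")
def small_cfg():
    return synthetic.SyntheticConfig(
        n_cell_lines=3, n_ions=30, n_background_ions=3, replicates=3, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return synthetic.generate_steady_state_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    intensities, meta, _ = small_dataset
    return steady_state.SteadyStateModel(intensities, meta).fit()


def noiseless_two_line_data():
    """Exact data from I = alpha_j*N + beta for two lines, handy oracle input."""
    alphas = {"A": 100.0, "B": 200.0}
    beta = 50.0
    rows, intensities = [], []
    for line, alpha in alphas.items():
        for k, n in enumerate([1000, 2000, 3000, 4000, 5000]):
            rows.append(
                {
                    "sample_id": f"{line}{k}",
                    "cell_line": line,
                    "replicate": k,
                    "time_h": float(k),
                    "treatment": "none",
                    "cell_number": float(n),
                    "confluence": 0.3,
                }
            )
            intensities.append(alpha * n + beta)
    meta = pd.DataFrame(rows).set_index("sample_id")
    I = pd.DataFrame(
        [intensities], index=["ion1"], columns=meta.index, dtype=float
    )
    return I, meta, alphas, beta


@pytest.fixture
def two_line_exact():
    return noiseless_two_line_data()
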