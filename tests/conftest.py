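import dataclasses

import numpy as np
import pytest

import specgc as sg

# Canonical coupled fixture: X_n = 0.5 X_{n-1} + 0.4 Y_{n-1} + eps,
# Y_n = 0.7 Y_{n-1} + eta, unit independent innovations. Ground truth:
# information flows Y -> X only.
COUPLED = (0.5, 0.4, 0.7)


@pytest.fixture(scope="session")
def coupled_model():
    return sg.make_unidirectional_var(*COUPLED)


@pytest.fixture(scope="session")
def uncoupled_model():
    return sg.make_unidirectional_var(0.5, 0.0, 0.7)


@pytest.fixture(scope="session")
def coupled_spectrum(coupled_model):
    return sg.var_spectrum(coupled_model, 512)


@pytest.fixture(scope="session")
def coupled_factor_wilson(coupled_spectrum):
    return sg.factorize_wilson(coupled_spectrum)


@pytest.fixture(scope="session")
def coupled_factor_fine(coupled_model):
    """Wilson factor on a 2048 grid (unit fs), for multi-lag GC checks."""
    S = sg.var_spectrum(coupled_model, 2048)
    return dataclasses.replace(sg.factorize_wilson(S), fs=1.0)


def random_stationary_models(n_models: int, seed: int):
    """Random stable bivariate VAR(1) and MA(1) models with random SPD noise."""
    rng = np.random.default_rng(seed)
    models = []
    while len(models) < n_models:
        kind = "var" if len(models) % 2 == 0 else "ma"
        A = rng.uniform(-0.6, 0.6, (2, 2))
        rho = np.max(np.abs(np.linalg.eigvals(A)))
        if rho >= 0.9:
            continue
        R = rng.standard_normal((2, 2)) * 0.3
        cov = R @ R.T + np.eye(2)
        models.append((kind, A, cov))
    return models


def model_spectrum(kind, A, cov, n_freq):
    """Analytic spectrum of a bivariate VAR(1) or MA(1) on the N-grid."""
    if kind == "var":
        m = sg.VARModel(coeffs=A[None], noise_cov=cov, labels=("X", "Y"))
        return sg.var_spectrum(m, n_freq)
    f = np.arange(n_freq) / n_freq
    z = np.exp(-2j * np.pi * f)
    H = np.eye(2)[None] + A[None] * z[:, None, None]
    S = H @ cov[None] @ np.conj(np.swapaxes(H, 1, 2))
    S = 0.5 * (S + np.conj(np.swapaxes(S, 1, 2)))
    return sg.SpectralDensityMatrix(values=S, fs=1.0, labels=("X", "Y"))
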