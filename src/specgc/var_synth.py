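"""Stationary VAR ground truth: simulation and exact Granger-causality oracles.

Real ictal EEG is rarely shareable, so every downstream stage of the
nonparametric GC chain (multitaper spectrum -> spectral factorization ->
prediction-error variances) is validated against vector-autoregressive
processes whose spectrum, autocovariances and multi-step prediction-error
variances are all computable in closed form from the generating coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import linalg as sla

from .containers import MultiTrialSegment
from .gc import GCResult
from .spectral import SpectralDensityMatrix

__all__ = [
    "VARModel",
    "make_unidirectional_var",
    "simulate_var",
    "var_spectrum",
    "lag0_covariance",
    "autocovariance",
    "oracle_multilag_gc",
]


@dataclass
class VARModel:
    """A vector autoregression ``x_n = sum_k coeffs[k-1] x_{n-k} + w_n``.

    ``noise_cov`` is the covariance of the innovation ``w_n``. The model must
    be stationary: the companion matrix must have spectral radius < 1.
    """

    coeffs: np.ndarray  # (p, n, n)
    noise_cov: np.ndarray  # (n, n)
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.coeffs = np.atleast_3d(np.asarray(self.coeffs, dtype=float))
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        n = len(self.labels)
        self.labels = tuple(self.labels)
        if self.coeffs.shape[1:] != (n, n):
            raise ValueError("coefficient matrices must be n x n")
        if self.noise_cov.shape != (n, n):
            raise ValueError("noise_cov must be n x n")
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise ValueError("noise_cov must be symmetric")
        if np.min(np.linalg.eigvalsh(self.noise_cov)) <= 0:
            raise ValueError("noise_cov must be positive definite")
        rho = self.spectral_radius
        if rho >= 1:
            raise ValueError(
                f"non-stationary model: companion spectral radius {rho:.4f} >= 1"
            )

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    def companion(self) -> np.ndarray:
        """The (p*n) x (p*n) companion matrix of the VAR(p)."""
        p, n = self.order, self.n_channels
        C = np.zeros((p * n, p * n))
        C[:n, :] = np.concatenate(list(self.coeffs), axis=1)
        if p > 1:
            C[n:, :-n] = np.eye((p - 1) * n)
        return C

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    # -- serialization (keeps CLI fixtures self-contained) ------------------
    def to_json(self, path: str | Path) -> None:
        obj = {
            "coeffs": self.coeffs.tolist(),
            "noise_cov": self.noise_cov.tolist(),
            "labels": list(self.labels),
        }
        Path(path).write_text(json.dumps(obj, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "VARModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            coeffs=np.asarray(obj["coeffs"], dtype=float),
            noise_cov=np.asarray(obj["noise_cov"], dtype=float),
            labels=tuple(obj["labels"]),
        )


def make_unidirectional_var(
    a: float, c: float, d: float, labels: tuple[str, str] = ("X", "Y")
) -> VARModel:
    """Bivariate VAR(1) with coupling from the second channel into the first.

    ``X_n = a X_{n-1} + c Y_{n-1} + eps_n`` and ``Y_n = d Y_{n-1} + eta_n``
    with independent unit-variance innovations. The triangular structure makes
    the companion eigenvalues exactly ``{a, d}``, so stationarity reduces to
    ``|a| < 1`` and ``|d| < 1``.
    """
    if abs(a) >= 1 or abs(d) >= 1:
        raise ValueError(
            f"non-stationary parameters: need |a|<1 and |d|<1, got a={a}, d={d}"
        )
    coeffs = np.array([[[a, c], [0.0, d]]])
    return VARModel(coeffs=coeffs, noise_cov=np.eye(2), labels=labels)


def simulate_var(
    model: VARModel,
    n_samples: int,
    n_trials: int = 1,
    burn_in: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    fs: float = 1000.0,
    epoch_tag: str = "simulated",
) -> MultiTrialSegment:
    """Draw independent trials from ``model`` with Gaussian innovations.

    Trials use distinct child streams of the seeded generator, so they are
    independent yet jointly reproducible: the same seed gives bit-identical
    output. A burn-in of ``burn_in`` samples is discarded per trial to reach
    approximate stationarity from a zero initial state.
    """
    if n_samples <= model.order:
        raise ValueError("n_samples must exceed the model order")
    p, n = model.order, model.n_channels
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_trials)
    chol = np.linalg.cholesky(model.noise_cov)
    total = burn_in + n_samples
    # innovations come from per-trial child streams (trial independence with
    # joint reproducibility); the recursion itself is vectorized over trials
    w = np.stack(
        [
            np.random.default_rng(child).standard_normal((total, n))
            for child in children
        ],
        axis=1,
    ) @ chol.T  # (total, trials, n)
    coeffs_T = model.coeffs.transpose(0, 2, 1)
    x = np.zeros((total + p, n_trials, n))
    for i in range(total):
        acc = w[i]
        for k in range(p):
            acc = acc + x[p + i - 1 - k] @ coeffs_T[k]
        x[p + i] = acc
    out = x[p + burn_in :].transpose(1, 2, 0)
    return MultiTrialSegment(out, fs=fs, labels=model.labels, epoch_tag=epoch_tag)


def var_spectrum(model: VARModel, n_freq: int) -> SpectralDensityMatrix:
    """Analytic two-sided spectral density matrix of a stationary VAR.

    Computes ``S(f) = A(f)^{-1} Sigma A(f)^{-*}`` with
    ``A(f) = I - sum_k coeffs[k] exp(-i 2 pi f k)`` on the grid
    ``f_j = j/N`` (cycles/sample), normalized so the grid mean of ``S``
    equals the lag-0 covariance.
    """
    if n_freq < 4 * model.order:
        raise ValueError("n_freq must be at least 4x the model order")
    n = model.n_channels
    f = np.arange(n_freq) / n_freq
    A = np.tile(np.eye(n, dtype=complex), (n_freq, 1, 1))
    for k in range(model.order):
        A -= model.coeffs[k][None] * np.exp(-2j * np.pi * f * (k + 1))[:, None, None]
    det = np.linalg.det(A)
    bad = np.abs(det) < 1e-14
    if np.any(bad):
        j = int(np.argmax(bad))
        raise np.linalg.LinAlgError(
            f"VAR transfer polynomial singular at grid frequency index {j}"
        )
    Ainv = np.linalg.inv(A)
    S = Ainv @ model.noise_cov[None] @ np.conj(np.swapaxes(Ainv, 1, 2))
    S = 0.5 * (S + np.conj(np.swapaxes(S, 1, 2)))  # enforce exact Hermitianity
    return SpectralDensityMatrix(values=S, fs=1.0, labels=model.labels)


def lag0_covariance(model: VARModel) -> np.ndarray:
    """Exact lag-0 process covariance via the companion-form Lyapunov equation."""
    p, n = model.order, model.n_channels
    C = model.companion()
    Q = np.zeros((p * n, p * n))
    Q[:n, :n] = model.noise_cov
    G = sla.solve_discrete_lyapunov(C, Q)
    return G[:n, :n]


def autocovariance(model: VARModel, max_lag: int) -> np.ndarray:
    """Exact autocovariances ``R(0..max_lag)``, shape (max_lag+1, n, n).

    ``R(tau) = E[x_{n+tau} x_n^T]`` from the companion recursion
    ``Gamma(tau) = C Gamma(tau-1)`` started at the Lyapunov solution.
    """
    p, n = model.order, model.n_channels
    C = model.companion()
    Q = np.zeros((p * n, p * n))
    Q[:n, :n] = model.noise_cov
    G = sla.solve_discrete_lyapunov(C, Q)
    out = np.empty((max_lag + 1, n, n))
    cur = G
    out[0] = cur[:n, :n]
    for tau in range(1, max_lag + 1):
        cur = C @ cur
        out[tau] = cur[:n, :n]
    return out


def _ma_coefficients(model: VARModel, n_terms: int) -> np.ndarray:
    """Wold moving-average matrices ``B_0..B_{n_terms-1}`` (companion powers)."""
    p, n = model.order, model.n_channels
    C = model.companion()
    B = np.empty((n_terms, n, n))
    cur = np.eye(p * n)
    B[0] = cur[:n, :n]
    for k in range(1, n_terms):
        cur = C @ cur
        B[k] = cur[:n, :n]
    return B


def _univariate_msa_variances(
    r: np.ndarray, L_list: np.ndarray, order: int
) -> np.ndarray:
    """L-step prediction-error variances of a scalar series from its own past.

    Fits an AR(order) by solving the Yule-Walker (Toeplitz) system of the
    exact autocovariances ``r[0..order]`` (Levinson recursion inside
    ``solve_toeplitz``), expands it to its moving-average representation
    ``psi``, and returns ``v * cumsum(psi^2)`` evaluated at each horizon.
    """
    phi = sla.solve_toeplitz(r[:order], r[1 : order + 1])
    v = float(r[0] - phi @ r[1 : order + 1])
    L_max = int(np.max(L_list))
    psi = np.zeros(L_max)
    psi[0] = 1.0
    for j in range(1, L_max):
        m = min(j, order)
        psi[j] = phi[:m] @ psi[j - m : j][::-1]
    cum = np.cumsum(psi**2) * v
    return cum[L_list - 1]


def oracle_multilag_gc(
    model: VARModel,
    L_max: int,
    target: str | None = None,
    include_current: bool = True,
    fs: float = 1000.0,
    base_order: int = 200,
    tol: float = 1e-10,
) -> GCResult:
    """Exact multi-step GC ratios ``I^L`` computed from the generative model.

    The joint L-step prediction-error variance of the target channel uses the
    Wold expansion (companion-matrix powers): ``sum_{k<L} [B_k Sigma B_k^T]``.
    The univariate error variance comes from the exact marginal autocovariance
    of the target pushed through a high-order Yule-Walker/Levinson fit; the
    order is doubled from ``base_order`` until the variances move by less
    than ``tol``, realizing the infimum over all finite predictors as a
    converged limit.

    ``include_current=True`` conditions on samples up to and including time
    ``n`` when predicting ``x_{n+L}`` (predictor lags k >= 0); ``False``
    conditions on the strictly earlier past (k >= 1).
    """
    if model.n_channels != 2:
        raise ValueError("the multi-lag GC oracle is defined for channel pairs only")
    if L_max < 1:
        raise ValueError("L_max must be >= 1")
    labels = model.labels
    target = labels[0] if target is None else target
    t = labels.index(target)
    source = labels[1 - t]
    offset = 0 if include_current else 1
    L = np.arange(1, L_max + 1)
    horizons = L + offset  # number of unpredictable innovation terms

    n_terms = int(np.max(horizons))
    B = _ma_coefficients(model, n_terms)
    contrib = np.einsum("kij,jl,kml->kim", B, model.noise_cov, B)[:, t, t]
    joint = np.cumsum(contrib)[horizons - 1]

    order = base_order
    r = autocovariance(model, order + int(np.max(horizons)))[:, t, t]
    uni = _univariate_msa_variances(r, horizons, order)
    while True:
        order *= 2
        r = autocovariance(model, order + int(np.max(horizons)))[:, t, t]
        uni_new = _univariate_msa_variances(r, horizons, order)
        if np.max(np.abs(uni_new - uni)) < tol:
            uni = uni_new
            break
        uni = uni_new
        if order > 12800:  # ~64x base order: refuse to loop forever
            break

    return GCResult(
        source=source,
        target=target,
        lags=L,
        step_ms=1000.0 / fs,
        I_vals=uni / joint,
        uni_var=uni,
        joint_var=joint,
    )
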