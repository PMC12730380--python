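"""Matrix spectral factorization: S(f) = Psi(f) Psi(f)*.

Two interchangeable backends compute the analytic (causal) outer factor of a
Hermitian positive-definite spectral density matrix on a uniform two-sided
frequency grid:

* ``factorize_wilson`` — the classical Newton-type fixed-point iteration,
  quadratically convergent, used here as the reference backend.
* ``factorize_jla`` — a Janashia–Lagvilava-style two-stage construction for
  channel pairs: a lower-triangular pre-factorization built from nested
  scalar (Kolmogorov/cepstral) factorizations of Schur complements, followed
  by a unitary-valued correction, parameterized by causal polynomials, that
  restores analyticity.

Both return the same mathematical object up to a constant right-unitary
rotation; ``canonicalize`` removes that ambiguity (lower-triangular A_0 with
positive real diagonal), which is how cross-backend agreement is tested.
Fourier convention throughout: Psi(f) = sum_{k>=0} A_k exp(-i 2 pi f k).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import linalg as sla

from .spectral import SpectralDensityMatrix

__all__ = [
    "SpectralFactor",
    "scalar_factor",
    "factorize_wilson",
    "factorize_jla",
    "canonicalize",
    "save_factor",
    "load_factor",
    "FactorizationError",
]


class FactorizationError(RuntimeError):
    """Raised when a factorization cannot be computed to tolerance."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


@dataclass
class SpectralFactor:
    """Analytic outer factor of a spectral density matrix.

    ``coeffs[k]`` holds the Fourier coefficient A_k (n x n complex) of
    Psi(f) = sum_{k>=0} A_k exp(-i 2 pi f k); ``grid_values`` is Psi on the
    same N-point grid as the source spectrum.
    """

    coeffs: np.ndarray  # (n_coeffs, n, n)
    grid_values: np.ndarray  # (N, n, n)
    backend: str
    labels: tuple[str, ...]
    fs: float = 1.0
    canonical: bool = False
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=complex)
        self.grid_values = np.asarray(self.grid_values, dtype=complex)
        self.labels = tuple(self.labels)

    @property
    def A0(self) -> np.ndarray:
        return self.coeffs[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    @property
    def n_freq(self) -> int:
        return self.grid_values.shape[0]

    def reconstruction(self) -> np.ndarray:
        """Psi(f_j) Psi(f_j)* on the grid."""
        return self.grid_values @ np.conj(np.swapaxes(self.grid_values, 1, 2))

    def reconstruction_residual(self, S: SpectralDensityMatrix) -> float:
        """max_j ||S_j - Psi_j Psi_j*||_F / ||S_j||_F."""
        R = self.reconstruction()
        num = np.linalg.norm(S.values - R, axis=(1, 2))
        den = np.linalg.norm(S.values, axis=(1, 2))
        return float(np.max(num / den))

    def analyticity_defect(self) -> float:
        """Fraction of Fourier energy of the grid values at negative indices."""
        c = np.fft.ifft(self.grid_values, axis=0)
        N = c.shape[0]
        total = np.sum(np.abs(c) ** 2)
        neg = np.sum(np.abs(c[N // 2 + 1 :]) ** 2)
        return float(neg / total)

    def szego_defect(self, S: SpectralDensityMatrix) -> float:
        """Relative error of det(A0 A0*) vs exp(mean log det S) (outerness)."""
        lhs = float(np.real(np.linalg.det(self.A0 @ np.conj(self.A0.T))))
        logdet = np.linalg.slogdet(S.values)[1]
        rhs = float(np.exp(np.mean(logdet)))
        return abs(lhs - rhs) / rhs


# ---------------------------------------------------------------------------
# scalar (1x1) factorization: Kolmogorov / cepstral construction
# ---------------------------------------------------------------------------

def scalar_factor(psd: np.ndarray) -> np.ndarray:
    """Causal minimum-phase coefficients of a positive scalar spectrum.

    Given ``psd`` on the N-point two-sided grid, computes the cepstrum
    ``c = IFFT(log psd)``, keeps the causal half (index 0 and N/2 halved),
    exponentiates back, and returns the length-N coefficient sequence of
    ``s+`` with ``|s+(f_j)|^2 = psd_j`` exactly on the grid. For a symmetric
    (real-signal) spectrum the coefficients are real up to rounding and are
    returned as such.
    """
    psd = np.asarray(psd, dtype=float)
    if psd.ndim != 1:
        raise ValueError("psd must be a 1-D array on the frequency grid")
    if np.any(psd <= 0):
        raise ValueError(
            "scalar_factor requires a strictly positive spectrum (log undefined); "
            "floor near-zero bins explicitly, e.g. psd.clip(eps * psd.max()), "
            "if that is acceptable for your data"
        )
    N = psd.size
    c = np.fft.ifft(np.log(psd))
    chat = np.zeros(N, dtype=complex)
    chat[0] = 0.5 * c[0]
    half = N // 2
    chat[1:half] = c[1:half]
    if N % 2 == 0:
        chat[half] = 0.5 * c[half]
    else:
        chat[half] = c[half]
    log_splus = np.fft.fft(chat)
    grid = np.exp(log_splus)
    coeffs = np.fft.ifft(grid)
    if np.max(np.abs(coeffs.imag)) < 1e-9 * np.max(np.abs(coeffs.real)):
        return coeffs.real
    return coeffs


def _scalar_factor_grid(psd: np.ndarray) -> np.ndarray:
    """Grid values s+(f_j) of the scalar minimum-phase factor."""
    coeffs = scalar_factor(psd)
    return np.fft.fft(coeffs.astype(complex))


# ---------------------------------------------------------------------------
# shared checks
# ---------------------------------------------------------------------------

def _check_positive_definite(S: SpectralDensityMatrix, ridge: float) -> np.ndarray:
    """Return S values (plus optional ridge), rejecting near-singular bins.

    Band-passed signals have near-zero power out of band; such spectra are
    rejected rather than silently regularized. Callers who accept the bias
    can pass ``ridge`` > 0 to add ``ridge * I`` explicitly.
    """
    V = S.values.copy()
    if ridge > 0:
        V = V + ridge * np.eye(S.n_channels)[None]
    ev = np.linalg.eigvalsh(V)
    floor = 1e-12 * float(np.max(ev))
    worst = int(np.argmin(ev[:, 0]))
    if ev[worst, 0] <= floor:
        raise FactorizationError(
            f"spectrum numerically singular at grid index {worst} "
            f"(min eigenvalue {ev[worst, 0]:.3e}); if this is out-of-band "
            "leakage, pass a ridge explicitly"
        )
    return V


def _plus_operator(G: np.ndarray) -> np.ndarray:
    """Causal projection along the frequency axis.

    Keeps Fourier coefficients k = 1..N/2-1, halves k = 0 and k = N/2,
    drops the strictly negative indices.
    """
    N = G.shape[0]
    c = np.fft.ifft(G, axis=0)
    c[0] *= 0.5
    half = N // 2
    if N % 2 == 0:
        c[half] *= 0.5
        c[half + 1 :] = 0
    else:
        c[half + 1 :] = 0
    return np.fft.fft(c, axis=0)


def _coeffs_from_grid(grid: np.ndarray) -> np.ndarray:
    """Causal Fourier coefficients A_0..A_{N/2} of grid values."""
    c = np.fft.ifft(grid, axis=0)
    N = c.shape[0]
    return c[: N // 2 + 1]


# ---------------------------------------------------------------------------
# Wilson backend
# ---------------------------------------------------------------------------

def factorize_wilson(
    S: SpectralDensityMatrix,
    tol: float = 1e-9,
    max_iter: int = 100,
    ridge: float = 0.0,
) -> SpectralFactor:
    """Outer spectral factor by Wilson's Newton-type fixed-point iteration.

    Iterates ``Psi <- Psi [Psi^{-1} S Psi^{-*} + I]_+`` (the causal projection
    halves the zero-index coefficient), starting from the constant Cholesky
    factor of the grid-mean spectrum. Stops when the relative change of the
    factor drops below ``tol``. The per-iteration reconstruction residual is
    recorded in ``info["residuals"]``.
    """
    V = _check_positive_definite(S, ridge)
    N, n, _ = V.shape
    S0 = V.mean(axis=0)
    S0 = 0.5 * (S0 + np.conj(S0.T))
    psi = np.tile(np.linalg.cholesky(S0).astype(complex), (N, 1, 1))
    Id = np.eye(n)[None]
    normS = np.linalg.norm(V, axis=(1, 2))
    residuals = []
    converged = False
    for it in range(max_iter):
        psi_inv = np.linalg.inv(psi)
        G = psi_inv @ V @ np.conj(np.swapaxes(psi_inv, 1, 2)) + Id
        psi_new = psi @ _plus_operator(G)
        rec = psi_new @ np.conj(np.swapaxes(psi_new, 1, 2))
        residuals.append(float(np.max(np.linalg.norm(V - rec, axis=(1, 2)) / normS)))
        delta = np.linalg.norm(psi_new - psi) / np.linalg.norm(psi)
        psi = psi_new
        if delta < tol:
            converged = True
            break
    if not converged and residuals[-1] > 1e-7:
        raise FactorizationError(
            f"Wilson iteration did not converge in {max_iter} iterations "
            f"(final residual {residuals[-1]:.3e})",
            residuals=residuals,
        )
    return SpectralFactor(
        coeffs=_coeffs_from_grid(psi),
        grid_values=psi,
        backend="wilson",
        labels=S.labels,
        fs=S.fs,
        info={"residuals": residuals, "iterations": len(residuals)},
    )


# ---------------------------------------------------------------------------
# Janashia–Lagvilava-style backend (channel pairs)
# ---------------------------------------------------------------------------

def _jla_solve(
    phi_hat: np.ndarray, f2_hat: np.ndarray, N: int, degree: int
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the linear annihilation system for the unitary correction.

    Unknowns are the coefficients of the causal polynomials a and b (the
    latter through its conjugates) in the unitary-valued matrix
    ``U = [[a, b], [-conj(b), conj(a)]]``. The equations require the
    strictly negative Fourier coefficients of the corrected second row,
    ``phi*a - f2*conj(b)`` and ``phi*b + f2*conj(a)``, to vanish; at an
    exact solution |a|^2 + |b|^2 is then automatically constant, which is
    what makes a pointwise row normalization exactly unitary. Solved in the
    least-squares sense via SVD; the smallest right singular vector is the
    sought coefficient pair (unique up to the constant-unitary ambiguity of
    the factor itself).
    """
    neg = np.arange(N // 2 + 1, N)  # strictly negative frequencies
    pos = np.arange(1, N // 2)  # strictly positive, from conjugated eqs
    k = np.arange(degree + 1)
    # E1 rows: coeff_m[phi a] - coeff_m[f2 conj(b)] = 0, m negative
    A11 = phi_hat[(neg[:, None] - k[None, :]) % N]
    A12 = -f2_hat[(neg[:, None] + k[None, :]) % N]
    # E2 rows (conjugated): coeff_m[conj(phi) conj(b)] + coeff_m[conj(f2) a] = 0,
    # m positive; conj(g) has coefficient conj(g_hat[-m]) at index m.
    A21 = np.conj(f2_hat[(k[None, :] - pos[:, None]) % N])
    A22 = np.conj(phi_hat[(-pos[:, None] - k[None, :]) % N])
    A = np.block([[A11, A12], [A21, A22]])
    _, s, Vh = np.linalg.svd(A, full_matrices=False)
    z = Vh[-1].conj()
    a = z[: degree + 1]
    b_conj = z[degree + 1 :]
    return a, b_conj


def factorize_jla(
    S: SpectralDensityMatrix,
    poly_order: int | None = None,
    tol: float = 1e-6,
    analyt_tol: float = 1e-3,
    ridge: float = 0.0,
) -> SpectralFactor:
    """Outer spectral factor by the two-stage triangular-plus-unitary route.

    Stage one builds a pointwise lower-triangular factor from scalar
    factorizations: ``M11 = s+(S11)``, ``M21 = S21 / conj(M11)``,
    ``M22 = s+(det S / S11)`` (the Schur complement), so ``S = M M*`` holds
    on the grid but ``M21`` is generally non-causal. Stage two right-
    multiplies by a unitary-valued ``U(f)`` with det 1 — rows built from
    causal polynomials of degree ``poly_order`` — chosen to annihilate the
    negative-index Fourier coefficients of the product. The polynomial
    degree starts at N/8 and doubles until the analyticity defect of the
    result is below ``tol**2`` (energy fraction) or N/2 is reached.

    Because the unitary correction is exactly unitary pointwise, the
    reconstruction ``Psi Psi* = S`` is exact to rounding; the finite
    polynomial degree shows up only in the (measured) analyticity defect.
    Supports one- and two-channel spectra, the pairwise setting directed
    connectivity analysis works in.
    """
    V = _check_positive_definite(S, ridge)
    N, n, _ = V.shape
    if n == 1:
        coeffs = scalar_factor(V[:, 0, 0].real).astype(complex)
        grid = np.fft.fft(coeffs)
        return SpectralFactor(
            coeffs=coeffs[: N // 2 + 1, None, None],
            grid_values=grid[:, None, None],
            backend="jla",
            labels=S.labels,
            fs=S.fs,
            info={"poly_order": 0},
        )
    if n != 2:
        raise NotImplementedError(
            "the triangular-plus-unitary backend factorizes channel pairs; "
            "use factorize_wilson for more than 2 channels"
        )

    s11 = V[:, 0, 0].real
    detS = np.real(V[:, 0, 0] * V[:, 1, 1] - V[:, 0, 1] * V[:, 1, 0])
    f1 = _scalar_factor_grid(s11)
    f2 = _scalar_factor_grid(detS / s11)
    phi = V[:, 1, 0] / np.conj(f1)

    phi_hat = np.fft.ifft(phi)
    f2_hat = np.fft.ifft(f2)

    # keep the annihilation system overdetermined: 2(degree+1) unknowns
    # against ~N-2 equations
    max_degree = 3 * N // 8
    degree = poly_order if poly_order is not None else max(4, N // 8)
    degree = min(degree, max_degree)
    attempts = []
    best = None
    while True:
        a_c, b_conj_c = _jla_solve(phi_hat, f2_hat, N, degree)
        pad_a = np.zeros(N, dtype=complex)
        pad_a[: degree + 1] = a_c
        a = np.fft.fft(pad_a)
        pad_b = np.zeros(N, dtype=complex)
        pad_b[: degree + 1] = b_conj_c
        # conj(b)(f) = sum_k conj(b_k) e^{+i2pifk}; undo the conjugation on the grid
        b = np.conj(N * np.fft.ifft(pad_b))
        g = np.abs(a) ** 2 + np.abs(b) ** 2
        if np.min(g) <= 0:
            raise FactorizationError("degenerate unitary correction (zero norm row)")
        scale = np.sqrt(g)
        a_n, b_n = a / scale, b / scale
        psi = np.empty((N, 2, 2), dtype=complex)
        psi[:, 0, 0] = f1 * a_n
        psi[:, 0, 1] = f1 * b_n
        psi[:, 1, 0] = phi * a_n - f2 * np.conj(b_n)
        psi[:, 1, 1] = phi * b_n + f2 * np.conj(a_n)
        factor = SpectralFactor(
            coeffs=_coeffs_from_grid(psi),
            grid_values=psi,
            backend="jla",
            labels=S.labels,
            fs=S.fs,
            info={"poly_order": degree},
        )
        defect = factor.analyticity_defect()
        attempts.append((degree, defect))
        if best is None or defect < best[1]:
            best = (factor, defect)
        # smooth spectra converge to ~machine precision; estimated (rough)
        # spectra bottom out at a defect set by their own irregularity, so
        # stop once the defect is tiny, stops improving, or the degree cap
        # is reached
        if defect < tol**2 or poly_order is not None:
            break
        if degree >= max_degree or (len(attempts) > 1 and defect > 0.5 * attempts[-2][1]):
            break
        degree = min(2 * degree, max_degree)
    factor, defect = best
    if defect > analyt_tol:
        raise FactorizationError(
            f"analyticity defect {defect:.3e} above analyt_tol {analyt_tol:g} at "
            f"maximum polynomial degree {max_degree}",
            residuals=attempts,
        )
    factor.info["attempts"] = attempts
    return factor


# ---------------------------------------------------------------------------
# canonical representative
# ---------------------------------------------------------------------------

def canonicalize(factor: SpectralFactor) -> SpectralFactor:
    """Rotate the factor to the unique representative with lower-triangular
    A_0 having a strictly positive real diagonal.

    The outer factor is unique only up to a constant right-unitary; GC is
    invariant to that rotation, but cross-backend comparison needs a fixed
    representative. Uses the LQ decomposition of A_0; Sigma = A_0 A_0* is
    unchanged to machine precision.
    """
    A0 = factor.A0
    if np.linalg.cond(A0) > 1e12:
        raise FactorizationError(
            "singular A0: degenerate (rank-deficient) spectrum cannot be "
            "canonicalized"
        )
    # LQ via QR of the conjugate transpose: A0^H = Q~ R~  =>  A0 = R~^H Q~^H
    Qt, Rt = np.linalg.qr(np.conj(A0.T))
    L, Q = np.conj(Rt.T), np.conj(Qt.T)
    d = np.diagonal(L)
    phase = np.where(np.abs(d) > 0, d / np.abs(d), 1.0)
    # A0 @ rot = L @ diag(conj(phase)): lower-triangular, positive real diagonal
    rot = np.conj(Q.T) @ np.diag(np.conj(phase))
    return replace(
        factor,
        coeffs=factor.coeffs @ rot,
        grid_values=factor.grid_values @ rot,
        canonical=True,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_factor(path: str | Path, factor: SpectralFactor) -> None:
    np.savez(
        path,
        coeffs=factor.coeffs,
        grid_values=factor.grid_values,
        backend=factor.backend,
        labels=np.asarray(factor.labels),
        fs=factor.fs,
        canonical=factor.canonical,
    )


def load_factor(path: str | Path) -> SpectralFactor:
    with np.load(path, allow_pickle=False) as z:
        return SpectralFactor(
            coeffs=z["coeffs"],
            grid_values=z["grid_values"],
            backend=str(z["backend"]),
            labels=tuple(str(l) for l in z["labels"]),
            fs=float(z["fs"]),
            canonical=bool(z["canonical"]),
        )
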