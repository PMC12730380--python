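"""Granger-causality measures from a spectral factor.

The factor supplies the moving-average (Wold) representation of the pair:
``Sigma = A0 A0*`` is the joint innovation covariance and
``H(f) = Psi(f) A0^{-1}`` the transfer function, whose Fourier coefficients
``B_k`` propagate innovations forward in time. The L-step-ahead joint
prediction-error variance of the target channel is then a partial sum of
``[B_k Sigma B_k*]`` terms, while the univariate error variance comes from
the scalar minimum-phase factorization of the target's own spectrum. Their
ratio is the causality measure: how much the source's past shortens the
target's prediction error at each millisecond-scale horizon.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .specfac import SpectralFactor, scalar_factor

__all__ = [
    "TransferNoise",
    "GCResult",
    "transfer_noise",
    "multilag_gc",
    "onestep_gc",
    "dominant_direction",
    "DirectionCall",
]


@dataclass
class TransferNoise:
    """Transfer function H(f) and innovation covariance Sigma of a factor."""

    H: np.ndarray  # (N, n, n) complex, zeroth Fourier coefficient = I
    Sigma: np.ndarray  # (n, n) Hermitian positive definite
    labels: tuple[str, ...]


@dataclass
class GCResult:
    """Directed GC ratios over prediction horizons L = 1..L_max.

    ``I_vals[L-1] = uni_var[L-1] / joint_var[L-1]`` is the ratio of the
    target's univariate to joint L-step prediction-error variance; values
    above 1 mean the source's past improves prediction of the target.
    """

    source: str
    target: str
    lags: np.ndarray
    step_ms: float
    I_vals: np.ndarray
    uni_var: np.ndarray
    joint_var: np.ndarray

    @property
    def log_vals(self) -> np.ndarray:
        """ln of the ratio, for users expecting Geweke's log form."""
        return np.log(self.I_vals)

    @property
    def lag_ms(self) -> np.ndarray:
        return self.lags * self.step_ms

    @property
    def pair(self) -> str:
        return f"{self.source}->{self.target}"

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: pair, source, target, L, lag_ms, I, lnI, variances."""
        return pd.DataFrame(
            {
                "pair": self.pair,
                "source": self.source,
                "target": self.target,
                "L": self.lags,
                "lag_ms": self.lag_ms,
                "I": self.I_vals,
                "lnI": self.log_vals,
                "uni_var": self.uni_var,
                "joint_var": self.joint_var,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def transfer_noise(factor: SpectralFactor) -> TransferNoise:
    """Split a spectral factor into transfer function and noise covariance.

    ``Sigma = A0 A0*`` and ``H(f) = Psi(f) A0^{-1}``; both are invariant
    under the constant right-unitary ambiguity of the factor.
    """
    A0 = factor.A0
    if np.linalg.cond(A0) > 1e12:
        raise np.linalg.LinAlgError("singular A0: cannot form transfer function")
    A0_inv = np.linalg.inv(A0)
    Sigma = A0 @ np.conj(A0.T)
    H = factor.grid_values @ A0_inv
    return TransferNoise(H=H, Sigma=0.5 * (Sigma + np.conj(Sigma.T)), labels=factor.labels)


def multilag_gc(
    factor: SpectralFactor,
    source: str,
    target: str,
    L_max: int = 25,
    include_current: bool = True,
) -> GCResult:
    """Multi-step-ahead GC ratios I^L for L = 1..L_max from a spectral factor.

    ``joint_var[L]`` sums the first L terms ``[B_k Sigma B_k*]_tt`` of the
    joint Wold expansion; ``uni_var[L]`` sums squared coefficients of the
    scalar minimum-phase factor of the target's own spectral density. With
    ``include_current=True`` the predictors condition on samples up to and
    including time n (lags k >= 0 in the prediction representations);
    ``False`` conditions on the strictly earlier past.
    """
    if L_max < 1:
        raise ValueError("L_max must be >= 1")
    labels = factor.labels
    for lab in (source, target):
        if lab not in labels:
            raise KeyError(f"channel {lab!r} not in factor labels {list(labels)}")
    if source == target:
        raise ValueError("source and target must differ")
    if len(labels) != 2:
        raise ValueError("multilag_gc is defined for factors of channel pairs")
    N = factor.n_freq
    offset = 0 if include_current else 1
    if L_max + offset > N // 2:
        raise ValueError(
            f"L_max={L_max} exceeds the coefficient support N/2={N // 2} of the grid"
        )
    t = labels.index(target)
    tn = transfer_noise(factor)
    B = np.fft.ifft(tn.H, axis=0)[: L_max + offset]
    contrib = np.real(np.einsum("kij,jl,kml->kim", B, tn.Sigma, np.conj(B)))[:, t, t]
    joint_full = np.cumsum(contrib)

    S_tt = np.sum(np.abs(factor.grid_values[:, t, :]) ** 2, axis=1)
    c = np.abs(scalar_factor(S_tt)[: L_max + offset]) ** 2
    uni_full = np.cumsum(c)

    sl = slice(offset, L_max + offset)
    lags = np.arange(1, L_max + 1)
    uni = uni_full[sl]
    joint = joint_full[sl]
    return GCResult(
        source=source,
        target=target,
        lags=lags,
        step_ms=1000.0 / factor.fs,
        I_vals=uni / joint,
        uni_var=uni,
        joint_var=joint,
    )


def onestep_gc(
    factor: SpectralFactor, source: str, target: str, include_current: bool = True
) -> float:
    """Classical one-step-ahead GC ratio (the L=1 point of the multi-lag curve)."""
    res = multilag_gc(factor, source, target, L_max=1, include_current=include_current)
    return float(res.I_vals[0])


@dataclass
class DirectionCall:
    """Outcome of comparing the two directions of a pair at one horizon."""

    dominant: str  # "source->target" of the larger-I direction
    reverse: str
    L: int
    values: dict[str, float]  # direction -> I^L
    tie: bool


def dominant_direction(gc_ab: GCResult, gc_ba: GCResult, L: int) -> DirectionCall:
    """Label the direction with the larger I^L as dominant, the other reverse.

    Ties are broken toward the lexicographically smaller source label and
    flagged. Both results must describe the same channel pair on the same
    lag grid.
    """
    if {gc_ab.source, gc_ab.target} != {gc_ba.source, gc_ba.target}:
        raise ValueError("results describe different channel pairs")
    if gc_ab.source == gc_ba.source:
        raise ValueError("both results have the same direction")
    if not np.array_equal(gc_ab.lags, gc_ba.lags):
        raise ValueError("results have different lag grids")
    if L not in gc_ab.lags:
        raise ValueError(f"L={L} not on the computed lag grid")
    i = int(np.where(gc_ab.lags == L)[0][0])
    va, vb = float(gc_ab.I_vals[i]), float(gc_ba.I_vals[i])
    values = {gc_ab.pair: va, gc_ba.pair: vb}
    tie = va == vb
    if va > vb or (tie and gc_ab.source < gc_ba.source):
        dom, rev = gc_ab, gc_ba
    else:
        dom, rev = gc_ba, gc_ab
    return DirectionCall(dominant=dom.pair, reverse=rev.pair, L=L, values=values, tie=tie)
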