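"""Multitaper cross-power spectral density estimation.

Spectra use the discrete-time two-sided convention on the grid
``f_j = j/N`` (cycles/sample): ``S(f) = sum_tau R(tau) exp(-i 2 pi f tau)``,
so the grid mean ``(1/N) sum_j S(f_j)`` recovers the lag-0 covariance and the
zeroth Fourier coefficient of the spectral factor is directly the innovation
square root. A physical-Hz axis is attached only for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.signal import windows

from .containers import MultiTrialSegment

__all__ = [
    "SpectralDensityMatrix",
    "multitaper_csd",
    "tapered_spectra",
    "csd_from_tapered",
    "save_spectrum",
    "load_spectrum",
]


@dataclass
class SpectralDensityMatrix:
    """Hermitian cross-spectral density on an N-point two-sided grid.

    ``values`` is complex, indexed ``[freq, row, col]``. ``fs`` is metadata
    for axis labeling only; all internal frequencies are cycles/sample.
    ``dof`` is the effective degrees of freedom (2 x tapers x trials) of the
    estimate, zero for analytic spectra.
    """

    values: np.ndarray
    fs: float
    labels: tuple[str, ...]
    n_tapers: int = 0
    dof: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 3 or self.values.shape[1] != self.values.shape[2]:
            raise ValueError("values must be [freq, n, n]")
        self.labels = tuple(self.labels)
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("labels must match matrix dimension")

    @property
    def n_freq(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def freqs(self) -> np.ndarray:
        """Grid frequencies in cycles/sample, ``f_j = j/N``."""
        return np.arange(self.n_freq) / self.n_freq

    @property
    def freqs_hz(self) -> np.ndarray:
        return self.freqs * self.fs

    def hermitian_defect(self) -> float:
        return float(
            np.max(np.abs(self.values - np.conj(np.swapaxes(self.values, 1, 2))))
        )

    def min_eigenvalue(self) -> float:
        return float(np.min(np.linalg.eigvalsh(self.values)))

    def grid_mean(self) -> np.ndarray:
        """(1/N) sum_j S(f_j); equals the lag-0 covariance for a true spectrum."""
        return self.values.mean(axis=0)

    def select(self, labels) -> "SpectralDensityMatrix":
        idx = [self.labels.index(l) for l in labels]
        v = self.values[:, idx, :][:, :, idx]
        return replace(self, values=v, labels=tuple(labels))


def _fft_grid_size(n_samples: int, n_freq: int | None) -> int:
    """Next power of two >= max(requested grid, trial length)."""
    target = max(n_samples, n_freq or 0)
    return 1 << int(np.ceil(np.log2(target)))


def tapered_spectra(
    segment: MultiTrialSegment,
    nw: float = 4.0,
    n_tapers: int = 7,
    n_freq: int | None = None,
) -> np.ndarray:
    """DPSS-tapered eigenspectra, shape ``(trials, channels, tapers, N)``.

    The building block of :func:`multitaper_csd`, exposed separately so
    surrogate resampling can re-pair or re-FFT single channels without
    redoing all transforms. Tapers are unit-energy, so eigenspectra are
    unbiased for the two-sided discrete-time spectrum. The per-trial,
    per-channel mean is removed before tapering.
    """
    if n_tapers > 2 * nw - 1:
        raise ValueError(
            f"inadmissible taper count: need n_tapers <= 2*NW-1 = {2 * nw - 1:g}, "
            f"got {n_tapers}"
        )
    if segment.n_samples < 8:
        raise ValueError("multitaper estimation needs at least 8 samples per trial")
    N = _fft_grid_size(segment.n_samples, n_freq)
    tapers = windows.dpss(segment.n_samples, nw, Kmax=n_tapers)  # (K, samples)
    x = segment.data - segment.data.mean(axis=2, keepdims=True)
    tapered = x[:, :, None, :] * tapers[None, None, :, :]
    return np.fft.fft(tapered, n=N, axis=-1)


def csd_from_tapered(
    X: np.ndarray,
    segment_labels,
    fs: float,
) -> SpectralDensityMatrix:
    """Average tapered eigenspectra into one cross-spectral density matrix."""
    n_trials, _, n_tapers, _ = X.shape
    S = np.einsum("tckf,tdkf->fcd", X, np.conj(X)) / (n_trials * n_tapers)
    S = 0.5 * (S + np.conj(np.swapaxes(S, 1, 2)))
    return SpectralDensityMatrix(
        values=S,
        fs=fs,
        labels=tuple(segment_labels),
        n_tapers=n_tapers,
        dof=2.0 * n_tapers * n_trials,
    )


def multitaper_csd(
    segment: MultiTrialSegment,
    nw: float = 4.0,
    n_tapers: int = 7,
    n_freq: int | None = None,
) -> SpectralDensityMatrix:
    """Multitaper cross-spectral density matrix, averaged over tapers and trials.

    Parameters
    ----------
    segment
        Input trials; the mean is removed per trial and channel.
    nw
        Time-half-bandwidth product of the DPSS taper family.
    n_tapers
        Number of tapers K; must satisfy ``K <= 2*NW - 1``.
    n_freq
        Requested two-sided grid size; the FFT length is the next power of
        two >= max(n_freq, trial length) and is recorded in the result.
    """
    X = tapered_spectra(segment, nw=nw, n_tapers=n_tapers, n_freq=n_freq)
    return csd_from_tapered(X, segment.labels, segment.fs)


def save_spectrum(path: str | Path, S: SpectralDensityMatrix) -> None:
    """Write a spectrum with axis metadata to an NPZ archive."""
    np.savez(
        path,
        values=S.values,
        fs=S.fs,
        labels=np.asarray(S.labels),
        n_tapers=S.n_tapers,
        dof=S.dof,
        freqs_cycles_per_sample=S.freqs,
        freqs_hz=S.freqs_hz,
    )


def load_spectrum(path: str | Path) -> SpectralDensityMatrix:
    with np.load(path, allow_pickle=False) as z:
        return SpectralDensityMatrix(
            values=z["values"],
            fs=float(z["fs"]),
            labels=tuple(str(l) for l in z["labels"]),
            n_tapers=int(z["n_tapers"]),
            dof=float(z["dof"]),
        )
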