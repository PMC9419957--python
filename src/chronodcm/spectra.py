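"""Cross-spectral density estimation and the inversion feature mapping.

The default data-feature estimator is a least-squares multivariate
autoregression (MAR) whose implied spectrum is evaluated on the analysis
grid; an averaged windowed periodogram (Welch) estimator serves as an
independent oracle.  Both return two-sided spectral densities per Hz, so a
unit-variance white series has a flat spectrum of height TR.

``feature_vector`` flattens a Hermitian cross-spectrum into the real vector
the variational inversion consumes: first the real parts of the upper
triangle (diagonal included) across frequencies, then the imaginary parts of
the strict upper triangle.  The mapping is invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .forward import CrossSpectrum, FrequencyGrid

__all__ = [
    "MarModel",
    "fit_mar",
    "mar_csd",
    "welch_csd",
    "feature_vector",
    "feature_to_csd",
    "feature_layout",
]

DEFAULT_MAR_ORDER = 8


@dataclass
class MarModel:
    """Multivariate autoregression ``x_t = sum_k coeffs[k] x_{t-k} + e_t``."""

    order: int
    coeffs: np.ndarray  # (order, n, n)
    noise_cov: np.ndarray  # (n, n), symmetric PSD

    @property
    def n_rois(self) -> int:
        return self.noise_cov.shape[0]


def fit_mar(series: np.ndarray, order: int = DEFAULT_MAR_ORDER) -> MarModel:
    """Least-squares MAR fit of the stated order to a volumes x ROI series."""
    y = np.asarray(series, dtype=float)
    if y.ndim != 2:
        raise ValueError("series must be volumes x ROIs")
    t, n = y.shape
    if t <= order * n + 1:
        raise ValueError("series too short for the requested MAR order")
    # lagged design: predict y[t] from y[t-1..t-order]
    X = np.hstack([y[order - k - 1 : t - k - 1] for k in range(order)])
    Y = y[order:]
    sol, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError(
            "ill-conditioned MAR regression; try a lower order or a longer series"
        )
    resid = Y - X @ sol
    noise_cov = resid.T @ resid / resid.shape[0]
    coeffs = sol.T.reshape(n, order, n).transpose(1, 0, 2)
    return MarModel(order=order, coeffs=coeffs, noise_cov=noise_cov)


def mar_csd(model: MarModel, grid: FrequencyGrid, tr: float) -> CrossSpectrum:
    """Spectrum implied by a MAR model: ``TR * A(f)^-1 Sigma A(f)^-*``."""
    n = model.n_rois
    f = grid.freqs
    A = np.broadcast_to(np.eye(n, dtype=complex), (f.size, n, n)).copy()
    for k in range(model.order):
        phase = np.exp(-2j * np.pi * f * (k + 1) * tr)
        A -= phase[:, None, None] * model.coeffs[k]
    Ainv = np.linalg.inv(A)
    S = tr * Ainv @ model.noise_cov @ np.conj(np.transpose(Ainv, (0, 2, 1)))
    S = 0.5 * (S + np.conj(np.transpose(S, (0, 2, 1))))
    return CrossSpectrum(grid=grid, S=S)


def welch_csd(
    series: np.ndarray,
    grid: FrequencyGrid,
    tr: float,
    window_length: int | None = None,
    overlap: float = 0.5,
) -> CrossSpectrum:
    """Averaged windowed periodogram cross-spectra interpolated to the grid.

    Hann window, 50% overlap by default; the default window length is
    volumes/8 rounded down to a power of two.  Oracle estimator only.
    """
    y = np.asarray(series, dtype=float)
    t, n = y.shape
    if window_length is None:
        window_length = 2 ** int(np.log2(max(t // 8, 8)))
    if window_length > t:
        raise ValueError("window length exceeds the number of volumes")
    fs = 1.0 / tr
    noverlap = int(window_length * overlap)
    kwargs = dict(
        fs=fs,
        window="hann",
        nperseg=window_length,
        noverlap=noverlap,
        detrend="constant",
        return_onesided=False,
        scaling="density",
    )
    S = None
    for i in range(n):
        for j in range(i, n):
            freqs, sij = sp_signal.csd(y[:, i], y[:, j], **kwargs)
            if S is None:
                pos = freqs > 0
                fpos = freqs[pos]
                order = np.argsort(fpos)
                fpos = fpos[order]
                if grid.freqs[0] < fpos.min() - 1e-12 or grid.freqs[-1] > fpos.max() + 1e-12:
                    raise ValueError("analysis grid extends outside the resolvable Welch band")
                S = np.empty((len(grid), n, n), dtype=complex)
            sij = sij[pos][order]
            interp = np.interp(grid.freqs, fpos, sij.real) + 1j * np.interp(
                grid.freqs, fpos, sij.imag
            )
            S[:, i, j] = interp
            S[:, j, i] = np.conj(interp)
    return CrossSpectrum(grid=grid, S=S)


def feature_layout(n_rois: int, n_freq: int):
    """Index bookkeeping for the feature vector.

    Returns ``(iu_real, iu_imag, n_real, n_imag)`` where ``iu_real`` indexes
    the upper triangle with diagonal and ``iu_imag`` the strict upper
    triangle.  Total feature length is ``n_freq * n_rois**2``.
    """
    iu_real = np.triu_indices(n_rois, k=0)
    iu_imag = np.triu_indices(n_rois, k=1)
    return iu_real, iu_imag, n_freq * iu_real[0].size, n_freq * iu_imag[0].size


def feature_vector(S: CrossSpectrum | np.ndarray, n_rois: int | None = None) -> np.ndarray:
    """Flatten Hermitian spectra to reals: upper-triangle real parts then
    strict-upper-triangle imaginary parts, frequency-major within each block."""
    arr = S.S if isinstance(S, CrossSpectrum) else np.asarray(S)
    nf, n = arr.shape[0], arr.shape[1]
    iu_real, iu_imag, _, _ = feature_layout(n, nf)
    re = arr[:, iu_real[0], iu_real[1]].real.ravel()
    im = arr[:, iu_imag[0], iu_imag[1]].imag.ravel()
    return np.concatenate([re, im])


def feature_to_csd(vec: np.ndarray, grid: FrequencyGrid, n_rois: int) -> CrossSpectrum:
    """Inverse of :func:`feature_vector`."""
    nf = len(grid)
    iu_real, iu_imag, n_re, n_im = feature_layout(n_rois, nf)
    if vec.size != n_re + n_im:
        raise ValueError("feature vector length does not match grid/ROI count")
    re = vec[:n_re].reshape(nf, -1)
    im = vec[n_re:].reshape(nf, -1)
    S = np.zeros((nf, n_rois, n_rois), dtype=complex)
    S[:, iu_real[0], iu_real[1]] = re
    S[:, iu_imag[0], iu_imag[1]] += 1j * im
    # mirror to the lower triangle
    low = np.tril_indices(n_rois, k=-1)
    S[:, low[0], low[1]] = np.conj(S[:, low[1], low[0]])
    return CrossSpectrum(grid=grid, S=S)
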