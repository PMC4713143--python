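"""Spectral power and dwPLI connectivity.

Band power comes from Welch periodograms on a 0.25 Hz grid; connectivity
from the debiased weighted phase lag index (dwPLI) computed over epochs at
each time-frequency bin of a short-time Fourier decomposition, then averaged
over time.  The dwPLI is built from imaginary cross-spectra only, so
zero-lag (volume-conducted) coupling cancels, and the debiasing removes the
positive sample-size bias of the weighted phase lag index.

For epoch j with imaginary cross-spectrum I_j at a fixed channel pair and
time-frequency bin,

    dwPLI = [ (sum_j I_j)^2 - sum_j I_j^2 ] / [ (sum_j |I_j|)^2 - sum_j I_j^2 ]

with the convention 0 when the denominator vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window, welch

from .containers import EpochedData

#: Canonical band edges (Hz).  Alpha and beta deliberately overlap.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 15.0),
    "beta": (12.0, 25.0),
    "gamma": (25.0, 40.0),
}

#: Slow-oscillation band used only for phase-amplitude coupling.
SLOW_BAND: tuple[float, float] = (0.5, 1.5)


@dataclass
class PowerSpectrum:
    freqs: np.ndarray  # Hz
    power: np.ndarray  # (channels, freqs), uV^2/Hz
    band_relative: dict[str, np.ndarray]  # band -> per-channel percent
    labels: list[str] = field(default_factory=list)


@dataclass
class TFDecomposition:
    """Short-time Fourier coefficients, epochs x channels x freqs x times."""

    coeffs: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    fs: float
    window: str
    labels: list[str] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]


@dataclass
class ConnectivityResult:
    """Per-frequency (time-averaged) dwPLI matrices."""

    dwpli: np.ndarray  # (channels, channels, freqs)
    freqs: np.ndarray
    labels: list[str] = field(default_factory=list)


def welch_power(epochs: EpochedData, bin: float = 0.25) -> PowerSpectrum:
    """Averaged-periodogram power spectrum on a ``bin``-Hz grid.

    Hamming segments of 1/bin seconds with 50% overlap, averaged over
    segments and epochs; band-relative power is each channel's percentage
    contribution of every canonical band to the total over the five bands.
    """
    nperseg = int(round(epochs.fs / bin))
    if nperseg > epochs.n_samples:
        raise ValueError("bin finer than 1/epoch_length")
    flat = epochs.data.transpose(1, 0, 2)  # (channels, epochs, samples)
    freqs, psd = welch(
        flat,
        fs=epochs.fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        axis=-1,
    )
    power = psd.mean(axis=1)  # average over epochs

    band_sums = {}
    for name, (lo, hi) in BANDS.items():
        mask = (freqs >= lo) & (freqs <= hi)
        band_sums[name] = power[:, mask].sum(axis=1)
    total = np.sum(list(band_sums.values()), axis=0)
    band_relative = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for name, s in band_sums.items():
            rel = np.where(total > 0, 100.0 * s / np.where(total > 0, total, 1.0), np.nan)
            band_relative[name] = rel
    return PowerSpectrum(
        freqs=freqs, power=power, band_relative=band_relative,
        labels=list(epochs.labels),
    )


def tf_decompose(
    epochs: EpochedData,
    freq_step: float = 0.49,
    time_step: float = 0.04,
    fmax: float | None = 45.0,
    window: str = "hann",
) -> TFDecomposition:
    """Short-time Fourier decomposition.

    Window length is ``round(fs / freq_step)`` samples and the hop is
    ``round(fs * time_step)`` samples; segments are demeaned before
    windowing and a one-sided spectrum is kept (cropped at ``fmax`` to bound
    memory).
    """
    fs = epochs.fs
    win_len = int(round(fs / freq_step))
    hop = int(round(fs * time_step))
    if win_len < 2 or hop < 1:
        raise ValueError("freq_step/time_step incompatible with sampling rate")
    n = epochs.n_samples
    if win_len > n:
        raise ValueError("epoch shorter than the analysis window")
    starts = np.arange(0, n - win_len + 1, hop)
    freqs = np.fft.rfftfreq(win_len, 1.0 / fs)
    keep = slice(None) if fmax is None else slice(0, int(np.searchsorted(freqs, fmax, "right")))
    freqs = freqs[keep]
    taper = get_window(window, win_len)

    n_e, n_c = epochs.n_epochs, epochs.n_channels
    coeffs = np.empty((n_e, n_c, len(freqs), len(starts)), dtype=np.complex64)
    for e in range(n_e):
        for c in range(n_c):
            segs = np.stack(
                [epochs.data[e, c, s : s + win_len] for s in starts]
            )
            segs = (segs - segs.mean(axis=1, keepdims=True)) * taper
            coeffs[e, c] = np.fft.rfft(segs, axis=1)[:, keep].T
    times = (starts + win_len / 2) / fs
    return TFDecomposition(
        coeffs=coeffs, freqs=freqs, times=times, fs=fs, window=window,
        labels=list(epochs.labels),
    )


def dwpli_from_imag(imag: np.ndarray, axis: int = 0) -> np.ndarray:
    """Debiased WPLI from imaginary cross-spectra along ``axis`` (epochs)."""
    s1 = imag.sum(axis=axis)
    s2 = (imag**2).sum(axis=axis)
    s1a = np.abs(imag).sum(axis=axis)
    num = s1**2 - s2
    den = s1a**2 - s2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den != 0, num / np.where(den != 0, den, 1.0), 0.0)
    return out


def dwpli(tf: TFDecomposition) -> ConnectivityResult:
    """Time-averaged dwPLI for every channel pair and frequency.

    The expectation runs over epochs at each time-frequency bin; the
    per-bin dwPLI is then averaged across time bins.
    """
    if tf.n_epochs < 2:
        raise ValueError("dwPLI undefined for a single epoch")
    n_e, n_c, n_f, n_t = tf.coeffs.shape
    # accumulate in the input's own precision: complex64 coefficients get a
    # float32 path (memory-bandwidth bound at realistic sizes), complex128
    # keeps full double precision for oracle-grade comparisons
    single = tf.coeffs.dtype == np.complex64
    real = np.float32 if single else np.float64
    eps = 1e-6 if single else 1e-12
    s1 = np.zeros((n_c, n_c, n_f, n_t), dtype=real)
    s2 = np.zeros_like(s1)
    s1a = np.zeros_like(s1)
    for e in range(n_e):
        x = tf.coeffs[e]
        for i in range(n_c - 1):
            cross = x[i][None] * np.conj(x[i + 1 :])
            im = np.imag(cross)
            # imaginary parts at rounding level of |cross| are numerical
            # noise (proportional signals); the scale-free estimator would
            # otherwise amplify them
            im[np.abs(im) <= eps * np.abs(cross)] = 0.0
            s1[i, i + 1 :] += im
            s2[i, i + 1 :] += im * im
            s1a[i, i + 1 :] += np.abs(im)
    s1 = s1.astype(np.float64)
    s2 = s2.astype(np.float64)
    s1a = s1a.astype(np.float64)
    num = s1**2 - s2
    den = s1a**2 - s2
    with np.errstate(invalid="ignore", divide="ignore"):
        val = np.where(den != 0, num / np.where(den != 0, den, 1.0), 0.0)
    per_freq = val.mean(axis=-1)  # average over time bins
    full = per_freq + per_freq.transpose(1, 0, 2)
    return ConnectivityResult(dwpli=full, freqs=tf.freqs, labels=list(tf.labels))


def band_connectivity(
    conn: ConnectivityResult, band: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair dwPLI at the in-band peak frequency.

    For each channel pair the in-band frequency bin with the largest
    time-averaged dwPLI is selected (ties toward the lower frequency);
    returns the symmetric band matrix and the per-pair peak frequencies.
    """
    lo, hi = band
    mask = (conn.freqs >= lo) & (conn.freqs <= hi)
    if not mask.any():
        raise ValueError("no frequency bins inside the requested band")
    sub = conn.dwpli[:, :, mask]
    idx = sub.argmax(axis=-1)
    values = np.take_along_axis(sub, idx[..., None], axis=-1)[..., 0]
    peak = conn.freqs[mask][idx]
    np.fill_diagonal(values, 0.0)
    np.fill_diagonal(peak, 0.0)
    return values, peak


def median_connectivity(matrix: np.ndarray) -> float:
    """Median over the strict upper triangle of a symmetric matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    iu = np.triu_indices(m.shape[0], k=1)
    return float(np.median(m[iu]))
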