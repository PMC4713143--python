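"""Preprocessing chain: filter -> epoch -> baseline -> reject -> interpolate
-> average reference.

The chain mirrors a standard resting-EEG cleaning pipeline: a zero-phase
0.5-45 Hz band-pass, segmentation into non-overlapping 10 s epochs,
per-epoch baseline correction, variance-based rejection of noisy epochs and
channels, spherical-spline interpolation of rejected channels, and
re-referencing to the channel average.  The stage order is fixed; the
orchestrator below enforces it.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from scipy.signal import butter, sosfiltfilt
from scipy.special import eval_legendre

from .containers import EpochedData, Recording


def bandpass(recording: Recording, low: float = 0.5, high: float = 45.0) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass (forward-backward)."""
    nyq = recording.fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError("band must satisfy 0 < low < high < Nyquist")
    sos = butter(4, (low, high), btype="bandpass", fs=recording.fs, output="sos")
    out = recording.copy()
    out.data = sosfiltfilt(sos, out.data, axis=-1)
    return out


def epoch(recording: Recording, length: float = 10.0) -> EpochedData:
    """Segment into consecutive non-overlapping epochs; trailing remainder
    is discarded."""
    n_per = int(round(length * recording.fs))
    if n_per <= 0:
        raise ValueError("epoch length must be positive")
    n_epochs = recording.n_samples // n_per
    if n_epochs < 1:
        raise ValueError("recording shorter than one epoch")
    trimmed = recording.data[:, : n_epochs * n_per]
    data = trimmed.reshape(recording.n_channels, n_epochs, n_per).transpose(1, 0, 2)
    return EpochedData(
        data=data.copy(),
        fs=recording.fs,
        labels=list(recording.labels),
        positions=None if recording.positions is None else recording.positions.copy(),
    )


def baseline_correct(epochs: EpochedData) -> EpochedData:
    """Subtract each epoch x channel trace's mean over the entire epoch."""
    out = epochs.copy()
    out.data = out.data - out.data.mean(axis=-1, keepdims=True)
    return out


def reject_by_variance(
    epochs: EpochedData,
    z_threshold: float = 3.0,
    max_fraction: float = 0.5,
) -> EpochedData:
    """Flag and drop abnormally noisy (or dead) epochs and channels.

    The per-item statistic is the log of the variance: each channel's mean
    log-variance across epochs and each epoch's mean log-variance across
    channels are z-scored against their own population, and items with
    |z| > ``z_threshold`` are removed (a single pass).  A warning is raised
    when more than ``max_fraction`` of either population is dropped.
    """
    if epochs.n_epochs < 3 or epochs.n_channels < 3:
        raise ValueError("need at least 3 epochs and 3 channels")
    out = epochs.copy()
    var = out.data.var(axis=-1)  # (epochs, channels)
    logvar = np.log(np.maximum(var, np.finfo(float).tiny))

    def zscores(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        return np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd

    z_epoch = zscores(logvar.mean(axis=1))
    z_chan = zscores(logvar.mean(axis=0))
    bad_epochs = np.abs(z_epoch) > z_threshold
    bad_chans = np.abs(z_chan) > z_threshold
    if bad_epochs.all() or bad_chans.all():
        raise ValueError("all epochs or channels flagged; data degenerate")

    for pos in np.nonzero(bad_epochs)[0]:
        out.rejection_log.append(
            {
                "kind": "epoch",
                "index": out.retained_epochs[pos],
                "zscore": float(z_epoch[pos]),
                "reason": "abnormal log-variance",
            }
        )
    for pos in np.nonzero(bad_chans)[0]:
        out.rejection_log.append(
            {
                "kind": "channel",
                "index": out.retained_channels[pos],
                "label": out.labels[pos],
                "zscore": float(z_chan[pos]),
                "reason": "abnormal log-variance",
            }
        )
    if bad_epochs.mean() > max_fraction or bad_chans.mean() > max_fraction:
        warnings.warn(
            "variance rejection removed more than "
            f"{max_fraction:.0%} of epochs or channels",
            stacklevel=2,
        )
    keep_e = ~bad_epochs
    keep_c = ~bad_chans
    out.data = out.data[keep_e][:, keep_c]
    out.retained_epochs = [
        e for e, k in zip(out.retained_epochs, keep_e) if k
    ]
    out.retained_channels = [
        c for c, k in zip(out.retained_channels, keep_c) if k
    ]
    out.labels = [lbl for lbl, k in zip(out.labels, keep_c) if k]
    if out.positions is not None:
        out.positions = out.positions[keep_c]
    return out


def _spline_g(cosang: np.ndarray, m: int = 4, n_terms: int = 7) -> np.ndarray:
    """Perrin spherical-spline g function (Legendre series)."""
    n = np.arange(1, n_terms + 1)
    coeff = (2 * n + 1) / (n * (n + 1.0)) ** m
    out = np.zeros_like(cosang, dtype=float)
    for k, c in zip(n, coeff):
        out += c * eval_legendre(k, cosang)
    return out / (4 * np.pi)


def interpolate_channels(
    epochs: EpochedData,
    bad: list[int],
    m: int = 4,
    n_terms: int = 7,
    reg: float = 1e-5,
) -> EpochedData:
    """Replace bad channels by a spherical-spline estimate from good ones.

    ``bad`` holds positions into the current channel axis.  Requires unit
    (or unit-normalizable) 3-D electrode positions and at least 4 good
    channels; good channels are untouched.
    """
    if not bad:
        return epochs.copy()
    if epochs.positions is None:
        raise ValueError("channel positions required for interpolation")
    bad = sorted(set(bad))
    if any(b < 0 or b >= epochs.n_channels for b in bad):
        raise ValueError("bad channel index out of range")
    good = [c for c in range(epochs.n_channels) if c not in bad]
    if len(good) < 4:
        raise ValueError("need at least 4 good channels")

    pos = epochs.positions / np.linalg.norm(epochs.positions, axis=1, keepdims=True)
    pg, pb = pos[good], pos[bad]
    g_gg = _spline_g(np.clip(pg @ pg.T, -1, 1), m, n_terms)
    g_bg = _spline_g(np.clip(pb @ pg.T, -1, 1), m, n_terms)
    ng = len(good)
    lhs = np.zeros((ng + 1, ng + 1))
    lhs[:ng, :ng] = g_gg + reg * np.eye(ng)
    lhs[:ng, ng] = 1.0
    lhs[ng, :ng] = 1.0

    out = epochs.copy()
    flat = out.data[:, good, :].transpose(1, 0, 2).reshape(ng, -1)
    rhs = np.vstack([flat, np.zeros((1, flat.shape[1]))])
    sol = np.linalg.solve(lhs, rhs)
    est = g_bg @ sol[:ng] + sol[ng]
    out.data[:, bad, :] = est.reshape(len(bad), out.n_epochs, out.n_samples).transpose(
        1, 0, 2
    )
    for b in bad:
        out.rejection_log.append(
            {
                "kind": "interpolation",
                "index": out.retained_channels[b],
                "label": out.labels[b],
                "reason": "spherical-spline interpolated",
            }
        )
    return out


def average_reference(epochs: EpochedData) -> EpochedData:
    """Re-reference to the instantaneous mean across channels."""
    if epochs.n_channels < 2:
        raise ValueError("need at least 2 channels")
    out = epochs.copy()
    out.data = out.data - out.data.mean(axis=1, keepdims=True)
    return out


def preprocess(
    recording: Recording,
    low: float = 0.5,
    high: float = 45.0,
    epoch_length: float = 10.0,
    z_threshold: float = 3.0,
    interpolate_bad: bool = True,
) -> EpochedData:
    """Run the full fixed-order preprocessing chain.

    Rejected channels are spherical-spline interpolated back in (when
    positions are available) so every participant keeps a common montage,
    then data are average-referenced.
    """
    filtered = bandpass(recording, low, high)
    ep = epoch(filtered, epoch_length)
    ep = baseline_correct(ep)
    before_channels = list(ep.retained_channels)
    ep = reject_by_variance(ep, z_threshold)
    if interpolate_bad and ep.positions is not None:
        dropped = [c for c in before_channels if c not in ep.retained_channels]
        if dropped:
            # reinstate dropped channels as zero traces, then interpolate
            restored = _reinstate_channels(ep, recording, dropped)
            bad_pos = [restored.retained_channels.index(c) for c in dropped]
            ep = interpolate_channels(restored, bad_pos)
    return average_reference(ep)


def _reinstate_channels(
    ep: EpochedData, original: Recording, dropped: list[int]
) -> EpochedData:
    all_chans = sorted(ep.retained_channels + dropped)
    n_e, n_s = ep.n_epochs, ep.n_samples
    data = np.zeros((n_e, len(all_chans), n_s))
    for k, c in enumerate(all_chans):
        if c in ep.retained_channels:
            data[:, k, :] = ep.data[:, ep.retained_channels.index(c), :]
    return replace(
        ep,
        data=data,
        labels=[original.labels[c] for c in all_chans],
        retained_channels=all_chans,
        positions=None
        if original.positions is None
        else original.positions[all_chans],
    )
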