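"""Morlet-wavelet ERSP: per-trial time-frequency power, log-ratio baseline
normalisation to dB, and alpha/beta band averaging.

Power is the squared magnitude of the convolution of each epoch with
unit-energy complex Morlet wavelets (complex sine tapered by a Gaussian,
sigma_t = n_cycles / (2 pi f); 5 cycles by default).  Convolution runs over
FFT with reflective padding; samples within one wavelet half-support of the
epoch edges are flagged invalid and must not enter the baseline or analysis
windows (the -4..-2 s baseline and 0..4 s crop are interior to the -5.5..5 s
epoch by construction).  Power is rescaled per trial/channel/frequency with a
log-ratio transformation, dB(t) = 10 log10(P(t) / mean_baseline P), then
averaged over the band's integer frequency bins (dB-then-average order) and
cropped to the exploration window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import fft as sp_fft

from touchersp.preprocess import EegEpochs

#: Gaussian support kept per side, in units of sigma_t (beyond this the
#: envelope is < 1e-5 of peak)
_SUPPORT_SIGMAS = 5.0


class TimeFreqError(ValueError):
    """Labelled error from the time-frequency stage."""


@dataclass
class TfPower:
    """Trials x channels x frequencies x time power (uV^2) or dB after
    baseline rescaling; ``valid`` masks samples free of edge contamination
    per frequency."""

    data: np.ndarray
    freqs: np.ndarray
    t_ms: np.ndarray
    fs: float
    n_cycles: float
    valid: np.ndarray  # frequencies x time, bool
    trials: pd.DataFrame
    ch_names: list[str]
    subject: str = ""
    is_db: bool = False
    provenance: list[dict] = field(default_factory=list)


@dataclass
class BandPowerEpochs:
    """Trials x channels x time band-averaged ERSP in dB, cropped to the
    exploration window.  Negative values are ERD, positive ERS."""

    data: np.ndarray
    band: str
    band_hz: tuple[float, float]
    t_ms: np.ndarray
    fs: float
    trials: pd.DataFrame
    ch_names: list[str]
    subject: str = ""
    baseline_ms: tuple[float, float] = (-4000.0, -2000.0)


def morlet_sigma_t(freq_hz: float, n_cycles: float = 5.0) -> float:
    """Temporal width (s) of the Morlet wavelet: n_cycles / (2 pi f)."""
    return n_cycles / (2.0 * np.pi * freq_hz)


def morlet_wavelet(freq_hz: float, fs: float, n_cycles: float = 5.0) -> np.ndarray:
    """Discrete unit-energy complex Morlet wavelet at ``freq_hz``."""
    sigma = morlet_sigma_t(freq_hz, n_cycles)
    half = int(np.ceil(_SUPPORT_SIGMAS * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(-(t**2) / (2 * sigma**2)) * np.exp(2j * np.pi * freq_hz * t)
    return w / np.linalg.norm(w)


def morlet_power(
    ep: EegEpochs,
    freqs: np.ndarray | list[float] | None = None,
    n_cycles: float = 5.0,
    *,
    precision: str = "double",
) -> TfPower:
    """Time-frequency power of every epoch (FFT convolution, reflective pad).

    ``freqs`` defaults to the full 1..40 Hz range in 1-Hz steps; pass a
    subset (e.g. only the band bins) to bound memory.  The epoch must be at
    least twice as long as the widest wavelet.  ``precision='single'``
    halves memory and runtime; the log-ratio ERSP is unaffected at the dB
    scales of interest (relative power error ~1e-6).
    """
    if freqs is None:
        freqs = np.arange(1.0, 41.0)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.min() <= 0:
        raise TimeFreqError("frequencies must be positive")
    x = np.asarray(ep.data, dtype=float)
    n = x.shape[-1]

    halfmax = int(np.ceil(_SUPPORT_SIGMAS * morlet_sigma_t(freqs.min(), n_cycles) * ep.fs))
    if n < 2 * halfmax + 1:
        raise TimeFreqError(
            f"epoch of {n} samples shorter than twice the widest wavelet "
            f"({2 * halfmax + 1} samples at {freqs.min()} Hz)"
        )
    if precision not in ("single", "double"):
        raise TimeFreqError("precision must be 'single' or 'double'")
    pad = halfmax
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    if precision == "single":
        xp = xp.astype(np.float32)
    nfft = sp_fft.next_fast_len(xp.shape[-1] + 2 * halfmax + 1)
    X = sp_fft.fft(xp, nfft, axis=-1)

    out_dtype = np.float32 if precision == "single" else np.float64
    out = np.empty(x.shape[:-1] + (len(freqs), n), dtype=out_dtype)
    valid = np.ones((len(freqs), n), dtype=bool)
    for i, f in enumerate(freqs):
        w = morlet_wavelet(f, ep.fs, n_cycles)
        half = len(w) // 2
        W = sp_fft.fft(w, nfft)
        if precision == "single":
            W = W.astype(np.complex64)
        conv = sp_fft.ifft(X * W, axis=-1)
        # 'same' alignment: convolution output k corresponds to input k - half
        seg = conv[..., pad + half : pad + half + n]
        out[..., i, :] = seg.real**2 + seg.imag**2
        valid[i, :half] = False
        valid[i, n - half :] = False

    return TfPower(
        data=out,
        freqs=freqs,
        t_ms=ep.t_ms.copy(),
        fs=ep.fs,
        n_cycles=n_cycles,
        valid=valid,
        trials=ep.trials,
        ch_names=ep.ch_names,
        subject=ep.subject,
        provenance=ep.provenance + [{"step": "morlet_power", "n_cycles": n_cycles,
                                     "freqs": [float(f) for f in freqs]}],
    )


def logratio_baseline(
    tf: TfPower,
    baseline_ms: tuple[float, float] = (-4000.0, -2000.0),
    *,
    scale: str = "db",
    statistic: str = "mean",
    out_window_ms: tuple[float, float] | None = None,
) -> TfPower:
    """Rescale power to dB relative to the pre-onset baseline.

    Per trial, channel and frequency: dB(t) = 10 log10(P(t) / B) with B the
    mean (or median, ``statistic='median'``) power over the baseline window.
    ``scale='ln'`` gives a natural-log ratio instead of dB.  The baseline
    window must lie inside the edge-valid samples at every frequency.
    ``out_window_ms`` restricts the returned time axis (the baseline is
    always taken from the full epoch first); values outside are identical,
    merely not materialised.
    """
    if tf.is_db:
        raise TimeFreqError("power already baseline-rescaled")
    sel = (tf.t_ms >= baseline_ms[0]) & (tf.t_ms <= baseline_ms[1])
    if not sel.any():
        raise TimeFreqError(f"baseline window {baseline_ms} outside the epoch")
    if not tf.valid[:, sel].all():
        raise TimeFreqError("baseline window overlaps edge-contaminated samples")
    base = tf.data[..., sel]
    red = np.mean if statistic == "mean" else np.median
    b = red(base, axis=-1, keepdims=True)
    if np.any(b <= 0):
        raise TimeFreqError("zero baseline power; cannot form log-ratio")
    if out_window_ms is not None:
        keep = (tf.t_ms >= out_window_ms[0]) & (tf.t_ms <= out_window_ms[1])
    else:
        keep = np.ones_like(tf.t_ms, dtype=bool)
    ratio = tf.data[..., keep] / b
    out = 10.0 * np.log10(ratio) if scale == "db" else np.log(ratio)
    return TfPower(
        data=out.astype(tf.data.dtype),
        freqs=tf.freqs,
        t_ms=tf.t_ms[keep],
        fs=tf.fs,
        n_cycles=tf.n_cycles,
        valid=tf.valid[:, keep],
        trials=tf.trials,
        ch_names=tf.ch_names,
        subject=tf.subject,
        is_db=True,
        provenance=tf.provenance + [{"step": "logratio_baseline", "baseline_ms": list(baseline_ms),
                                     "scale": scale, "statistic": statistic}],
    )


def band_average_crop(
    tf_db: TfPower,
    band: str | tuple[float, float],
    crop_ms: tuple[float, float] = (0.0, 4000.0),
) -> BandPowerEpochs:
    """Average dB values over the band's frequency bins, then crop in time.

    ``band`` is 'alpha' (8-12 Hz), 'beta' (16-24 Hz) or an explicit (lo, hi)
    pair; the integer bins lo..hi must all be present in ``tf_db.freqs``.
    """
    from touchersp.config import BANDS

    if isinstance(band, str):
        if band not in BANDS:
            raise TimeFreqError(f"unknown band {band!r}")
        name, (lo, hi) = band, BANDS[band]
    else:
        lo, hi = band
        name = f"{lo:g}-{hi:g}Hz"
    sel_f = (tf_db.freqs >= lo) & (tf_db.freqs <= hi)
    if not sel_f.any():
        raise TimeFreqError(f"band {name} has no frequency bins in {tf_db.freqs}")
    sel_t = (tf_db.t_ms >= crop_ms[0]) & (tf_db.t_ms <= crop_ms[1])
    if not tf_db.valid[np.ix_(sel_f, sel_t)].all():
        raise TimeFreqError("crop window overlaps edge-contaminated samples")
    data = tf_db.data[..., sel_f, :].mean(axis=-2)[..., sel_t]
    return BandPowerEpochs(
        data=data,
        band=name,
        band_hz=(float(lo), float(hi)),
        t_ms=tf_db.t_ms[sel_t],
        fs=tf_db.fs,
        trials=tf_db.trials,
        ch_names=tf_db.ch_names,
        subject=tf_db.subject,
    )
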