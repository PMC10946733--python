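"""EEG filtering, onset-locked epoching, downsampling and re-referencing.

Raw EEG is zero-phase band-pass filtered 1-100 Hz with a 48-52 Hz band-stop
(fourth-order Butterworth sections applied forward-backward; an FIR mode is
available), fused with the per-trial movement-onset markers from the touch
sensor, epoched -5.5..+5 s around movement onset, downsampled to 256 Hz with
polyphase anti-alias filtering, and re-referenced to the common average.
Residual high-amplitude trials can be dropped with a simple peak-to-peak
threshold (the stand-in for manual artifact screening; the synthetic data
contain no ocular sources).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal


class PreprocessError(ValueError):
    """Labelled error from the preprocessing stage."""


@dataclass
class EegRecording:
    """Continuous EEG: ``data`` channels x samples in uV at ``fs`` Hz."""

    data: np.ndarray
    fs: float
    ch_names: list[str]
    montage: pd.DataFrame | None = None
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise PreprocessError("EEG data must be channels x samples")
        if len(self.ch_names) != self.data.shape[0]:
            raise PreprocessError("channel name count does not match data rows")
        if self.fs <= 0:
            raise PreprocessError("fs must be > 0")


@dataclass
class EegEpochs:
    """Onset-locked epochs: ``data`` trials x channels x samples (uV),
    ``t_ms`` relative to movement onset; ``trials`` carries one row of labels
    per retained epoch (trial, texture, condition, ...)."""

    data: np.ndarray
    t_ms: np.ndarray
    fs: float
    trials: pd.DataFrame
    ch_names: list[str]
    subject: str = ""
    montage: pd.DataFrame | None = None
    provenance: list[dict] = field(default_factory=list)

    def copy_with(self, data: np.ndarray, t_ms: np.ndarray | None = None, fs: float | None = None,
                  trials: pd.DataFrame | None = None, extra_prov: dict | None = None) -> "EegEpochs":
        prov = list(self.provenance) + ([extra_prov] if extra_prov else [])
        return EegEpochs(
            data=data,
            t_ms=self.t_ms if t_ms is None else t_ms,
            fs=self.fs if fs is None else fs,
            trials=self.trials if trials is None else trials,
            ch_names=self.ch_names,
            subject=self.subject,
            montage=self.montage,
            provenance=prov,
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def filter_raw(
    rec: EegRecording,
    *,
    hp_hz: float = 1.0,
    lp_hz: float = 100.0,
    notch_hz: tuple[float, float] = (48.0, 52.0),
    order: int = 4,
    mode: str = "iir",
) -> EegRecording:
    """Zero-phase 1-100 Hz band-pass plus 48-52 Hz band-stop.

    ``mode='iir'`` (default) uses Butterworth second-order sections applied
    with ``sosfiltfilt``; ``mode='fir'`` uses linear-phase windowed-sinc
    filters applied with ``filtfilt``-style compensation.  The filter family
    and order are recorded in the provenance log.
    """
    nyq = rec.fs / 2.0
    if lp_hz >= nyq:
        raise PreprocessError(
            f"low-pass edge {lp_hz} Hz requires fs > {2 * lp_hz} Hz (got fs={rec.fs})"
        )
    x = np.asarray(rec.data, dtype=float)
    if mode == "iir":
        sos_bp = signal.butter(order, [hp_hz, lp_hz], btype="bandpass", fs=rec.fs, output="sos")
        sos_bs = signal.butter(order, list(notch_hz), btype="bandstop", fs=rec.fs, output="sos")
        y = signal.sosfiltfilt(sos_bp, x, axis=-1)
        y = signal.sosfiltfilt(sos_bs, y, axis=-1)
    elif mode == "fir":
        numtaps = int(3 * rec.fs / hp_hz) | 1
        taps_bp = signal.firwin(numtaps, [hp_hz, lp_hz], pass_zero=False, fs=rec.fs)
        taps_bs = signal.firwin(int(rec.fs) | 1, list(notch_hz), fs=rec.fs)  # band-stop
        y = signal.filtfilt(taps_bp, [1.0], x, axis=-1)
        y = signal.filtfilt(taps_bs, [1.0], y, axis=-1)
    else:
        raise PreprocessError(f"unknown filter mode {mode!r}")
    prov = rec.provenance + [
        {
            "step": "filter_raw",
            "mode": mode,
            "order": order,
            "hp_hz": hp_hz,
            "lp_hz": lp_hz,
            "notch_hz": list(notch_hz),
            "zero_phase": True,
        }
    ]
    return EegRecording(y, rec.fs, rec.ch_names, rec.montage, prov)


def epoch_to_onsets(
    rec: EegRecording,
    trials: pd.DataFrame,
    *,
    window_ms: tuple[float, float] = (-5500.0, 5000.0),
    subject: str = "",
) -> EegEpochs:
    """Cut one epoch per accepted trial around (cue time + movement onset).

    ``trials`` needs columns ``trial, cue_time_ms, texture, condition,
    onset_ms, accepted`` (the touch-kinetics output joined with events); EEG
    and sensor are assumed to share a clock.  Epochs whose window exceeds the
    recording bounds are dropped with a logged reason.
    """
    acc = trials[trials["accepted"]].copy() if "accepted" in trials else trials.copy()
    if acc.empty:
        raise PreprocessError("no accepted trials to epoch")
    lo, hi = window_ms
    n_out = int(round((hi - lo) / 1000.0 * rec.fs)) + 1
    epochs = []
    kept_rows = []
    dropped = 0
    for _, row in acc.iterrows():
        onset_abs_ms = float(row["cue_time_ms"]) + float(row["onset_ms"])
        start = int(round((onset_abs_ms + lo) / 1000.0 * rec.fs))
        if start < 0 or start + n_out > rec.data.shape[1]:
            dropped += 1
            continue
        epochs.append(rec.data[:, start : start + n_out])
        kept_rows.append(row)
    if not epochs:
        raise PreprocessError("all epochs fell outside the recording bounds")
    data = np.stack(epochs)
    t_ms = lo + np.arange(n_out) * (1000.0 / rec.fs)
    prov = rec.provenance + [
        {"step": "epoch_to_onsets", "window_ms": list(window_ms), "dropped_out_of_bounds": dropped}
    ]
    return EegEpochs(data, t_ms, rec.fs, pd.DataFrame(kept_rows).reset_index(drop=True),
                     rec.ch_names, subject, rec.montage, prov)


def downsample(ep: EegEpochs, target_hz: float = 256.0) -> EegEpochs:
    """Anti-alias resample epochs to ``target_hz`` (polyphase)."""
    if target_hz >= ep.fs:
        raise PreprocessError(f"target rate {target_hz} must be below fs {ep.fs}")
    frac = Fraction(target_hz / ep.fs).limit_denominator(1000)
    y = signal.resample_poly(ep.data, frac.numerator, frac.denominator, axis=-1)
    t_ms = ep.t_ms[0] + np.arange(y.shape[-1]) * (1000.0 / target_hz)
    return ep.copy_with(y, t_ms=t_ms, fs=target_hz,
                        extra_prov={"step": "downsample", "target_hz": target_hz,
                                    "up": frac.numerator, "down": frac.denominator})


def common_average_reference(ep: EegEpochs) -> EegEpochs:
    """Subtract the instantaneous across-channel mean at every timepoint."""
    if ep.data.shape[1] < 2:
        raise PreprocessError("common average reference needs >= 2 channels")
    y = ep.data - ep.data.mean(axis=1, keepdims=True)
    return ep.copy_with(y, extra_prov={"step": "common_average_reference"})


def amplitude_artifact_reject(ep: EegEpochs, threshold_uv: float = 500.0) -> EegEpochs:
    """Drop trials whose peak-to-peak amplitude exceeds the threshold on any
    channel (simple stand-in for manual artifact screening)."""
    if threshold_uv <= 0:
        raise PreprocessError("threshold must be > 0")
    ptp = ep.data.max(axis=-1) - ep.data.min(axis=-1)  # trials x channels
    keep = (ptp <= threshold_uv).all(axis=1)
    if not keep.any():
        raise PreprocessError(
            f"amplitude threshold {threshold_uv} uV rejected every trial; review the threshold"
        )
    n_drop = int((~keep).sum())
    return ep.copy_with(
        ep.data[keep],
        trials=ep.trials[keep].reset_index(drop=True),
        extra_prov={"step": "amplitude_artifact_reject", "threshold_uv": threshold_uv,
                    "n_dropped": n_drop},
    )
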