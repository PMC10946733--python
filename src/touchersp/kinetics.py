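"""Six-axis force/torque streams -> per-trial touch kinetics and QC.

A plate instrumented with a six-axis sensor records the forces (Fx, Fy, Fz; N)
and torques (Mx, My, Mz; N*m) the exploring finger applies.  Under static
equilibrium the contact point (centre of pressure) is recoverable from the
moments and the normal force; the tangential force magnitude is the friction
force and |Fz| the load.  Channels are block-averaged to 20 Hz before any
kinetic quantity is computed, movement onset is detected from per-axis
velocity peaks, and trials violating the rejection rules (missing trigger,
baseline movement, onset later than 400 ms after the cue, |z| > 2 outliers)
are flagged.

Sign convention (shared with the synthetic generator): compression gives
Fz < 0; the contact plane sits at z = -h relative to the sensor reference,
so x = (-My - Fx*h)/Fz and y = (Mx - Fy*h)/Fz, with h the plate thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from touchersp.config import G_STANDARD

SENSOR_COLUMNS = ["t_ms", "Fx_N", "Fy_N", "Fz_N", "Mx_Nm", "My_Nm", "Mz_Nm"]

QC_FLAGS = ("no_trigger", "baseline_movement", "late_onset", "zscore_outlier")


class KineticsError(ValueError):
    """Labelled input error from the kinetics stage."""


@dataclass
class SixAxisRecording:
    """Raw force/torque channels plus trial events.

    ``data`` is a DataFrame with columns ``t_ms, Fx_N..Mz_Nm`` sampled
    uniformly at ``fs`` Hz; ``events`` holds one row per trial with columns
    ``trial, cue_time_ms, texture, condition`` (and optionally ``block``).
    """

    data: pd.DataFrame
    fs: float
    events: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SENSOR_COLUMNS if c not in self.data.columns]
        if missing:
            raise KineticsError(f"sensor data missing columns {missing}")
        if self.fs <= 0:
            raise KineticsError("fs must be > 0")


@dataclass
class KineticsTrace:
    """Per-trial 20-Hz kinetics: contact position (mm), friction (N),
    load (g) and scalar speed (mm/s); NaN where the finger is off the plate."""

    t_ms: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    friction_n: np.ndarray
    load_g: np.ndarray
    speed_mm_s: np.ndarray
    fs: float = 20.0


@dataclass
class TouchTrial:
    """Per-trial summary: detected onset, median covariates and QC flags."""

    trial: int
    texture: str
    condition: str
    subject: str = ""
    block: int = 0
    onset_ms: float | None = None
    median_speed: float | None = None
    median_friction: float | None = None
    median_load: float | None = None
    qc_flags: set = field(default_factory=set)

    @property
    def accepted(self) -> bool:
        return not self.qc_flags


def trials_to_frame(trials: list[TouchTrial]) -> pd.DataFrame:
    rows = []
    for tr in trials:
        rows.append(
            {
                "subject": tr.subject,
                "trial": tr.trial,
                "block": tr.block,
                "texture": tr.texture,
                "condition": tr.condition,
                "onset_ms": np.nan if tr.onset_ms is None else tr.onset_ms,
                "median_speed": np.nan if tr.median_speed is None else tr.median_speed,
                "median_friction": np.nan if tr.median_friction is None else tr.median_friction,
                "median_load": np.nan if tr.median_load is None else tr.median_load,
                "qc_flags": ",".join(sorted(tr.qc_flags)),
                "accepted": tr.accepted,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def block_average(series: np.ndarray, fs: float, target_rate: float = 20.0) -> np.ndarray:
    """Non-overlapping block means reducing ``fs`` to ``target_rate``.

    Each output sample is the arithmetic mean of one block of ``fs /
    target_rate`` consecutive input samples; a final partial block is
    truncated.  Works on the last axis of any array.
    """
    if target_rate > fs:
        raise KineticsError(f"target_rate {target_rate} exceeds sampling rate {fs}")
    block = fs / target_rate
    if abs(block - round(block)) > 1e-9:
        # non-integer ratio: truncate to the largest usable length
        block = int(np.floor(block))
    block = int(round(block))
    series = np.asarray(series, dtype=float)
    n_out = series.shape[-1] // block
    trimmed = series[..., : n_out * block]
    return trimmed.reshape(*series.shape[:-1], n_out, block).mean(axis=-1)


def compute_kinetics(
    data: pd.DataFrame,
    fs: float = 20.0,
    *,
    plate_thickness_mm: float = 3.0,
    contact_threshold_n: float = 0.05,
) -> KineticsTrace:
    """Contact position, friction, load and speed from 20-Hz channels.

    ``data`` must already be block-averaged to ``fs`` (20 Hz).  Position is
    the centre of pressure under static equilibrium (see module docstring for
    the sign convention); friction is the tangential force magnitude
    sqrt(Fx^2+Fy^2); load |Fz| expressed in grams-force.  Speed is the
    first-difference path speed in mm/s (first sample 0).  Samples with
    |Fz| below ``contact_threshold_n`` carry NaN position/speed.
    """
    t = data["t_ms"].to_numpy(dtype=float)
    fx = data["Fx_N"].to_numpy(dtype=float)
    fy = data["Fy_N"].to_numpy(dtype=float)
    fz = data["Fz_N"].to_numpy(dtype=float)
    mx = data["Mx_Nm"].to_numpy(dtype=float)
    my = data["My_Nm"].to_numpy(dtype=float)

    friction = np.hypot(fx, fy)
    load_g = np.abs(fz) / G_STANDARD * 1000.0

    h = plate_thickness_mm / 1000.0  # m
    contact = np.abs(fz) >= contact_threshold_n
    with np.errstate(divide="ignore", invalid="ignore"):
        x_m = (-my - fx * h) / fz
        y_m = (mx - fy * h) / fz
    x_mm = np.where(contact, x_m * 1000.0, np.nan)
    y_mm = np.where(contact, y_m * 1000.0, np.nan)

    speed = np.full_like(x_mm, np.nan)
    if len(x_mm) > 1:
        step = np.hypot(np.diff(x_mm), np.diff(y_mm)) * fs
        speed[1:] = step
    if len(speed):
        speed[0] = 0.0 if contact[0] else np.nan
    return KineticsTrace(t, x_mm, y_mm, friction, load_g, speed, fs=fs)


def _first_peak(v: np.ndarray, t: np.ndarray, prominence: float, distance: int) -> float | None:
    """Earliest candidate from the positive and negative extrema of one
    signed velocity trace, per the half-height peak rule."""
    cands = []
    vmax = np.nanmax(v) if len(v) else 0.0
    vmin = np.nanmin(v) if len(v) else 0.0
    if vmax > 0:
        idx, _ = find_peaks(v, height=vmax / 2.0, prominence=prominence, distance=distance)
        if len(idx):
            cands.append(t[idx[0]])
    if vmin < 0:
        idx, _ = find_peaks(-v, height=-vmin / 2.0, prominence=prominence, distance=distance)
        if len(idx):
            cands.append(t[idx[0]])
    return min(cands) if cands else None


def detect_movement_onset(
    trace: KineticsTrace,
    cue_time_ms: float = 0.0,
    *,
    window_ms: tuple[float, float] = (-200.0, 4000.0),
    prominence: float = 1.0,
    distance: int = 1,
    use_scalar_speed: bool = False,
) -> float | None:
    """Movement onset relative to the cue, from velocity peaks.

    Signed per-axis velocities v_x, v_y (first differences of position) are
    scanned within ``window_ms`` around the cue for the first local maximum
    with height at least half the trace extremum (positive side) and the
    first local minimum mirrored likewise, with peak prominence and minimum
    separation as configured (both default 1, the permissive peak-finder
    defaults).  The onset is the earliest candidate; ``None`` when no
    candidate exists (flat trace).

    ``use_scalar_speed`` switches to peaks of the nonnegative speed trace.
    """
    rel = trace.t_ms - cue_time_ms
    sel = (rel >= window_ms[0]) & (rel <= window_ms[1])
    if sel.sum() < 3:
        return None
    t = rel[sel]
    if use_scalar_speed:
        v = np.nan_to_num(trace.speed_mm_s[sel])
        vmax = v.max()
        if vmax <= 0:
            return None
        idx, _ = find_peaks(v, height=vmax / 2.0, prominence=prominence, distance=distance)
        return float(t[idx[0]]) if len(idx) else None

    # forward-difference stamping: movement inside sample k is attributed to
    # t[k], never later -- the conservative convention for an onset detector
    cands = []
    for pos in (trace.x_mm, trace.y_mm):
        v = np.diff(np.nan_to_num(pos[sel])) * trace.fs  # mm/s, signed
        c = _first_peak(v, t[:-1], prominence, distance)
        if c is not None:
            cands.append(c)
    return float(min(cands)) if cands else None


def _longest_run(mask: np.ndarray) -> int:
    """Length of the longest run of True values."""
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def qc_and_summarise(
    trials: list[tuple[KineticsTrace, pd.Series]],
    *,
    baseline_still_mm_s: float = 5.0,
    baseline_min_run: int = 5,
    onset_max_ms: float = 400.0,
    baseline_window_ms: tuple[float, float] = (-4900.0, 0.0),
    trial_end_ms: float = 4000.0,
    onset_kwargs: dict | None = None,
) -> list[TouchTrial]:
    """Apply the trial-rejection rules and compute median covariates.

    Per trial: flag ``no_trigger`` when the cue event is missing (NaN cue
    time), ``baseline_movement`` when speed exceeds the stillness threshold
    *sustained* over at least ``baseline_min_run`` consecutive 20-Hz samples
    (250 ms by default, so isolated noise exceedances never reject a trial)
    of the baseline/cue window, and ``late_onset`` when onset is
    undefined or strictly later than ``onset_max_ms`` after the cue.  Median
    speed, friction and load are computed from movement onset to the end of
    the trial period for trials with a defined onset.
    """
    if not trials:
        raise KineticsError("empty trial list")
    onset_kwargs = onset_kwargs or {}
    out: list[TouchTrial] = []
    for trace, ev in trials:
        tt = TouchTrial(
            trial=int(ev["trial"]),
            texture=str(ev["texture"]),
            condition=str(ev["condition"]),
            subject=str(ev.get("subject", "")),
            block=int(ev.get("block", 0)),
        )
        cue = float(ev["cue_time_ms"])
        if not np.isfinite(cue):
            tt.qc_flags.add("no_trigger")
            out.append(tt)
            continue
        rel = trace.t_ms - cue
        base = (rel >= baseline_window_ms[0]) & (rel < baseline_window_ms[1])
        over = np.nan_to_num(trace.speed_mm_s[base]) > baseline_still_mm_s
        if _longest_run(over) >= baseline_min_run:
            tt.qc_flags.add("baseline_movement")

        onset = detect_movement_onset(trace, cue, **onset_kwargs)
        tt.onset_ms = onset
        if onset is None or onset > onset_max_ms:
            tt.qc_flags.add("late_onset")
        if onset is not None:
            win = (rel >= onset) & (rel <= trial_end_ms)
            tt.median_speed = float(np.nanmedian(trace.speed_mm_s[win]))
            tt.median_friction = float(np.nanmedian(trace.friction_n[win]))
            tt.median_load = float(np.nanmedian(trace.load_g[win]))
        out.append(tt)
    return out


def zscore_exclude(trials: list[TouchTrial], *, z_limit: float = 2.0) -> list[TouchTrial]:
    """Flag outlying accepted trials within (subject, block, texture) groups.

    Within each group, z-scores (sample SD, n-1) of median speed, friction
    and load are computed over the accepted trials; a trial whose |z| is
    strictly greater than ``z_limit`` on any measure gains the
    ``zscore_outlier`` flag.  Single-pass (no iterative re-exclusion);
    groups with < 2 accepted trials or zero SD pass through unchanged.
    """
    groups: dict[tuple, list[TouchTrial]] = {}
    for tr in trials:
        groups.setdefault((tr.subject, tr.block, tr.texture), []).append(tr)
    for members in groups.values():
        ok = [tr for tr in members if tr.accepted and tr.median_speed is not None]
        if len(ok) < 2:
            continue
        for attr in ("median_speed", "median_friction", "median_load"):
            vals = np.array([getattr(tr, attr) for tr in ok], dtype=float)
            sd = vals.std(ddof=1)
            if sd == 0:
                continue
            z = (vals - vals.mean()) / sd
            for tr, zi in zip(ok, z):
                if abs(zi) > z_limit:
                    tr.qc_flags.add("zscore_outlier")
    return trials
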