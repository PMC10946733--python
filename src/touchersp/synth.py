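"""Synthetic force-plate and EEG recordings with known ground truth.

The generator emulates the statistical structure the analysis assumes, so
every downstream stage is testable without the study's recordings:

* **Touch trials** — a stationary finger through baseline (4 s) and cue (1 s),
  then a smooth two-dimensional exploratory trajectory starting at a drawn
  onset latency.  Fz encodes the (grams-force) load, the tangential force is
  Amontons friction ``|F_xy| = mu_texture * |Fz|`` plus sensor noise, and the
  moments place the centre of pressure at the contact point under static
  equilibrium, so the kinetics stage recovers the trajectory exactly up to
  noise.  The trajectory phase is chosen so tangential speed is maximal at
  movement onset (a brisk start), which is what a first-velocity-peak onset
  detector marks.
* **EEG trials** — 1/f-shaped background noise plus alpha and beta
  oscillators (random phase per channel and trial) whose post-onset amplitude
  on designated channel groups is scaled by ``10**(erd_db/20)`` relative to
  the pre-onset amplitude, so the log-ratio ERSP in dB recovers ``erd_db``.
  Between-subject and trial-to-trial variability of the injected effect are
  configurable dB standard deviations.

Deliberately invalid trials (late onset, baseline movement, missing trigger)
are labelled in the ground-truth table so QC tests are exact, not
statistical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from touchersp.config import (
    BANDS,
    CONDITIONS,
    G_STANDARD,
    RATING_SCALES,
    TEXTURES,
    ConfigError,
    StudyConfig,
    channel_groups,
    geodesic_montage,
)
from touchersp.kinetics import SENSOR_COLUMNS, SixAxisRecording, block_average
from touchersp.preprocess import EegRecording

#: seconds of recording per trial slot; the cue sits at the slot centre so a
#: -5.5..+5 s epoch around any onset within 400 ms of the cue always fits
SLOT_S = 12.0


@dataclass
class GroundTruth:
    """True per-trial generator state: onset, medians, injected ERD."""

    trial: int
    texture: str
    condition: str
    block: int = 0
    subject: str = ""
    onset_ms: float = np.nan
    median_speed: float = np.nan
    median_friction: float = np.nan
    median_load: float = np.nan
    violation: str = ""  # "" | late_onset | baseline_movement | no_trigger
    erd_db: dict[tuple[str, str], float] = field(default_factory=dict)  # (band, group) -> dB


@dataclass
class SyntheticSubject:
    subject: str
    sensor: SixAxisRecording
    eeg: EegRecording
    events: pd.DataFrame
    truth: list[GroundTruth]


@dataclass
class SyntheticStudy:
    config: StudyConfig
    montage: pd.DataFrame
    groups: dict[str, list[str]]
    subjects: list[SyntheticSubject]
    ratings: pd.DataFrame

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for sub in self.subjects:
            for gt in sub.truth:
                row = {
                    "subject": gt.subject,
                    "trial": gt.trial,
                    "block": gt.block,
                    "texture": gt.texture,
                    "condition": gt.condition,
                    "onset_ms": gt.onset_ms,
                    "median_speed": gt.median_speed,
                    "median_friction": gt.median_friction,
                    "median_load": gt.median_load,
                    "violation": gt.violation,
                }
                for (band, group), db in gt.erd_db.items():
                    row[f"erd_{band}_{group}"] = db
                rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Touch trial
# ---------------------------------------------------------------------------


def _trajectory(
    cfg: StudyConfig, rng: np.random.Generator, onset_ms: float, baseline_move: bool, t_ms: np.ndarray
):
    """Analytic contact trajectory (m) and its velocity (m/s) on ``t_ms``
    (ms relative to the cue).  Speed is maximal at onset."""
    tau = (t_ms - onset_ms) / 1000.0  # s since onset
    explore_end = cfg.explore_s * 1000.0

    amp_x = rng.uniform(0.015, 0.030) * rng.choice([-1.0, 1.0])  # m
    amp_y = rng.uniform(0.010, 0.020) * rng.choice([-1.0, 1.0])
    f_x = rng.uniform(0.8, 1.4)  # Hz
    f_y = rng.uniform(0.8, 1.4)
    x0 = rng.uniform(-0.015, 0.015)
    y0 = rng.uniform(-0.015, 0.015)

    moving = (t_ms >= onset_ms) & (t_ms <= explore_end)
    tau_m = np.clip(tau, 0.0, (explore_end - onset_ms) / 1000.0)
    wx = 2 * np.pi * f_x
    wy = 2 * np.pi * f_y
    x = x0 + amp_x * np.sin(wx * tau_m)
    y = y0 + amp_y * (1.0 - np.cos(wy * tau_m))
    vx = np.where(moving, amp_x * wx * np.cos(wx * tau_m), 0.0)
    vy = np.where(moving, amp_y * wy * np.sin(wy * tau_m), 0.0)

    if baseline_move:
        # deliberate movement inside the baseline window (-3..-1 s pre-cue)
        wig = (t_ms >= onset_ms - 5000.0) & (t_ms <= onset_ms - 2000.0)
        tb = (t_ms - (onset_ms - 5000.0)) / 1000.0
        wb = 2 * np.pi * 1.0
        x = x + np.where(wig, 0.005 * np.sin(wb * tb), 0.0)
        vx = vx + np.where(wig, 0.005 * wb * np.cos(wb * tb), 0.0)
    return x, y, vx, vy


def simulate_touch_trial(
    cfg: StudyConfig,
    texture: str,
    rng: np.random.Generator,
    *,
    condition: str = "no_estimation",
    violation: str = "",
    trial: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """One six-axis trial segment spanning -5..+5 s around the cue.

    Returns the 1000-Hz (``cfg.fs_sensor``) force/torque DataFrame with
    ``t_ms`` relative to the cue, and the ground-truth record holding the
    drawn onset latency and the true median speed / friction / load over the
    onset-to-trial-end window (computed from the noiseless 20-Hz traces).
    """
    if texture not in TEXTURES:
        raise ConfigError(f"unknown texture {texture!r}; expected one of {TEXTURES}")
    fs = cfg.fs_sensor
    n = int(round(10.0 * fs))
    t_ms = (np.arange(n) - n // 2) * (1000.0 / fs)  # -5000 .. +4999

    if violation == "late_onset":
        onset = rng.uniform(500.0, 1500.0)
    else:
        # valid trials stay one detector tolerance (50-ms block + margin)
        # below the 400-ms rejection boundary so quantisation of the onset
        # estimate cannot push them over
        onset = float(
            np.clip(rng.normal(cfg.onset_latency_mean_ms, cfg.onset_latency_sd_ms), 0.0, 340.0)
        )
    x, y, vx, vy = _trajectory(cfg, rng, onset, violation == "baseline_movement", t_ms)

    load_g0 = max(40.0, rng.normal(cfg.load_mean_g, cfg.load_sd_g))
    load_g0 *= cfg.condition_load_gain.get(condition, 1.0)
    # slow +-8% load undulation while exploring
    load_g = load_g0 * (1.0 + 0.08 * np.sin(2 * np.pi * 0.3 * t_ms / 1000.0 + rng.uniform(0, 2 * np.pi)))
    load_n = load_g * G_STANDARD / 1000.0

    mu = cfg.mu_friction[texture]
    speed = np.hypot(vx, vy)
    moving = speed > 1e-9
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(moving, vx / np.where(moving, speed, 1.0), 0.0)
        uy = np.where(moving, vy / np.where(moving, speed, 1.0), 0.0)

    fz = -load_n
    f_t = mu * np.abs(fz)  # kinetic friction magnitude while sliding
    fx = np.where(moving, f_t * ux, 0.0)
    fy = np.where(moving, f_t * uy, 0.0)

    # static-equilibrium moments; contact plane at z = -h wrt sensor reference
    h = cfg.plate_thickness_mm / 1000.0
    mx = y * fz + fy * h
    my = -x * fz - fx * h
    mz = x * fy - y * fx

    if cfg.sensor_noise_n > 0:
        fx = fx + rng.normal(0, cfg.sensor_noise_n, n)
        fy = fy + rng.normal(0, cfg.sensor_noise_n, n)
        fz = fz + rng.normal(0, cfg.sensor_noise_n, n)
        arm = 0.01  # m; moment noise for a ~1 cm lever
        mx = mx + rng.normal(0, cfg.sensor_noise_n * arm, n)
        my = my + rng.normal(0, cfg.sensor_noise_n * arm, n)
        mz = mz + rng.normal(0, cfg.sensor_noise_n * arm, n)

    seg = pd.DataFrame(
        {
            "t_ms": t_ms,
            "Fx_N": fx,
            "Fy_N": fy,
            "Fz_N": fz,
            "Mx_Nm": mx,
            "My_Nm": my,
            "Mz_Nm": mz,
        }
    )

    # true medians over onset..trial-end at the 20-Hz analysis rate
    t20 = block_average(t_ms, fs, 20.0)
    sp20 = block_average(speed * 1000.0, fs, 20.0)  # mm/s
    fr20 = block_average(f_t, fs, 20.0)
    ld20 = block_average(load_g, fs, 20.0)
    win = (t20 >= onset) & (t20 <= cfg.explore_s * 1000.0)
    gt = GroundTruth(
        trial=trial,
        texture=texture,
        condition=condition,
        onset_ms=onset,
        median_speed=float(np.median(sp20[win])) if win.any() else np.nan,
        median_friction=float(np.median(fr20[win])) if win.any() else np.nan,
        median_load=float(np.median(ld20[win])) if win.any() else np.nan,
        violation=violation,
    )
    return seg, gt


# ---------------------------------------------------------------------------
# EEG trial
# ---------------------------------------------------------------------------


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], fs: float, psd_at_1hz: float) -> np.ndarray:
    """Gaussian 1/f (pink) noise with one-sided PSD ``psd_at_1hz / f``."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    gain = np.zeros_like(freqs)
    gain[1:] = np.sqrt(psd_at_1hz / freqs[1:] * fs / 2.0)
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1) * gain
    return np.fft.irfft(spec, n=n, axis=-1)


def simulate_eeg_trial(
    cfg: StudyConfig,
    truth: GroundTruth,
    montage: pd.DataFrame,
    rng: np.random.Generator,
    *,
    groups: dict[str, list[str]] | None = None,
    subject_offsets: dict[tuple[str, str, str, str], float] | None = None,
    record_erd: bool = True,
) -> np.ndarray:
    """One EEG trial segment, channels x samples (uV), -6..+6 s around the cue.

    Background 1/f noise plus alpha/beta oscillators with random phase per
    channel; on channels of each configured group the oscillator amplitude
    switches at the true movement onset to ``10**(db/20)`` of its pre-onset
    value, where db = configured effect + subject offset + trial jitter.
    The realised per-(band, group) dB is written into ``truth.erd_db``.
    """
    if len(montage) < 2:
        raise ConfigError("montage must provide >= 2 channels")
    groups = groups if groups is not None else channel_groups(montage)
    subject_offsets = subject_offsets or {}
    labels = list(montage["label"])
    n_ch = len(labels)
    fs = cfg.fs_eeg
    n = int(round(SLOT_S * fs))
    t_ms = (np.arange(n) - n // 2) * (1000.0 / fs)

    osc_power = cfg.osc_amp_uv**2 / 2.0
    # pink-noise level such that alpha-band noise power is noise_db below the
    # oscillator baseline power: band power of c/f over [f1,f2] = c*ln(f2/f1)
    f1, f2 = BANDS["alpha"]
    c = osc_power * 10.0 ** (cfg.noise_db / 10.0) / np.log(f2 / f1)
    data = _pink_noise(rng, (n_ch, n), fs, c)

    onset = truth.onset_ms if np.isfinite(truth.onset_ms) else 0.0
    post = t_ms >= onset

    for band, f_osc in (("alpha", cfg.alpha_hz), ("beta", cfg.beta_hz)):
        jitter = rng.normal(0.0, cfg.trial_db_sd) if cfg.trial_db_sd > 0 else 0.0
        db_ch = np.zeros(n_ch)
        touched = np.zeros(n_ch, dtype=bool)
        for group, members in groups.items():
            base_db = cfg.erd_for(truth.texture, truth.condition, band, group)
            off = subject_offsets.get((truth.texture, truth.condition, band, group), 0.0)
            has_effect = any(
                eff.band == band and eff.group == group and eff.matches(truth.texture, truth.condition)
                for eff in cfg.erd_db
            )
            if not has_effect:
                continue
            db = base_db + off + jitter
            idx = [labels.index(m) for m in members]
            db_ch[idx] += db
            touched[idx] = True
            if record_erd:
                truth.erd_db[(band, group)] = truth.erd_db.get((band, group), 0.0) + db
        phases = rng.uniform(0, 2 * np.pi, n_ch)
        carrier = np.sin(2 * np.pi * f_osc * t_ms[None, :] / 1000.0 + phases[:, None])
        gain = np.ones((n_ch, n))
        gain[:, post] = 10.0 ** (db_ch[:, None] / 20.0)
        data += cfg.osc_amp_uv * gain * carrier
    return data


def _missing_group_check(cfg: StudyConfig, groups: dict[str, list[str]]) -> None:
    for eff in cfg.erd_db:
        if eff.group not in groups:
            raise ConfigError(
                f"erd_db references channel group {eff.group!r} not present in montage groups "
                f"{sorted(groups)}"
            )


# ---------------------------------------------------------------------------
# Whole study
# ---------------------------------------------------------------------------


def _subject_events(cfg: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Blocked, pseudorandomised trial list: four blocks, texture switching at
    each block's halfway point, conditions shuffled within texture runs."""
    per_tex = [
        [(tex, cond) for cond in CONDITIONS for _ in range(cfg.trials_per_cell)]
        for tex in TEXTURES
    ]
    for lst in per_tex:
        rng.shuffle(lst)
    chunks = [np.array_split(np.arange(len(lst)), cfg.n_blocks) for lst in per_tex]
    rows = []
    trial = 0
    for b in range(cfg.n_blocks):
        order = (0, 1) if b % 2 == 0 else (1, 0)
        for tx in order:
            for i in chunks[tx][b]:
                tex, cond = per_tex[tx][int(i)]
                rows.append(
                    {
                        "trial": trial,
                        "cue_time_ms": (trial + 0.5) * SLOT_S * 1000.0,
                        "texture": tex,
                        "condition": cond,
                        "block": b + 1,
                    }
                )
                trial += 1
    return pd.DataFrame(rows)


def _assign_violations(cfg: StudyConfig, n_trials: int, rng: np.random.Generator) -> list[str]:
    labels = [""] * n_trials
    pool = list(range(n_trials))
    rng.shuffle(pool)
    for frac, name in (
        (cfg.frac_late_onset, "late_onset"),
        (cfg.frac_baseline_move, "baseline_movement"),
        (cfg.frac_no_trigger, "no_trigger"),
    ):
        k = int(round(frac * n_trials))
        for _ in range(k):
            if not pool:
                break
            labels[pool.pop()] = name
    return labels


def simulate_subject(
    cfg: StudyConfig,
    subject: str,
    rng: np.random.Generator,
    montage: pd.DataFrame,
    groups: dict[str, list[str]],
    *,
    with_eeg: bool = True,
) -> SyntheticSubject:
    events = _subject_events(cfg, rng)
    n_trials = len(events)
    violations = _assign_violations(cfg, n_trials, rng)

    offsets = {
        (eff_tex, eff_cond, eff.band, eff.group): rng.normal(0.0, cfg.subject_db_sd)
        for eff in cfg.erd_db
        for eff_tex in (TEXTURES if eff.texture == "*" else (eff.texture,))
        for eff_cond in (CONDITIONS if eff.condition == "*" else (eff.condition,))
    } if cfg.subject_db_sd > 0 else {}

    fs_s = cfg.fs_sensor
    n_sensor = int(round(n_trials * SLOT_S * fs_s))
    sensor = np.zeros((6, n_sensor))
    fs_e = cfg.fs_eeg
    n_eeg_slot = int(round(SLOT_S * fs_e))
    eeg = np.zeros((len(montage), n_trials * n_eeg_slot), dtype=np.float32) if with_eeg else None

    truths: list[GroundTruth] = []
    for k in range(n_trials):
        ev = events.iloc[k]
        seg, gt = simulate_touch_trial(
            cfg,
            str(ev["texture"]),
            rng,
            condition=str(ev["condition"]),
            violation=violations[k],
            trial=int(ev["trial"]),
        )
        gt.block = int(ev["block"])
        gt.subject = subject
        cue_idx = int(round(float(ev["cue_time_ms"]) / 1000.0 * fs_s))
        start = cue_idx - len(seg) // 2
        sensor[:, start : start + len(seg)] = seg[SENSOR_COLUMNS[1:]].to_numpy().T

        if with_eeg:
            trial_eeg = simulate_eeg_trial(
                cfg, gt, montage, rng, groups=groups, subject_offsets=offsets
            )
            eeg[:, k * n_eeg_slot : (k + 1) * n_eeg_slot] = trial_eeg
        truths.append(gt)

    if violations.count("no_trigger"):
        events = events.copy()
        for k, v in enumerate(violations):
            if v == "no_trigger":
                events.loc[k, "cue_time_ms"] = np.nan

    t_ms = np.arange(n_sensor) * (1000.0 / fs_s)
    sensor_df = pd.DataFrame({"t_ms": t_ms})
    for i, col in enumerate(SENSOR_COLUMNS[1:]):
        sensor_df[col] = sensor[i]
    rec_sensor = SixAxisRecording(sensor_df, fs_s, events)
    rec_eeg = (
        EegRecording(eeg, fs_e, list(montage["label"]), montage) if with_eeg else None
    )
    return SyntheticSubject(subject, rec_sensor, rec_eeg, events, truths)


def _ratings(cfg: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Trial-level VAS ratings (hedonic trials rate pleasant/comfort, sensory
    trials smooth/soft): silk preferred on every scale; hessian comfort and
    pleasantness decline over blocks (sensitisation to the rough texture)."""
    base = {
        ("silk", "pleasant"): 70.0,
        ("silk", "comfort"): 70.0,
        ("silk", "smooth"): 75.0,
        ("silk", "soft"): 70.0,
        ("hessian", "pleasant"): 38.0,
        ("hessian", "comfort"): 36.0,
        ("hessian", "smooth"): 22.0,
        ("hessian", "soft"): 28.0,
    }
    drift = {"pleasant": -3.0, "comfort": -3.0, "smooth": -1.5, "soft": -1.5}
    n_per_block = max(1, cfg.trials_per_cell // cfg.n_blocks)
    rows = []
    for s in range(cfg.n_subjects):
        subj = f"sub-{s + 1:02d}"
        off = rng.normal(0, 5.0)
        for block in range(1, cfg.n_blocks + 1):
            for tex in TEXTURES:
                for scale in RATING_SCALES:
                    for _ in range(n_per_block):
                        v = base[(tex, scale)] + off + rng.normal(0, 6.0)
                        if tex == "hessian":
                            v += drift[scale] * (block - 1)
                        rows.append(
                            {
                                "subject": subj,
                                "block": block,
                                "texture": tex,
                                "scale": scale,
                                "value": float(np.clip(v, 0.0, 100.0)),
                            }
                        )
    return pd.DataFrame(rows)


def simulate_study(cfg: StudyConfig, *, with_eeg: bool = True) -> SyntheticStudy:
    """Generate the full in-memory study (all subjects) from ``cfg.seed``.

    Bit-reproducible: equal configs give identical arrays.  Set
    ``with_eeg=False`` to generate touch/behaviour data only.
    """
    cfg.validate()
    montage = geodesic_montage(cfg.n_channels, cfg.head_radius_m)
    groups = channel_groups(montage)
    _missing_group_check(cfg, groups)
    subjects = []
    for s in range(cfg.n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1000 + s]))
        subjects.append(
            simulate_subject(cfg, f"sub-{s + 1:02d}", rng, montage, groups, with_eeg=with_eeg)
        )
    ratings = _ratings(cfg, np.random.default_rng(np.random.SeedSequence([cfg.seed, 77])))
    return SyntheticStudy(cfg, montage, groups, subjects, ratings)


def generate_study(cfg: StudyConfig, out_dir: str | Path, *, with_eeg: bool = True) -> SyntheticStudy:
    """Generate and write the study file tree (TSV fixtures + ground truth).

    Writes per subject ``sub-XX_eeg.tsv`` (samples x channels, header row of
    channel names, fs in a JSON sidecar), ``sub-XX_sensor.tsv``,
    ``sub-XX_events.tsv``; plus study-level ``montage.tsv``, ``ratings.tsv``
    and ``ground_truth.tsv``.  Intended for small configurations (EEG TSVs
    grow quickly); heavy verification runs use :func:`simulate_study`
    in memory.
    """
    from touchersp import io

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        study = simulate_study(cfg, with_eeg=with_eeg)
        io.write_montage_tsv(out / "montage.tsv", study.montage)
        study.ratings.to_csv(out / "ratings.tsv", sep="\t", index=False)
        study.truth_frame().to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        for sub in study.subjects:
            io.write_sensor_tsv(out / f"{sub.subject}_sensor.tsv", sub.sensor.data)
            sub.events.to_csv(out / f"{sub.subject}_events.tsv", sep="\t", index=False)
            if with_eeg:
                io.write_eeg_tsv(out / f"{sub.subject}_eeg.tsv", sub.eeg)
        (out / "study_config.json").write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True))
    except OSError as exc:
        raise OSError(f"failed writing study tree under {out}: {exc}") from exc
    return study
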