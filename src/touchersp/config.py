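"""Study and pipeline configuration, montage construction and channel groups.

The synthetic study emulates the trial structure of the active-touch texture
experiment it verifies: two textures (rough hessian, smooth silk) crossed with
three estimation conditions (sensory, hedonic, no estimation), explored with
the right index finger while 128-channel EEG and a six-axis force/torque
sensor record at 1000 Hz.  Desk-scale defaults (8 subjects, 12 trials per
texture x condition cell) keep continuous verification cheap; the full-scale
configuration (31 subjects, 60 trials per cell = 360 trials) is available via
:func:`StudyConfig.paper_scale`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

TEXTURES = ("hessian", "silk")
CONDITIONS = ("sensory", "hedonic", "no_estimation")

#: Cell codes in design-matrix column order: hedonic hessian, sensory hessian,
#: no-estimation hessian, hedonic silk, sensory silk, no-estimation silk.
CELLS = ("HH", "SH", "NH", "HS", "SS", "NS")

CELL_OF = {
    ("hessian", "hedonic"): "HH",
    ("hessian", "sensory"): "SH",
    ("hessian", "no_estimation"): "NH",
    ("silk", "hedonic"): "HS",
    ("silk", "sensory"): "SS",
    ("silk", "no_estimation"): "NS",
}

BANDS = {"alpha": (8.0, 12.0), "beta": (16.0, 24.0)}

RATING_SCALES = ("pleasant", "comfort", "smooth", "soft")

#: standard gravity, m/s^2, for grams-force <-> newton conversion
G_STANDARD = 9.80665


class ConfigError(ValueError):
    """Raised when a configuration value is out of its documented range."""


@dataclass
class ErdEffect:
    """One injected ERD/ERS effect: a dB change of post-onset band amplitude
    relative to pre-onset, applied to a named channel group.

    ``texture`` and ``condition`` accept ``"*"`` as a wildcard.
    Negative dB = desynchronisation (ERD), positive = synchronisation (ERS).
    """

    texture: str
    condition: str
    band: str
    group: str
    db: float

    def matches(self, texture: str, condition: str) -> bool:
        return self.texture in ("*", texture) and self.condition in ("*", condition)


def default_erd_effects() -> list[ErdEffect]:
    # Alpha ERD over contralateral (left) sensorimotor channels, stronger for
    # the rough texture: -3.36 dB hessian vs -1.91 dB silk.
    return [
        ErdEffect("hessian", "*", "alpha", "sensorimotor_left", -3.36),
        ErdEffect("silk", "*", "alpha", "sensorimotor_left", -1.91),
    ]


@dataclass
class StudyConfig:
    """Parameters of the simulated study; the stated world every test runs in.

    All rates in Hz, durations in seconds, forces derived from grams-force
    loads, ERD effects in dB.  ``seed`` fixes every random draw: equal configs
    produce bit-identical output.
    """

    n_subjects: int = 8
    trials_per_cell: int = 12
    n_blocks: int = 4
    fs_sensor: float = 1000.0
    fs_eeg: float = 1000.0
    baseline_s: float = 4.0
    cue_s: float = 1.0
    explore_s: float = 4.0
    #: unitless friction coefficient per texture (rough > smooth)
    mu_friction: dict[str, float] = field(default_factory=lambda: {"hessian": 0.55, "silk": 0.35})
    load_mean_g: float = 100.0
    load_sd_g: float = 20.0
    #: multiplicative load modulation by estimation condition (hedonic
    #: estimation recruits the highest finger load, no estimation the lowest)
    condition_load_gain: dict[str, float] = field(
        default_factory=lambda: {"sensory": 1.04, "hedonic": 1.08, "no_estimation": 1.0}
    )
    onset_latency_mean_ms: float = 200.0
    onset_latency_sd_ms: float = 60.0
    erd_db: list[ErdEffect] = field(default_factory=default_erd_effects)
    alpha_hz: float = 10.0
    beta_hz: float = 20.0
    #: pink-noise power within each oscillator's band, dB relative to the
    #: oscillator's baseline power (kept low so ERSP recovers the injected dB)
    noise_db: float = -20.0
    #: trial-to-trial SD of the injected amplitude change, dB
    trial_db_sd: float = 1.0
    #: between-subject SD of each injected effect, dB
    subject_db_sd: float = 0.3
    #: baseline oscillation amplitude, uV
    osc_amp_uv: float = 10.0
    #: sensor additive noise, N (0 => exact friction-load coupling)
    sensor_noise_n: float = 0.005
    n_channels: int = 32
    head_radius_m: float = 0.09
    #: plate-thickness term of the centre-of-pressure formula, mm
    plate_thickness_mm: float = 3.0
    #: fractions of deliberately invalid trials (ground-truth labelled)
    frac_late_onset: float = 0.0
    frac_baseline_move: float = 0.0
    frac_no_trigger: float = 0.0
    seed: int = 0

    @classmethod
    def paper_scale(cls, **overrides: Any) -> "StudyConfig":
        """Full-scale study: 31 subjects, 60 trials/cell (360 trials), 128
        channels, between-subject spread matching the reported cluster-power
        SDs (~1.6 dB).  Not used in CI."""
        kw: dict[str, Any] = dict(
            n_subjects=31, trials_per_cell=60, n_channels=128, subject_db_sd=1.64
        )
        kw.update(overrides)
        return cls(**kw)

    # -- validation ---------------------------------------------------------

    def validate(self) -> "StudyConfig":
        if self.trials_per_cell < 1:
            raise ConfigError("trials_per_cell must be >= 1")
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        for name in ("fs_sensor", "fs_eeg", "baseline_s", "cue_s", "explore_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for tex in TEXTURES:
            if tex not in self.mu_friction:
                raise ConfigError(f"mu_friction missing texture {tex!r}")
        for cond in CONDITIONS:
            if cond not in self.condition_load_gain:
                raise ConfigError(f"condition_load_gain missing condition {cond!r}")
        for eff in self.erd_db:
            if not np.isfinite(eff.db):
                raise ConfigError("erd_db values must be finite")
            if eff.band not in BANDS:
                raise ConfigError(f"unknown band {eff.band!r} in erd_db")
        for name in ("frac_late_onset", "frac_baseline_move", "frac_no_trigger"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.n_channels < 2:
            raise ConfigError("n_channels must be >= 2")
        return self

    @property
    def trials_per_subject(self) -> int:
        return self.trials_per_cell * len(TEXTURES) * len(CONDITIONS)

    @property
    def trial_s(self) -> float:
        return self.baseline_s + self.cue_s + self.explore_s

    def erd_for(self, texture: str, condition: str, band: str, group: str) -> float:
        """Injected dB change for one trial cell / band / channel group
        (0 when no configured effect matches)."""
        total = 0.0
        for eff in self.erd_db:
            if eff.band == band and eff.group == group and eff.matches(texture, condition):
                total += eff.db
        return total

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["erd_db"] = [dataclasses.asdict(e) for e in self.erd_db]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StudyConfig":
        d = dict(d)
        d["erd_db"] = [ErdEffect(**e) for e in d.get("erd_db", [])]
        return cls(**d).validate()


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------


def geodesic_montage(n_channels: int = 32, radius_m: float = 0.09) -> pd.DataFrame:
    """Quasi-uniform electrode layout on the upper head sphere.

    Channels are placed by a golden-angle (Fibonacci) spiral over the polar cap
    theta in [0, 105 deg], emulating the coverage of a geodesic sensor net.
    Coordinates follow the RAS-like convention used throughout: +x right,
    +y anterior, +z up, in metres, head centre at the origin.

    Returns a DataFrame with columns ``label, x_m, y_m, z_m``.
    """
    if n_channels < 2:
        raise ConfigError("montage needs >= 2 channels")
    k = np.arange(n_channels)
    theta_max = np.deg2rad(105.0)
    # area-uniform in cos(theta); first point near the vertex
    cos_theta = 1.0 - (1.0 - np.cos(theta_max)) * (k + 0.5) / n_channels
    theta = np.arccos(cos_theta)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = k * golden
    x = radius_m * np.sin(theta) * np.cos(phi)
    y = radius_m * np.sin(theta) * np.sin(phi)
    z = radius_m * np.cos(theta)
    labels = [f"E{i + 1:03d}" for i in range(n_channels)]
    return pd.DataFrame({"label": labels, "x_m": x, "y_m": y, "z_m": z})


def channel_groups(montage: pd.DataFrame) -> dict[str, list[str]]:
    """Named scalp regions defined geometrically on the montage.

    Groups mirror the regions the analysis talks about: left/right
    sensorimotor (central strip, one hemisphere), frontal, occipital and
    parietal.  A channel may belong to several groups; every group is
    guaranteed non-empty for montages of >= 16 channels (nearest channel to
    the region seed is added if the geometric predicate selects none).
    """
    r = float(np.sqrt((montage[["x_m", "y_m", "z_m"]] ** 2).sum(axis=1)).median())
    x = montage["x_m"].to_numpy() / r
    y = montage["y_m"].to_numpy() / r
    z = montage["z_m"].to_numpy() / r
    labels = montage["label"].to_numpy()

    masks = {
        "sensorimotor_left": (np.abs(y) < 0.40) & (x < -0.15) & (z > 0.2),
        "sensorimotor_right": (np.abs(y) < 0.40) & (x > 0.15) & (z > 0.2),
        "frontal": y > 0.45,
        "occipital": y < -0.45,
        "parietal_left": (y > -0.45) & (y < -0.05) & (x < -0.1),
        "parietal_right": (y > -0.45) & (y < -0.05) & (x > 0.1),
    }
    seeds = {
        "sensorimotor_left": (-0.6, 0.0, 0.7),
        "sensorimotor_right": (0.6, 0.0, 0.7),
        "frontal": (0.0, 0.8, 0.5),
        "occipital": (0.0, -0.8, 0.5),
        "parietal_left": (-0.5, -0.3, 0.7),
        "parietal_right": (0.5, -0.3, 0.7),
    }
    groups: dict[str, list[str]] = {}
    for name, mask in masks.items():
        sel = list(labels[mask])
        if not sel:
            sx, sy, sz = seeds[name]
            d2 = (x - sx) ** 2 + (y - sy) ** 2 + (z - sz) ** 2
            sel = [labels[int(np.argmin(d2))]]
        groups[name] = sel
    return groups


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """End-to-end analysis parameters.

    Defaults reproduce the published processing chain: 1-100 Hz band-pass with
    48-52 Hz band-stop, epochs -5.5..5 s around movement onset, 256 Hz,
    common average reference, 5-cycle Morlet ERSP log-ratio-normalised to the
    -4..-2 s baseline, alpha/beta band maps cropped to 0..4 s, 32x32
    scalp-time images smoothed 9x9 mm x 20 ms FWHM, cluster-forming p < .001
    with extent k >= 35 under 18-connectivity.
    """

    study: StudyConfig = field(default_factory=StudyConfig)
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"alpha": (8.0, 12.0), "beta": (16.0, 24.0)}
    )
    hp_hz: float = 1.0
    lp_hz: float = 100.0
    notch_hz: tuple[float, float] = (48.0, 52.0)
    filter_order: int = 4
    epoch_ms: tuple[float, float] = (-5500.0, 5000.0)
    resample_hz: float = 256.0
    baseline_ms: tuple[float, float] = (-4000.0, -2000.0)
    crop_ms: tuple[float, float] = (0.0, 4000.0)
    n_cycles: float = 5.0
    #: Morlet arithmetic precision; 'single' halves runtime/memory and leaves
    #: the dB maps unchanged to ~1e-5
    tf_precision: str = "single"
    amp_reject_uv: float = 500.0
    #: keep every n-th sample of the band maps when stacking scalp-time images
    time_decim: int = 4
    fwhm: tuple[float, float, float] = (9.0, 9.0, 20.0)
    p_form: float = 0.001
    k_min: int = 35
    connectivity: int = 18
    centring: str = "column"  # "column" | "cell"
    #: z-score behaviours before summation (commensurate units; avoids
    #: dummy-modulator collinearity of the raw N + g sum)
    covariate_standardise: bool = False
    baseline_still_mm_s: float = 5.0
    onset_max_ms: float = 400.0
    z_limit: float = 2.0
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        self.study.validate()
        if not 0 < self.p_form < 1:
            raise ConfigError("p_form must lie in (0, 1)")
        if self.k_min < 1:
            raise ConfigError("k_min must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ConfigError("connectivity must be one of 6, 18, 26")
        if self.centring not in ("column", "cell"):
            raise ConfigError("centring must be 'column' or 'cell'")
        if self.time_decim < 1:
            raise ConfigError("time_decim must be >= 1")
        if any(f <= 0 for f in self.fwhm):
            raise ConfigError("fwhm components must be > 0")
        if self.resample_hz > self.study.fs_eeg:
            raise ConfigError("resample_hz must not exceed fs_eeg")
        lo, hi = self.epoch_ms
        if lo >= hi:
            raise ConfigError("epoch_ms must be increasing")
        return self

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["study"] = self.study.to_dict()
        # YAML-friendly: tuples -> lists handled by asdict already via dataclasses? no
        return _tuples_to_lists(d)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        d["study"] = StudyConfig.from_dict(d.get("study", {}))
        for key in ("notch_hz", "epoch_ms", "baseline_ms", "crop_ms", "fwhm"):
            if key in d:
                d[key] = tuple(d[key])
        if "bands" in d:
            d["bands"] = {k: tuple(v) for k, v in d["bands"].items()}
        return cls(**d).validate()

    def to_yaml(self, path: str) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _tuples_to_lists(obj: Any) -> Any:
    if isinstance(obj, tuple):
        return [_tuples_to_lists(v) for v in obj]
    if isinstance(obj, list):
        return [_tuples_to_lists(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    return obj
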