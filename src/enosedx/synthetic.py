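"""Two-site synthetic breathprint generator.

Emulates a 14-channel metal-oxide (MOS) electronic-nose instrument measuring
exhaled breath. Each channel responds to the breath pulse with a
double-exponential adsorption/desorption curve; lung-cancer samples perturb
the channel amplitudes and reaction kinetics, and each acquisition site
applies its own gain, baseline, drift and noise — the domain shift that
degrades a classifier naively transferred between sites.

Nothing here is calibrated to physical gas concentrations; the generator
exists so the full preprocessing / augmentation / CNN / evaluation pipeline
is exercisable and testable without access to patient data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError

N_CHANNELS = 14
MIN_TRACE_LENGTH = 256

SITES = ("S1", "S2")
LABELS = ("lung_cancer", "healthy_control", "diseased_control")

# Fixed per-channel phenomenology of the simulated sensor array: response
# amplitude, rise/decay time constants (in units of normalised trace time)
# and idle baseline. Channels deliberately differ so the array carries a
# multivariate pattern rather than 14 copies of one curve.
_CHANNEL_AMPLITUDE = np.array(
    [1.00, 1.35, 0.80, 1.10, 0.65, 1.50, 0.90, 1.20, 0.75, 1.05, 1.40, 0.85, 0.95, 1.25]
)
_CHANNEL_RISE_TAU = np.array(
    [0.040, 0.060, 0.085, 0.050, 0.110, 0.045, 0.070, 0.095, 0.055, 0.080, 0.065, 0.100, 0.075, 0.048]
)
_CHANNEL_DECAY_TAU = np.array(
    [0.18, 0.30, 0.22, 0.40, 0.26, 0.20, 0.35, 0.24, 0.45, 0.28, 0.21, 0.38, 0.32, 0.25]
)
_CHANNEL_BASELINE = np.array(
    [0.30, 0.45, 0.25, 0.50, 0.35, 0.28, 0.42, 0.33, 0.55, 0.38, 0.27, 0.48, 0.40, 0.31]
)

# Exposure phase occupies the first 40% of the trace, recovery the rest.
_EXPOSURE_FRACTION = 0.4


@dataclass(frozen=True)
class SiteShiftModel:
    """Systematic measurement differences of one acquisition site.

    Parameters
    ----------
    gain : per-channel multiplicative gain (strictly positive, length 14).
    baseline_offset : per-channel additive offset (length 14).
    drift_slope : linear sensor drift added over the trace, per unit of
        normalised trace time (the trace spans time 0..1).
    noise_sd : standard deviation of i.i.d. Gaussian measurement noise, in
        sensor units.
    humidity_modulation : amplitude of a slow multiplicative modulation
        emulating ambient-humidity interference (0 disables it).
    onset_delay : sampling-grid positions by which the site's plumbing and
        flow path delay the breath response (0 = reference timing).
    """

    gain: np.ndarray
    baseline_offset: np.ndarray
    drift_slope: float = 0.0
    noise_sd: float = 0.0
    humidity_modulation: float = 0.0
    onset_delay: int = 0

    def __post_init__(self):
        gain = np.asarray(self.gain, dtype=float)
        offset = np.asarray(self.baseline_offset, dtype=float)
        if gain.shape != (N_CHANNELS,) or offset.shape != (N_CHANNELS,):
            raise InvalidArgumentError(
                f"gain and baseline_offset must have shape ({N_CHANNELS},)"
            )
        if not (np.all(np.isfinite(gain)) and np.all(gain > 0)):
            raise InvalidArgumentError("gain must be finite and strictly positive")
        if not np.all(np.isfinite(offset)):
            raise InvalidArgumentError("baseline_offset must be finite")
        for name in ("drift_slope", "noise_sd", "humidity_modulation"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise InvalidArgumentError(f"{name} must be finite")
        if self.noise_sd < 0 or self.humidity_modulation < 0:
            raise InvalidArgumentError("noise_sd and humidity_modulation must be >= 0")
        if self.onset_delay < 0:
            raise InvalidArgumentError("onset_delay must be >= 0")
        object.__setattr__(self, "gain", gain)
        object.__setattr__(self, "baseline_offset", offset)

    @classmethod
    def identity(cls) -> "SiteShiftModel":
        """The no-op site: unit gain, zero offset/drift/noise/humidity."""
        return cls(gain=np.ones(N_CHANNELS), baseline_offset=np.zeros(N_CHANNELS))


@dataclass(frozen=True)
class ClassEffectModel:
    """How disease alters the breathprint.

    ``amplitude_shift`` perturbs per-channel response amplitudes and
    ``kinetic_rate_factor`` speeds up (>1) or slows down (<1) the
    adsorption/desorption kinetics of lung-cancer samples. Both are scaled
    by ``effect_scale``; at ``effect_scale=0`` cases and controls are drawn
    from the identical distribution.
    """

    amplitude_shift: np.ndarray
    kinetic_rate_factor: float = 1.0
    effect_scale: float = 1.0

    def __post_init__(self):
        shift = np.asarray(self.amplitude_shift, dtype=float)
        if shift.shape != (N_CHANNELS,):
            raise InvalidArgumentError(f"amplitude_shift must have shape ({N_CHANNELS},)")
        if not np.all(np.isfinite(shift)):
            raise InvalidArgumentError("amplitude_shift must be finite")
        if not (np.isfinite(self.kinetic_rate_factor) and self.kinetic_rate_factor > 0):
            raise InvalidArgumentError("kinetic_rate_factor must be finite and > 0")
        if not (np.isfinite(self.effect_scale) and self.effect_scale >= 0):
            raise InvalidArgumentError("effect_scale must be finite and >= 0")
        object.__setattr__(self, "amplitude_shift", shift)


@dataclass
class SensorTrace:
    """One participant's raw 14-channel eNose recording plus metadata."""

    sample_id: str
    site: str
    label: str
    recruitment_time: int
    channels: np.ndarray  # (14, T)
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[0] != N_CHANNELS:
            raise InvalidArgumentError(f"channels must be ({N_CHANNELS}, T)")
        if self.site not in SITES:
            raise InvalidArgumentError(f"site must be one of {SITES}")
        if self.label not in LABELS:
            raise InvalidArgumentError(f"label must be one of {LABELS}")
        if not np.all(np.isfinite(self.channels)):
            raise InvalidArgumentError("trace values must all be finite")

    @property
    def n_timepoints(self) -> int:
        return self.channels.shape[1]

    @property
    def is_cancer(self) -> bool:
        return self.label == "lung_cancer"


# Fixed effect directions. The lung-cancer amplitude signature has mixed
# signs so no single channel is diagnostic on its own; diseased controls get
# a smaller perturbation along a different direction, making them harder to
# separate from cancer than healthy controls are.
_CANCER_AMPLITUDE_SHIFT = np.array(
    [0.10, -0.08, 0.12, 0.05, -0.10, 0.08, -0.06, 0.11, 0.04, -0.09, 0.07, -0.05, 0.09, -0.07]
)
_DISEASED_AMPLITUDE_SHIFT = np.array(
    [-0.04, 0.05, 0.03, -0.05, 0.04, -0.03, 0.05, -0.04, 0.03, 0.04, -0.05, 0.03, -0.04, 0.05]
)
_DISEASED_KINETIC_FACTOR = 1.06

# Between-subject biological variability (log-scale SDs).
_SUBJECT_INTENSITY_SD = 0.12   # whole-breath intensity
_CHANNEL_JITTER_SD = 0.05      # per-channel amplitude
_KINETIC_JITTER_SD = 0.05      # per-subject time constants


def default_class_model(effect_scale: float = 1.0) -> ClassEffectModel:
    """Default lung-cancer effect: kinetic speed-up plus amplitude pattern."""
    return ClassEffectModel(
        amplitude_shift=0.40 * _CANCER_AMPLITUDE_SHIFT,
        kinetic_rate_factor=1.07,
        effect_scale=effect_scale,
    )


def default_site_model(site: str) -> SiteShiftModel:
    """Default per-site measurement models.

    S1 is taken as the reference instrument. S2 differs by per-channel gains,
    baseline offsets, linear drift, extra noise and a humidity modulation —
    enough shift that a model trained on S1 transfers poorly to S2.
    """
    if site == "S1":
        return SiteShiftModel(
            gain=np.ones(N_CHANNELS),
            baseline_offset=np.zeros(N_CHANNELS),
            drift_slope=0.0,
            noise_sd=0.010,
            humidity_modulation=0.0,
        )
    if site == "S2":
        # Uncalibrated second instrument: per-channel gains running against
        # the channels' typical disease-related amplitude pattern, baseline
        # offsets, drift, humidity interference and a noisier front-end.
        gain = np.array(
            [0.75, 1.25, 0.78, 0.76, 1.22, 0.79, 1.27, 0.73, 0.80, 1.24, 0.78, 1.21, 0.74, 1.26]
        )
        offset = np.array(
            [0.25, -0.20, 0.18, -0.28, 0.22, 0.30, -0.18, 0.24, -0.25, 0.20, -0.30, 0.27, 0.21, -0.23]
        )
        return SiteShiftModel(
            gain=gain,
            baseline_offset=offset,
            drift_slope=0.30,
            noise_sd=0.30,
            humidity_modulation=0.20,
            onset_delay=6,
        )
    raise InvalidArgumentError(f"unknown site {site!r}")


def _response_curve(label: str, class_model: ClassEffectModel, T: int, rng: np.random.Generator) -> np.ndarray:
    """Noise-free 14xT response of one subject before any site transform.

    Double-exponential adsorption (exposure) then desorption (recovery),
    with seeded between-subject amplitude and kinetic jitter. The class
    effect enters only through terms multiplied by ``effect_scale`` so that
    at effect_scale=0 all labels share one distribution.
    """
    s = class_model.effect_scale
    amp = _CHANNEL_AMPLITUDE.copy()
    rise = _CHANNEL_RISE_TAU.copy()
    decay = _CHANNEL_DECAY_TAU.copy()

    if label == "lung_cancer":
        amp = amp * (1.0 + s * class_model.amplitude_shift)
        k = 1.0 + s * (class_model.kinetic_rate_factor - 1.0)
        rise = rise / k
        decay = decay / k
    elif label == "diseased_control":
        amp = amp * (1.0 + s * _DISEASED_AMPLITUDE_SHIFT)
        k = 1.0 + s * (_DISEASED_KINETIC_FACTOR - 1.0)
        rise = rise / k
        decay = decay / k

    # Subject-level variability; draws are label-independent.
    intensity = np.exp(_SUBJECT_INTENSITY_SD * rng.standard_normal())
    amp = amp * intensity * np.exp(_CHANNEL_JITTER_SD * rng.standard_normal(N_CHANNELS))
    kin = np.exp(_KINETIC_JITTER_SD * rng.standard_normal())
    rise = rise * kin
    decay = decay * kin

    u = np.linspace(0.0, 1.0, T)
    t_exp = _EXPOSURE_FRACTION
    curve = np.empty((N_CHANNELS, T))
    for c in range(N_CHANNELS):
        up = amp[c] * (1.0 - np.exp(-u / rise[c]))
        peak = amp[c] * (1.0 - np.exp(-t_exp / rise[c]))
        down = peak * np.exp(-(u - t_exp) / decay[c])
        curve[c] = _CHANNEL_BASELINE[c] + np.where(u <= t_exp, up, down)
    return curve


def simulate_sensor_response(
    class_model: ClassEffectModel,
    site_model: SiteShiftModel,
    label: str,
    T: int = 256,
    seed: int | np.random.SeedSequence = 0,
    sample_id: str = "sample",
    site: str = "S1",
    recruitment_time: int = 0,
    covariates: dict | None = None,
) -> SensorTrace:
    """Simulate one breathprint: response curve, site transform, noise.

    Deterministic for a given ``seed``. The Gaussian noise draw is the last
    use of the random stream and is scaled by ``noise_sd``, so the same seed
    with ``noise_sd=0`` yields exactly the underlying noiseless trace.
    """
    if T < MIN_TRACE_LENGTH:
        raise InvalidArgumentError(f"T must be >= {MIN_TRACE_LENGTH}, got {T}")
    if label not in LABELS:
        raise InvalidArgumentError(f"unknown label {label!r}")
    rng = np.random.default_rng(seed)

    x = _response_curve(label, class_model, T, rng)

    if site_model.onset_delay > 0:
        d = site_model.onset_delay
        delayed = np.empty_like(x)
        delayed[:, d:] = x[:, :-d]
        delayed[:, :d] = x[:, :1]
        x = delayed
    u = np.linspace(0.0, 1.0, T)
    x = site_model.gain[:, None] * x + site_model.baseline_offset[:, None]
    x = x + site_model.drift_slope * u[None, :]
    # Humidity: slow multiplicative modulation with a random breath-phase.
    phase = rng.uniform(0.0, 2.0 * np.pi)
    x = x * (1.0 + site_model.humidity_modulation * np.sin(2.0 * np.pi * u + phase))[None, :]
    x = x + site_model.noise_sd * rng.standard_normal((N_CHANNELS, T))

    return SensorTrace(
        sample_id=sample_id,
        site=site,
        label=label,
        recruitment_time=recruitment_time,
        channels=x,
        covariates=covariates or {},
    )


# Covariate marginals loosely matching the demographics of the two-site
# cohort the generator emulates (~65% never-smokers; cancer patients older
# and more often ever-smokers; histology mostly adenocarcinoma; mostly
# late-stage disease).
_SMOKING_LEVELS = ("current", "ex", "never")
_SMOKING_P = {"lung_cancer": (0.16, 0.28, 0.56), "control": (0.13, 0.15, 0.72)}
_HISTOLOGY_LEVELS = ("adenocarcinoma", "squamous", "small_cell", "other")
_HISTOLOGY_P = (0.70, 0.13, 0.08, 0.09)
_STAGE_LEVELS = ("I", "II", "III", "IV")
_STAGE_P = (0.06, 0.04, 0.25, 0.65)


def _draw_covariates(label: str, rng: np.random.Generator) -> dict:
    grp = "lung_cancer" if label == "lung_cancer" else "control"
    if label == "lung_cancer":
        age = rng.normal(63.5, 12.5)
    else:
        age = rng.normal(58.5, 17.0)
    age = float(np.clip(age, 25, 95))
    sex = "male" if rng.random() < 0.51 else "female"
    smoking = _SMOKING_LEVELS[rng.choice(3, p=_SMOKING_P[grp])]
    comorbidities = set()
    if rng.random() < (0.25 if label == "diseased_control" else 0.11):
        comorbidities.add("COPD")
    if rng.random() < 0.13:
        comorbidities.add("DM")
    if rng.random() < 0.26:
        comorbidities.add("HTN")
    cov = {"age": age, "sex": sex, "smoking": smoking, "comorbidities": comorbidities}
    if label == "lung_cancer":
        cov["histology"] = _HISTOLOGY_LEVELS[rng.choice(4, p=_HISTOLOGY_P)]
        cov["stage"] = _STAGE_LEVELS[rng.choice(4, p=_STAGE_P)]
    return cov


def simulate_cohort(
    n_cancer: int,
    n_healthy: int,
    n_diseased: int,
    site: str,
    class_model: ClassEffectModel | None = None,
    site_model: SiteShiftModel | None = None,
    T: int = 256,
    seed: int | np.random.SeedSequence = 0,
    start_time: int = 0,
) -> list[SensorTrace]:
    """Simulate one site's cohort with strictly increasing recruitment times.

    Recruitment order is a seeded shuffle of the group labels so that the
    temporal 7:3 split downstream contains every group on both sides.
    """
    for name, n in (("n_cancer", n_cancer), ("n_healthy", n_healthy), ("n_diseased", n_diseased)):
        if n < 0:
            raise InvalidArgumentError(f"{name} must be >= 0, got {n}")
    if class_model is None:
        class_model = default_class_model()
    if site_model is None:
        site_model = default_site_model(site)

    labels = (
        ["lung_cancer"] * n_cancer
        + ["healthy_control"] * n_healthy
        + ["diseased_control"] * n_diseased
    )
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    cohort_rng = np.random.default_rng(ss.spawn(1)[0])
    order = cohort_rng.permutation(len(labels))
    trace_seeds = ss.spawn(len(labels))

    traces = []
    for rank, idx in enumerate(order):
        label = labels[idx]
        cov = _draw_covariates(label, cohort_rng)
        trace = simulate_sensor_response(
            class_model,
            site_model,
            label,
            T=T,
            seed=trace_seeds[rank],
            sample_id=f"{site}-{start_time + rank:04d}",
            site=site,
            recruitment_time=start_time + rank,
            covariates=cov,
        )
        traces.append(trace)
    return traces


def write_cohort(traces: Sequence[SensorTrace], data_path: str | Path, metadata_path: str | Path) -> None:
    """Write a cohort to the package's delimited-text layout.

    ``data_path``: long CSV with columns sample_id, channel_index (1-14),
    time_index, value. ``metadata_path``: one row per sample with site,
    label, recruitment_time and covariates (comorbidities |-joined).
    """
    data_path, metadata_path = Path(data_path), Path(metadata_path)
    with open(data_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "channel_index", "time_index", "value"])
        for tr in traces:
            for c in range(N_CHANNELS):
                for t in range(tr.n_timepoints):
                    w.writerow([tr.sample_id, c + 1, t, repr(float(tr.channels[c, t]))])
    with open(metadata_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["sample_id", "site", "label", "recruitment_time", "age", "sex",
             "smoking", "comorbidities", "histology", "stage"]
        )
        for tr in traces:
            cov = tr.covariates
            w.writerow(
                [
                    tr.sample_id, tr.site, tr.label, tr.recruitment_time,
                    cov.get("age", ""), cov.get("sex", ""), cov.get("smoking", ""),
                    "|".join(sorted(cov.get("comorbidities", set()))),
                    cov.get("histology", ""), cov.get("stage", ""),
                ]
            )
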