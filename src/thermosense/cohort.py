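"""Synthetic climate-chamber cohort generator.

Emulates a chamber study in which each subject experiences a 2x2x2 factorial
of environment settings (air temperature 23/27 degC, relative humidity 60/80 %,
ceiling-fan breeze/strong wind) while ECG (as an RR-interval series), EMG, EEG,
GSR and three skin temperatures are recorded, and a thermal sensation (TS)
vote on the 7-point scale (-3 cold .. +3 hot) is collected per trial.

The generator is phenomenological: a linear latent TS model drives each
modality through simple response functions whose directions match the
correlation structure reported for this kind of study (EMG amplitude falls
with TS, skin temperatures and EEG beta rise, tonic GSR falls, and the HRV
LF/HF ratio follows a "smile" curve, minimal at neutral TS). A corruption
process produces the quality attrition that a downstream screen must detect.

All randomness flows from one root seed through named child streams per
(trial, modality), so regenerating one modality never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

MODALITIES = (
    "ECG_RR",
    "EMG",
    "EEG",
    "GSR",
    "TEMP_CHEST",
    "TEMP_FOREARM",
    "TEMP_CALF",
)

#: modalities where broadband corruption is detectable by an out-of-band
#: power rule; EMG (in-band nearly up to Nyquist) and the RR interval series
#: are corrupted by clipping/flatline only
_BROADBAND_OK = ("EEG", "GSR", "TEMP_CHEST", "TEMP_FOREARM", "TEMP_CALF")

CORRUPTION_MODES = ("clipping", "flatline", "broadband")

# stream ids for named child RNGs (order-independent regeneration)
_STREAMS = {
    "latent": 0,
    "ECG_RR": 1,
    "EMG": 2,
    "EEG": 3,
    "GSR": 4,
    "TEMP_CHEST": 5,
    "TEMP_FOREARM": 6,
    "TEMP_CALF": 7,
    "corrupt": 8,
}


@dataclass(frozen=True)
class SubjectProfile:
    """One cohort member.

    ``thermal_offset`` is a subject-level intercept on the TS scale;
    ``signal_gain`` holds per-modality multiplicative gains (all > 0) and
    ``temp_offset`` per-site additive baseline shifts (degC), drawn
    independently per site so no pair of sites shares its inter-subject
    variation.
    """

    subject_id: str
    sex: str  # "male" | "female"
    thermal_offset: float
    signal_gain: dict
    temp_offset: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if any(g <= 0 for g in self.signal_gain.values()):
            raise ValueError("signal gains must be positive")


@dataclass(frozen=True)
class EnvironmentSetting:
    """One chamber condition of the factorial design."""

    air_temp: float  # degC
    rh: float  # % relative humidity
    fan_level: str  # "breeze" | "strong"
    wind_speed: float  # m/s

    def __post_init__(self):
        if self.fan_level not in ("breeze", "strong"):
            raise ValueError(f"unknown fan level {self.fan_level!r}")
        if self.wind_speed <= 0:
            raise ValueError("wind_speed must be positive")


@dataclass(frozen=True)
class SignalTrace:
    """A single-modality recording.

    For sampled modalities ``samples`` are instantaneous values at
    ``sampling_rate`` Hz.  For ``ECG_RR`` the samples are successive beat
    intervals in ms and ``sampling_rate`` is None.
    """

    modality: str
    samples: np.ndarray
    sampling_rate: float | None
    units: str

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.size == 0:
            raise ValueError("trace must be non-empty")
        if self.modality == "ECG_RR":
            if self.sampling_rate is not None:
                raise ValueError("RR series carries intervals, not a sampling rate")
            if np.any(self.samples <= 0):
                raise ValueError("RR intervals must be positive")
        elif self.sampling_rate is None or self.sampling_rate <= 0:
            raise ValueError("sampled modalities need sampling_rate > 0")

    @property
    def duration_s(self) -> float:
        if self.modality == "ECG_RR":
            return float(np.sum(self.samples) / 1000.0)
        return float(self.samples.size / self.sampling_rate)


@dataclass
class TrialRecord:
    """One subject-in-one-setting observation."""

    subject: SubjectProfile
    setting: EnvironmentSetting
    traces: dict  # modality -> SignalTrace
    reported_ts: int
    latent_ts: float  # simulator ground truth, never fed to models
    quality_ok: bool = True
    corrupted_modality: str | None = None


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions and response parameters of the simulator.

    Defaults reproduce the study design this package targets: 20 subjects
    (9 male : 11 female), the 23/27 degC x 60/80 %RH x breeze/strong factorial,
    15-min trials analysed over the final 5 min, and a per-trial corruption
    probability chosen so that of 160 trials about 90 survive the screen.
    """

    n_subjects: int = 20
    male_ratio: float = 9 / 20

    # latent TS model: beta_temp*(Ta-25) + beta_wind*(v-0.6) + beta_rh*(RH-70)
    # + subject offset + noise
    beta_temp: float = 0.35  # TS units per degC
    beta_wind: float = 0.7  # TS units per m/s
    beta_rh: float = -0.01  # TS units per %RH
    ref_temp: float = 25.0
    ref_wind: float = 0.6
    ref_rh: float = 70.0
    subject_offset_sd: float = 0.6
    latent_noise_sd: float = 0.8

    # fan-level -> air speed mapping (m/s)
    wind_breeze: float = 0.3
    wind_strong: float = 0.9

    # trace geometry
    duration_s: float = 900.0
    fs_emg: float = 1000.0
    fs_eeg: float = 256.0
    fs_gsr: float = 32.0
    fs_temp: float = 4.0

    # RR-interval / HRV response
    rr_mean_ms: float = 800.0
    sdnn_ms: float = 50.0
    sdnn_ts_slope: float = -2.5  # ms per TS unit (HRV shrinks away from neutral-cool)
    lfhf_c0: float = 1.2  # LF/HF at neutral TS
    lfhf_c1: float = 0.3  # smile curvature (per TS unit squared)
    rr_jitter_frac: float = 0.2  # fraction of SDNN budget spent on white jitter
    lf_hz: float = 0.10
    hf_hz: float = 0.30

    # EMG: zero-mean band-limited noise, amplitude sigma0*exp(-decay*ts) (mV)
    emg_sigma0: float = 0.05
    emg_decay: float = 0.12
    emg_trial_sigma: float = 0.2  # lognormal trial-to-trial amplitude spread

    # EEG: alpha fixed, beta gain scales with TS, broadband floor (uV)
    eeg_alpha_amp: float = 20.0
    eeg_beta_amp: float = 10.0
    eeg_beta_slope: float = 0.12  # relative beta gain per TS unit
    eeg_floor_amp: float = 5.0
    # per-trial lognormal spread of each band's gain: real band power varies
    # substantially between sessions, so relative powers are noisy too
    eeg_trial_sigma: float = 0.25

    # GSR tonic level g0 - g1*ts plus slow drift (uS)
    gsr_base: float = 4.0
    gsr_slope: float = 0.12
    gsr_drift_sd: float = 0.3
    gsr_trial_sigma: float = 0.15  # lognormal trial-to-trial tonic spread

    # skin temperature baselines (degC) and slopes (degC per TS unit)
    temp_baseline: dict = field(
        default_factory=lambda: {
            "TEMP_CHEST": 36.0,
            "TEMP_FOREARM": 33.5,
            "TEMP_CALF": 33.0,
        }
    )
    temp_slope: dict = field(
        default_factory=lambda: {
            "TEMP_CHEST": 0.10,
            "TEMP_FOREARM": 0.10,
            "TEMP_CALF": 0.15,
        }
    )
    temp_wander_sd: float = 0.05  # stationary SD of AR(1) wander
    temp_wander_phi: float = 0.995
    temp_subject_sd: float = 0.2  # per-subject per-site baseline spread
    temp_trial_jitter_sd: float = 0.1  # sensor reattachment offset per trial

    # per-modality lognormal gain spread (sigma of log-gain)
    gain_sigma: dict = field(
        default_factory=lambda: {
            "ECG_RR": 0.3,
            "EMG": 0.5,
            "EEG": 0.2,
            "GSR": 0.3,
        }
    )

    # corruption
    corruption_prob: float = 0.4375
    corruption_snr_db: float = 0.0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.latent_noise_sd < 0 or self.subject_offset_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0.0 <= self.corruption_prob <= 1.0:
            raise ValueError("corruption_prob must be in [0, 1]")
        if not 0.0 <= self.rr_jitter_frac < 1.0:
            raise ValueError("rr_jitter_frac must be in [0, 1)")

    @classmethod
    def compact(cls, **overrides) -> "GeneratorConfig":
        """Reduced trace geometry (5.5-min trials, lower sampling rates).

        Keeps every statistical property of the default cohort while cutting
        memory and runtime; the analysis window is the same 5 minutes.
        """
        base = dict(duration_s=330.0, fs_emg=250.0, fs_eeg=128.0, fs_gsr=16.0)
        base.update(overrides)
        return cls(**base)

    def wind_speed(self, fan_level: str) -> float:
        return {"breeze": self.wind_breeze, "strong": self.wind_strong}[fan_level]


DEFAULT_SETTINGS_GRID = tuple(
    (temp, rh, fan) for temp in (23.0, 27.0) for rh in (60.0, 80.0) for fan in ("breeze", "strong")
)


def _rng(seed: int, subject_idx: int, setting_idx: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), subject_idx, setting_idx, _STREAMS[stream]])
    )


def make_subjects(n_subjects: int, seed: int, config: GeneratorConfig | None = None) -> list:
    """Draw subject profiles: sex by the configured ratio, thermal offsets and
    per-modality gains from subject-level streams."""
    config = config or GeneratorConfig()
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    n_male = int(round(n_subjects * config.male_ratio))
    subjects = []
    for i in range(n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), i, 10**6]))
        sex = "male" if i < n_male else "female"
        offset = float(rng.normal(0.0, config.subject_offset_sd))
        gains = {
            m: float(np.exp(rng.normal(0.0, s))) for m, s in sorted(config.gain_sigma.items())
        }
        temp_off = {
            site: float(rng.normal(0.0, config.temp_subject_sd))
            for site in ("TEMP_CHEST", "TEMP_FOREARM", "TEMP_CALF")
        }
        subjects.append(
            SubjectProfile(
                subject_id=f"S{i + 1:02d}",
                sex=sex,
                thermal_offset=offset,
                signal_gain=gains,
                temp_offset=temp_off,
            )
        )
    return subjects


def make_design(
    n_subjects: int, seed: int, config: GeneratorConfig | None = None
) -> list:
    """Full factorial design: every subject in each of the 8 settings once,
    with the within-subject setting order shuffled by the seed."""
    config = config or GeneratorConfig()
    subjects = make_subjects(n_subjects, seed, config)
    trials = []
    for i, subj in enumerate(subjects):
        order_rng = np.random.default_rng(np.random.SeedSequence([int(seed), i, 10**6 + 1]))
        order = order_rng.permutation(len(DEFAULT_SETTINGS_GRID))
        for j in order:
            temp, rh, fan = DEFAULT_SETTINGS_GRID[j]
            setting = EnvironmentSetting(
                air_temp=temp, rh=rh, fan_level=fan, wind_speed=config.wind_speed(fan)
            )
            trials.append((subj, setting))
    return trials


def latent_ts(
    setting: EnvironmentSetting,
    subject: SubjectProfile,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[float, int]:
    """Latent TS (linear in the environment factors plus subject offset and
    Gaussian noise) and the reported vote: rounded half-away-from-zero,
    clipped to [-3, 3]."""
    for name in ("beta_temp", "beta_wind", "beta_rh"):
        if not math.isfinite(getattr(config, name)):
            raise ValueError(f"{name} must be finite")
    latent = (
        config.beta_temp * (setting.air_temp - config.ref_temp)
        + config.beta_wind * (setting.wind_speed - config.ref_wind)
        + config.beta_rh * (setting.rh - config.ref_rh)
        + subject.thermal_offset
    )
    if config.latent_noise_sd > 0:
        latent += rng.normal(0.0, config.latent_noise_sd)
    reported = int(np.clip(_round_half_away(latent), -3, 3))
    return float(latent), reported


def _round_half_away(x: float) -> float:
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


def gen_rr_series(
    ts: float, config: GeneratorConfig, rng: np.random.Generator
) -> SignalTrace:
    """RR-interval series whose spectral LF/HF ratio follows the smile curve
    c0 + c1*ts^2 and whose interval SD matches the SDNN target.

    The tachogram is two sinusoids (LF at 0.10 Hz, HF at 0.30 Hz) plus white
    jitter; the sinusoid amplitudes split the variance budget so that
    A_LF^2 / A_HF^2 equals the target band-power ratio.
    """
    if config.duration_s < 300.0:
        raise ValueError("RR generation needs duration >= 300 s")
    ratio = config.lfhf_c0 + config.lfhf_c1 * ts**2
    if ratio <= 0:
        raise ValueError(f"target LF/HF ratio {ratio:.3g} not reachable (must be > 0)")
    sdnn = config.sdnn_ms + config.sdnn_ts_slope * ts
    if sdnn < 0:
        raise ValueError("SDNN target must be >= 0 (slope drove it negative)")
    jitter_sd = config.rr_jitter_frac * sdnn
    osc_var = sdnn**2 * (1.0 - config.rr_jitter_frac**2)
    a_hf = math.sqrt(2.0 * osc_var / (1.0 + ratio))
    a_lf = math.sqrt(ratio) * a_hf
    phi_lf, phi_hf = rng.uniform(0.0, 2 * math.pi, size=2)

    intervals = []
    t = 0.0
    while t < config.duration_s:
        rr = (
            config.rr_mean_ms
            + a_lf * math.sin(2 * math.pi * config.lf_hz * t + phi_lf)
            + a_hf * math.sin(2 * math.pi * config.hf_hz * t + phi_hf)
        )
        if jitter_sd > 0:
            rr += rng.normal(0.0, jitter_sd)
        rr = max(rr, 250.0)  # physiological floor
        intervals.append(rr)
        t += rr / 1000.0
    return SignalTrace("ECG_RR", np.array(intervals), None, "ms")


def _bandpass_noise(
    n: int, fs: float, lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise."""
    x = rng.standard_normal(n)
    nyq = fs / 2.0
    hi = min(hi, 0.98 * nyq)
    sos = butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
    y = sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(y**2))
    return y / rms if rms > 0 else y


def gen_emg(
    ts: float, config: GeneratorConfig, rng: np.random.Generator, gain: float = 1.0
) -> SignalTrace:
    """Surface-EMG-like band-limited noise; amplitude decays exponentially
    with TS (more muscle tone when cold)."""
    if config.emg_sigma0 < 0:
        raise ValueError("EMG amplitude must be non-negative")
    trial_factor = math.exp(rng.normal(0.0, config.emg_trial_sigma)) \
        if config.emg_trial_sigma > 0 else 1.0
    sigma = config.emg_sigma0 * gain * trial_factor * math.exp(-config.emg_decay * ts)
    n = int(round(config.duration_s * config.fs_emg))
    x = sigma * _bandpass_noise(n, config.fs_emg, 20.0, 450.0, rng)
    return SignalTrace("EMG", x, config.fs_emg, "mV")


def gen_eeg(
    ts: float, config: GeneratorConfig, rng: np.random.Generator, gain: float = 1.0
) -> SignalTrace:
    """EEG with fixed alpha (8-13 Hz), TS-modulated beta (13-30 Hz) and a
    broadband 1-40 Hz floor."""
    if config.eeg_alpha_amp < 0 or config.eeg_beta_amp < 0:
        raise ValueError("EEG amplitudes must be non-negative")
    if config.eeg_trial_sigma > 0:
        fa, fb, ff = np.exp(rng.normal(0.0, config.eeg_trial_sigma, size=3))
    else:
        fa = fb = ff = 1.0
    beta_gain = config.eeg_beta_amp * fb * max(1.0 + config.eeg_beta_slope * ts, 0.05)
    n = int(round(config.duration_s * config.fs_eeg))
    fs = config.fs_eeg
    x = (
        config.eeg_alpha_amp * fa * _bandpass_noise(n, fs, 8.0, 13.0, rng)
        + beta_gain * _bandpass_noise(n, fs, 13.0, 30.0, rng)
        + config.eeg_floor_amp * ff * _bandpass_noise(n, fs, 1.0, 40.0, rng)
    )
    return SignalTrace("EEG", gain * x, fs, "uV")


def gen_gsr(
    ts: float, config: GeneratorConfig, rng: np.random.Generator, gain: float = 1.0
) -> SignalTrace:
    """Tonic skin conductance g0 - g1*ts plus slow (<1 Hz) drift."""
    if config.gsr_base < 0:
        raise ValueError("GSR base level must be non-negative")
    trial_factor = math.exp(rng.normal(0.0, config.gsr_trial_sigma)) \
        if config.gsr_trial_sigma > 0 else 1.0
    tonic = config.gsr_base * gain * trial_factor - config.gsr_slope * ts
    n = int(round(config.duration_s * config.fs_gsr))
    drift = config.gsr_drift_sd * _bandpass_noise(n, config.fs_gsr, 0.005, 1.0, rng)
    x = np.maximum(tonic + drift, 0.05)
    return SignalTrace("GSR", x, config.fs_gsr, "uS")


def gen_temps(
    ts: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
    temp_offset: float = 0.0,
    site: str = "TEMP_CHEST",
) -> SignalTrace:
    """Skin temperature: baseline + slope*ts + AR(1) wander.  Chest responds
    least (core-like), calf most (exposed limb)."""
    base = config.temp_baseline[site] + temp_offset
    if config.temp_trial_jitter_sd > 0:
        base += rng.normal(0.0, config.temp_trial_jitter_sd)
    slope = config.temp_slope[site]
    n = int(round(config.duration_s * config.fs_temp))
    level = base + slope * ts
    if config.temp_wander_sd > 0:
        phi = config.temp_wander_phi
        innov_sd = config.temp_wander_sd * math.sqrt(1 - phi**2)
        e = rng.normal(0.0, innov_sd, size=n)
        w = np.empty(n)
        w[0] = rng.normal(0.0, config.temp_wander_sd)
        for i in range(1, n):
            w[i] = phi * w[i - 1] + e[i]
        x = level + w
    else:
        x = np.full(n, level)
    return SignalTrace(site, x, config.fs_temp, "degC")


def corrupt(
    trace: SignalTrace,
    mode: str,
    rng: np.random.Generator,
    snr_db: float = 0.0,
) -> SignalTrace:
    """Return a damaged copy of ``trace`` that the quality screen must reject.

    clipping  -- saturate at the inner 10/90 percentiles (>=20% at the rails)
    flatline  -- second half replaced by a constant
    broadband -- add full-bandwidth white noise at ``snr_db`` dB SNR
    """
    if mode not in CORRUPTION_MODES:
        raise ValueError(f"unknown corruption mode {mode!r}; use one of {CORRUPTION_MODES}")
    x = trace.samples.copy()
    if mode == "clipping":
        lo, hi = np.percentile(x, [10.0, 90.0])
        if hi <= lo:  # degenerate (constant) trace: fabricate rails
            lo, hi = x[0] - 1.0, x[0] + 1.0
        x = np.clip(x, lo, hi)
    elif mode == "flatline":
        half = x.size // 2
        x[half:] = x[half - 1] if half > 0 else x[0]
    else:  # broadband
        sd = float(np.std(x))
        if sd == 0:
            sd = 1.0
        noise_sd = sd * 10 ** (-snr_db / 20.0)
        x = x + rng.normal(0.0, noise_sd, size=x.size)
        if trace.modality == "ECG_RR":
            x = np.maximum(x, 1.0)
    return replace(trace, samples=x)


def generate_trial(
    subject: SubjectProfile,
    subject_idx: int,
    setting: EnvironmentSetting,
    setting_idx: int,
    config: GeneratorConfig,
    seed: int,
) -> TrialRecord:
    """Generate one complete trial from named child streams."""
    lat, rep = latent_ts(
        setting, subject, config, _rng(seed, subject_idx, setting_idx, "latent")
    )
    gains = subject.signal_gain
    traces = {
        "ECG_RR": gen_rr_series(lat, _scaled(config, gains.get("ECG_RR", 1.0)),
                                _rng(seed, subject_idx, setting_idx, "ECG_RR")),
        "EMG": gen_emg(lat, config, _rng(seed, subject_idx, setting_idx, "EMG"),
                       gains.get("EMG", 1.0)),
        "EEG": gen_eeg(lat, config, _rng(seed, subject_idx, setting_idx, "EEG"),
                       gains.get("EEG", 1.0)),
        "GSR": gen_gsr(lat, config, _rng(seed, subject_idx, setting_idx, "GSR"),
                       gains.get("GSR", 1.0)),
    }
    for site in ("TEMP_CHEST", "TEMP_FOREARM", "TEMP_CALF"):
        traces[site] = gen_temps(
            lat, config, _rng(seed, subject_idx, setting_idx, site),
            subject.temp_offset.get(site, 0.0), site,
        )
    record = TrialRecord(
        subject=subject,
        setting=setting,
        traces=traces,
        reported_ts=rep,
        latent_ts=lat,
        quality_ok=True,
    )
    crng = _rng(seed, subject_idx, setting_idx, "corrupt")
    if crng.uniform() < config.corruption_prob:
        modality = str(crng.choice(MODALITIES))
        modes = CORRUPTION_MODES if modality in _BROADBAND_OK else CORRUPTION_MODES[:2]
        mode = str(crng.choice(modes))
        record.traces[modality] = corrupt(
            record.traces[modality], mode, crng, config.corruption_snr_db
        )
        record.quality_ok = False
        record.corrupted_modality = modality
    return record


def _scaled(config: GeneratorConfig, sdnn_gain: float) -> GeneratorConfig:
    """Apply a subject's HRV gain to the SDNN target."""
    if sdnn_gain == 1.0:
        return config
    return replace(
        config,
        sdnn_ms=config.sdnn_ms * sdnn_gain,
        sdnn_ts_slope=config.sdnn_ts_slope * sdnn_gain,
    )


def generate_cohort(config: GeneratorConfig, seed: int) -> list:
    """Full factorial cohort with per-trial corruption.

    A corrupted modality voids the whole trial (``quality_ok=False``),
    mirroring how one impaired channel removes the sample from analysis.
    """
    subjects = make_subjects(config.n_subjects, seed, config)
    cohort = []
    for i, subj in enumerate(subjects):
        order_rng = np.random.default_rng(np.random.SeedSequence([int(seed), i, 10**6 + 1]))
        order = order_rng.permutation(len(DEFAULT_SETTINGS_GRID))
        for j in order:
            temp, rh, fan = DEFAULT_SETTINGS_GRID[j]
            setting = EnvironmentSetting(
                air_temp=temp, rh=rh, fan_level=fan, wind_speed=config.wind_speed(fan)
            )
            cohort.append(generate_trial(subj, i, setting, int(j), config, seed))
    return cohort
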