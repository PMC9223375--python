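"""Windowed feature extraction and trial quality screening.

Computes the 22-feature vector used for thermal-sensation modelling:

* ECG/HRV: heart rate, SDNN, total spectral power of the RR tachogram,
  relative LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz) power and their ratio;
* EMG time-domain amplitude: IEMG, MAV, RMS, SSI;
* EEG: alpha/beta band mean absolute amplitude, broadband mean absolute
  amplitude, and relative alpha/beta band power;
* GSR: mean of the low-pass (<5 Hz) filtered signal;
* mean skin temperature at chest, forearm and calf;
* the three environment factors (air temperature, air speed, RH).

All features are computed on the trailing analysis window (default the final
5 minutes of a trial).  Degenerate spectral quantities (e.g. a constant RR
series) come back as NaN with a warning rather than an exception, so a trial
with one dead derived quantity keeps its remaining features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.integrate import trapezoid
from scipy.signal import butter, periodogram, sosfiltfilt, welch

from .cohort import MODALITIES, SignalTrace, TrialRecord

#: canonical feature order of the extracted vector
FEATURE_NAMES = (
    "ECG_HR",
    "ECG_SDNN",
    "ECG_TP",
    "ECG_LF",
    "ECG_HF",
    "ECG_LF/HF",
    "EMG_IEMG",
    "EMG_MAV",
    "EMG_RMS",
    "EMG_SSI",
    "EEG_alpha",
    "EEG_beta",
    "EEG_AVG",
    "EEG_alpha_power",
    "EEG_beta_power",
    "GSR_avg5hz",
    "T1_chest",
    "T2_forearm",
    "T3_calf",
    "EnvTemp",
    "EnvWind",
    "EnvRH",
)

#: feature names grouped by source signal (used by the signal-ranking report)
SIGNAL_GROUPS = {
    "ECG": ("ECG_HR", "ECG_SDNN", "ECG_TP", "ECG_LF", "ECG_HF", "ECG_LF/HF"),
    "EMG": ("EMG_IEMG", "EMG_MAV", "EMG_RMS", "EMG_SSI"),
    "EEG": ("EEG_alpha", "EEG_beta", "EEG_AVG", "EEG_alpha_power", "EEG_beta_power"),
    "GSR": ("GSR_avg5hz",),
    "BodyTemp": ("T1_chest", "T2_forearm", "T3_calf"),
    "Environment": ("EnvTemp", "EnvWind", "EnvRH"),
}


@dataclass(frozen=True)
class ExtractionConfig:
    """Band edges, window geometry and PSD parameters.

    EEG band edges follow clinical convention (alpha 8-13 Hz, beta 13-30 Hz,
    broadband 1-40 Hz).  The HRV total band is 0.003-0.4 Hz so the LF and HF
    relative powers share a denominator without trivially summing to one.
    """

    window_s: float = 300.0
    trim_s: float = 1.0  # filter edge transient discarded each side
    filter_order: int = 4

    emg_band: tuple | None = (20.0, 450.0)
    eeg_alpha: tuple = (8.0, 13.0)
    eeg_beta: tuple = (13.0, 30.0)
    eeg_broad: tuple = (1.0, 40.0)
    gsr_cutoff: float = 5.0

    hrv_total: tuple = (0.003, 0.4)
    hrv_lf: tuple = (0.04, 0.15)
    hrv_hf: tuple = (0.15, 0.4)
    hrv_resample_hz: float = 4.0
    hrv_segment_s: float = 120.0
    min_intervals: int = 30

    def __post_init__(self):
        for name in ("eeg_alpha", "eeg_beta", "eeg_broad", "hrv_total", "hrv_lf", "hrv_hf"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} edges must be strictly increasing, got ({lo}, {hi})")
        if self.emg_band is not None and not self.emg_band[0] < self.emg_band[1]:
            raise ValueError("emg_band edges must be strictly increasing")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")


@dataclass(frozen=True)
class QualityThresholds:
    flatline_var_floor: float = 1e-12
    # half-window flatlines quantize to just under 0.5 in whole chunks
    flatline_fraction: float = 0.45
    clip_rail_tol: float = 1e-3  # fraction of the value range counted as "at rail"
    clip_fraction: float = 0.10
    snr_out_in_ratio: float = 0.15
    chunk_s: float = 1.0


@dataclass
class QualityReport:
    """Per-modality verdicts with reason codes; the trial passes iff every
    modality passes."""

    modality_pass: dict
    reasons: dict  # modality -> list of {"flatline","clipping","low_snr"}

    @property
    def trial_pass(self) -> bool:
        return all(self.modality_pass.values())


def _window(trace: SignalTrace, window_s: float) -> np.ndarray:
    """Trailing analysis window of a sampled trace."""
    n = int(round(window_s * trace.sampling_rate))
    if n <= 0 or n > trace.samples.size:
        raise ValueError(
            f"window of {window_s} s not extractable from {trace.modality} trace "
            f"of {trace.duration_s:.1f} s"
        )
    return trace.samples[-n:]


def _sos(order, edges, fs, btype):
    nyq = fs / 2.0
    if np.isscalar(edges):
        wn = edges / nyq
    else:
        wn = [e / nyq for e in edges]
    return butter(order, wn, btype=btype, output="sos")


def _filtered_window(trace, config, edges, btype):
    x = _window(trace, config.window_s + 2 * config.trim_s)
    y = sosfiltfilt(_sos(config.filter_order, edges, trace.sampling_rate, btype), x)
    k = int(round(config.trim_s * trace.sampling_rate))
    return y[k: y.size - k] if k > 0 else y


def emg_features(trace: SignalTrace, config: ExtractionConfig) -> tuple:
    """IEMG, MAV, RMS, SSI on the high-pass (or band-pass) filtered window.

    With ``emg_band=None`` the filter is bypassed and the statistics are the
    textbook formulas on the raw window.
    """
    if trace.modality != "EMG":
        raise ValueError(f"expected EMG trace, got {trace.modality}")
    if config.emg_band is None:
        x = _window(trace, min(config.window_s, trace.duration_s))
    else:
        lo, hi = config.emg_band
        nyq = trace.sampling_rate / 2.0
        if hi < 0.95 * nyq:
            x = _filtered_window(trace, config, (lo, hi), "band")
        else:
            x = _filtered_window(trace, config, lo, "high")
    if x.size == 0:
        raise ValueError("empty EMG window")
    iemg = float(np.sum(np.abs(x)))
    mav = iemg / x.size
    ssi = float(np.sum(x**2))
    rms = float(np.sqrt(ssi / x.size))
    return iemg, mav, rms, ssi


def hrv_features(rr: SignalTrace, config: ExtractionConfig) -> tuple:
    """HR, SDNN and spectral HRV measures of the trailing window.

    The tachogram is cubic-spline resampled to an even grid, mean-detrended,
    and its PSD estimated by an averaged periodogram (Welch, 120-s segments,
    50% overlap).  Band powers are integrated over the configured LF/HF/total
    bands; relative powers are referred to the total band.
    """
    if rr.modality != "ECG_RR":
        raise ValueError(f"expected an RR-interval series, got {rr.modality}")
    t = np.cumsum(rr.samples) / 1000.0
    mask = t > t[-1] - config.window_s
    intervals = rr.samples[mask]
    times = t[mask]
    if intervals.size < config.min_intervals:
        raise ValueError(
            f"need >= {config.min_intervals} intervals in window, got {intervals.size}"
        )
    hr = 60000.0 / float(np.mean(intervals))
    sdnn = float(np.std(intervals, ddof=1))

    fs = config.hrv_resample_hz
    grid = np.arange(times[0], times[-1], 1.0 / fs)
    if np.ptp(intervals) == 0.0:
        warnings.warn("constant RR series: spectral HRV features degenerate")
        return hr, sdnn, np.nan, np.nan, np.nan, np.nan
    tach = CubicSpline(times, intervals)(grid)
    tach = tach - np.mean(tach)
    nperseg = min(tach.size, int(config.hrv_segment_s * fs))
    f, psd = welch(tach, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)

    def band_power(lo, hi):
        m = (f >= lo) & (f <= hi)
        return float(trapezoid(psd[m], f[m])) if m.sum() > 1 else 0.0

    tp = band_power(*config.hrv_total)
    lf = band_power(*config.hrv_lf)
    hf = band_power(*config.hrv_hf)
    if tp <= 0 or hf <= 0:
        warnings.warn("zero HRV band power: relative powers/ratio degenerate")
        return hr, sdnn, tp, np.nan, np.nan, np.nan
    return hr, sdnn, tp, lf / tp, hf / tp, lf / hf


def eeg_features(trace: SignalTrace, config: ExtractionConfig) -> tuple:
    """Alpha/beta mean absolute amplitude, broadband mean absolute amplitude,
    and relative alpha/beta band power (Welch PSD over the broadband range)."""
    if trace.modality != "EEG":
        raise ValueError(f"expected EEG trace, got {trace.modality}")
    if trace.sampling_rate < 2 * config.eeg_broad[1]:
        raise ValueError(
            f"EEG sampling rate {trace.sampling_rate} Hz below Nyquist for "
            f"{config.eeg_broad[1]} Hz band edge"
        )
    alpha = _filtered_window(trace, config, config.eeg_alpha, "band")
    beta = _filtered_window(trace, config, config.eeg_beta, "band")
    broad = _filtered_window(trace, config, config.eeg_broad, "band")
    alpha_avg = float(np.mean(np.abs(alpha)))
    beta_avg = float(np.mean(np.abs(beta)))
    eeg_avg = float(np.mean(np.abs(broad)))

    x = _window(trace, config.window_s)
    x = x - np.mean(x)
    if np.ptp(x) == 0.0:
        warnings.warn("constant EEG window: relative band powers degenerate")
        return alpha_avg, beta_avg, eeg_avg, np.nan, np.nan
    fs = trace.sampling_rate
    nperseg = min(x.size, int(4.0 * fs))
    f, psd = welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)

    def band_power(lo, hi):
        m = (f >= lo) & (f <= hi)
        return float(trapezoid(psd[m], f[m])) if m.sum() > 1 else 0.0

    total = band_power(*config.eeg_broad)
    if total <= 0:
        warnings.warn("zero EEG broadband power: relative band powers degenerate")
        return alpha_avg, beta_avg, eeg_avg, np.nan, np.nan
    return (
        alpha_avg,
        beta_avg,
        eeg_avg,
        band_power(*config.eeg_alpha) / total,
        band_power(*config.eeg_beta) / total,
    )


def gsr_feature(trace: SignalTrace, config: ExtractionConfig) -> float:
    """Mean of the window after 5 Hz low-pass filtering (skipped when the
    sampling rate is already too low to carry content above the cutoff)."""
    if trace.modality != "GSR":
        raise ValueError(f"expected GSR trace, got {trace.modality}")
    if trace.sampling_rate > 2.5 * config.gsr_cutoff:
        x = _filtered_window(trace, config, config.gsr_cutoff, "low")
    else:
        x = _window(trace, min(config.window_s, trace.duration_s))
    if x.size == 0:
        raise ValueError("empty GSR window")
    return float(np.mean(x))


def temp_and_env_features(record: TrialRecord, config: ExtractionConfig) -> tuple:
    """Mean skin temperatures over the window plus the trial's environment
    means (air temperature degC, air speed m/s, RH %)."""
    means = []
    for site in ("TEMP_CHEST", "TEMP_FOREARM", "TEMP_CALF"):
        if site not in record.traces:
            raise ValueError(f"missing modality {site}")
        trace = record.traces[site]
        means.append(float(np.mean(_window(trace, min(config.window_s, trace.duration_s)))))
    s = record.setting
    return (*means, s.air_temp, s.wind_speed, s.rh)


# ---------------------------------------------------------------------------
# quality screening

#: in-band frequency range (Hz) used by the out-of-band power check.  EMG is
#: absent deliberately: its physiological band reaches nearly to Nyquist, so
#: an out-of-band rule is uninformative; EMG damage is caught by the
#: clipping/flatline checks instead.
_SNR_BANDS = {
    "EEG": (1.0, 40.0),
    "GSR": (0.0, 5.0),
    "TEMP_CHEST": (0.0, 0.2),
    "TEMP_FOREARM": (0.0, 0.2),
    "TEMP_CALF": (0.0, 0.2),
}


def _check_flatline(x: np.ndarray, chunk: int, th: QualityThresholds) -> bool:
    if chunk < 2:
        chunk = 2
    n_chunks = x.size // chunk
    if n_chunks == 0:
        return bool(np.var(x) < th.flatline_var_floor)
    v = x[: n_chunks * chunk].reshape(n_chunks, chunk).var(axis=1)
    return bool(np.mean(v < th.flatline_var_floor) >= th.flatline_fraction)


def _check_clipping(x: np.ndarray, th: QualityThresholds) -> bool:
    rng = float(np.ptp(x))
    if rng == 0.0:
        return False  # constant trace is the flatline check's business
    tol = th.clip_rail_tol * rng
    at_rail = (np.abs(x - x.min()) <= tol) | (np.abs(x - x.max()) <= tol)
    return bool(np.mean(at_rail) >= th.clip_fraction)


def _check_low_snr(x: np.ndarray, fs: float, modality: str, th: QualityThresholds) -> bool:
    if modality not in _SNR_BANDS:
        return False
    lo, hi = _SNR_BANDS[modality]
    f, psd = periodogram(x - np.mean(x), fs=fs)
    inb = (f >= lo) & (f <= hi)
    p_in = float(np.sum(psd[inb & (f > 0)]))
    p_out = float(np.sum(psd[~inb & (f > 0)]))
    if p_in <= 0:
        return p_out > 0
    return p_out / p_in > th.snr_out_in_ratio


def quality_screen(
    record: TrialRecord,
    thresholds: QualityThresholds | None = None,
    window_s: float = 300.0,
) -> QualityReport:
    """Screen every modality for flatline segments, rail clipping and
    out-of-band (broadband-noise) contamination; any failing modality fails
    the whole trial."""
    th = thresholds or QualityThresholds()
    passes, reasons = {}, {}
    for modality in MODALITIES:
        if modality not in record.traces:
            passes[modality] = False
            reasons[modality] = ["missing"]
            continue
        trace = record.traces[modality]
        codes = []
        if modality == "ECG_RR":
            x = trace.samples
            chunk = 10
            fs = None
        else:
            x = _window(trace, min(window_s, trace.duration_s))
            fs = trace.sampling_rate
            chunk = int(round(th.chunk_s * fs))
        if _check_flatline(x, chunk, th):
            codes.append("flatline")
        if _check_clipping(x, th):
            codes.append("clipping")
        if fs is not None and _check_low_snr(x, fs, modality, th):
            codes.append("low_snr")
        passes[modality] = not codes
        reasons[modality] = codes
    return QualityReport(modality_pass=passes, reasons=reasons)


# ---------------------------------------------------------------------------
# assembly

def extract(
    record: TrialRecord,
    config: ExtractionConfig | None = None,
    override_quality: bool = False,
    quality: QualityReport | None = None,
) -> pd.Series:
    """Assemble the full 22-feature vector for one passing trial.

    Refuses trials that fail the quality screen unless ``override_quality``
    is set; a pre-computed :class:`QualityReport` can be passed to avoid
    re-screening.
    """
    config = config or ExtractionConfig()
    report = quality or quality_screen(record, window_s=config.window_s)
    if not report.trial_pass and not override_quality:
        bad = {m: r for m, r in report.reasons.items() if r}
        raise ValueError(f"trial failed quality screen: {bad}; pass override_quality=True to force")

    hr, sdnn, tp, lf, hf, lfhf = hrv_features(record.traces["ECG_RR"], config)
    iemg, mav, rms, ssi = emg_features(record.traces["EMG"], config)
    a_avg, b_avg, eeg_avg, a_pow, b_pow = eeg_features(record.traces["EEG"], config)
    gsr = gsr_feature(record.traces["GSR"], config)
    t1, t2, t3, env_t, env_w, env_rh = temp_and_env_features(record, config)
    values = (
        hr, sdnn, tp, lf, hf, lfhf,
        iemg, mav, rms, ssi,
        a_avg, b_avg, eeg_avg, a_pow, b_pow,
        gsr, t1, t2, t3, env_t, env_w, env_rh,
    )
    return pd.Series(values, index=list(FEATURE_NAMES), dtype=float)


def build_feature_table(
    cohort: list,
    config: ExtractionConfig | None = None,
    screen: bool = True,
) -> pd.DataFrame:
    """Feature table over the quality-passing trials of a cohort.

    Columns: subject_id, sex, reported_ts followed by the 22 features.
    With ``screen=False`` the generator's own quality flags are trusted
    instead of re-screening (useful for speed in simulations).
    """
    config = config or ExtractionConfig()
    rows = []
    for record in cohort:
        if screen:
            report = quality_screen(record, window_s=config.window_s)
            if not report.trial_pass:
                continue
        elif not record.quality_ok:
            continue
        vec = extract(record, config, override_quality=True)
        meta = pd.Series(
            {
                "subject_id": record.subject.subject_id,
                "sex": record.subject.sex,
                "reported_ts": record.reported_ts,
            }
        )
        rows.append(pd.concat([meta, vec]))
    if not rows:
        raise ValueError("no passing trials")
    table = pd.DataFrame(rows).reset_index(drop=True)
    table["reported_ts"] = table["reported_ts"].astype(int)
    return table
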