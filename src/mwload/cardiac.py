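"""Cardiac processing: R-peak and pulse detection, time- and
frequency-domain heart-rate variability, pulse morphology.

ECG beats are found with a Pan-Tompkins-style chain (band-pass,
derivative, squaring, moving-window integration, adaptive threshold
with a 250 ms refractory period) followed by a deterministic
median-deviation correction that replaces manual editing.  PPG pulses
use an order-7 0.1-10 Hz Butterworth band-pass and prominence-based
peak picking with a minimum distance of 0.6 x the running median
inter-pulse interval.  HRV measures: heart rate, SDNN, RMSSD, and
Welch spectra of the 4 Hz-resampled tachogram integrated over
LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz), absolute and relative
(normalised to LF+HF), plus the LF/HF ratio — 8 ECG measures; PPG adds
mean pulse width and mean pulse amplitude for 10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal as sps

from .config import CardiacConfig
from .types import BeatSeries, BlockDesign, Recording, feature_rows

ECG_MEASURES = (
    "heartrate", "hrv_sd", "hrv_rms",
    "lf_abs", "lf_rel", "hf_abs", "hf_rel", "lf_hf",
)
PPG_EXTRA_MEASURES = ("mean_width", "mean_peak")


@dataclass
class PulseMorphology:
    mean_width_s: float  # full width at half prominence
    mean_peak_amplitude: float


def detect_rpeaks(ecg: Recording, cfg: CardiacConfig | None = None) -> BeatSeries:
    """Pan-Tompkins-style R-peak detection with automated interval
    correction (intervals deviating >30% from the running median are
    removed or merged and flagged)."""
    cfg = cfg or CardiacConfig()
    fs = ecg.sample_rate_hz
    if fs < 100:
        raise ValueError("ECG sample rate must be >= 100 Hz")
    x = ecg.samples[0]
    if np.ptp(x) == 0 or np.std(x) == 0:
        warnings.warn("flat ECG signal: no beats detected")
        return BeatSeries(np.zeros(0), source="ecg")

    sos = sps.butter(3, [5.0, 30.0], btype="bandpass", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(band) * fs
    squared = deriv**2
    w = max(int(round(0.12 * fs)), 1)
    integ = np.convolve(squared, np.ones(w) / w, mode="same")

    thr = 0.25 * np.quantile(integ, 0.99)
    refractory = int(round(0.25 * fs))
    peaks, _ = sps.find_peaks(integ, height=thr, distance=refractory)
    if peaks.size == 0:
        warnings.warn("no QRS complexes found")
        return BeatSeries(np.zeros(0), source="ecg")

    # refine each detection to the local band-passed R maximum
    half = int(round(0.06 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, x.size)
        refined.append(lo + int(np.argmax(band[lo:hi])))
    refined = np.unique(refined)
    times = ecg.t0_s + refined / fs

    return _correct_intervals(times, "ecg", cfg)


def _correct_intervals(
    times: np.ndarray, source: str, cfg: CardiacConfig
) -> BeatSeries:
    """Median-deviation rules standing in for manual beat editing:
    an interval shorter than (1 - dev) x running median deletes the
    later beat (double detection); remaining out-of-range intervals are
    flagged."""
    times = np.sort(np.asarray(times, dtype=float))
    if times.size < 3:
        return BeatSeries(times, source=source)
    dev = cfg.rr_deviation_frac
    keep = [times[0]]
    recent: list[float] = []
    for t in times[1:]:
        rr = (t - keep[-1]) * 1000.0
        med = np.median(recent[-11:]) if len(recent) >= 3 else None
        if med is not None and rr < (1 - dev) * med:
            continue  # spurious double detection inside the beat
        if rr < cfg.rr_min_ms:
            continue
        keep.append(t)
        recent.append(rr)
    keep = np.asarray(keep)
    rr = np.diff(keep) * 1000.0
    flags = np.zeros(rr.size, dtype=bool)
    if rr.size >= 3:
        med = np.median(rr)
        flags = (np.abs(rr - med) > dev * med) | (rr > cfg.rr_max_ms)
    return BeatSeries(keep, source=source, corrected_flags=flags)


def rr_time_metrics(beats: BeatSeries) -> dict[str, float]:
    """Heart rate (bpm), SDNN (ms) and RMSSD (ms) from the RR series."""
    rr = beats.rr_ms
    if beats.n_beats < 3:
        return {"heartrate": float("nan"), "hrv_sd": float("nan"),
                "hrv_rms": float("nan")}
    return {
        "heartrate": float(60000.0 / np.mean(rr)),
        "hrv_sd": float(np.std(rr, ddof=1)),
        "hrv_rms": float(np.sqrt(np.mean(np.diff(rr) ** 2))),
    }


def rr_spectrum(
    beats: BeatSeries, cfg: CardiacConfig | None = None
) -> dict[str, float]:
    """Frequency-domain HRV from the cubic-interpolated 4 Hz tachogram.

    LF = 0.04-0.15 Hz, HF = 0.15-0.4 Hz (ms^2, absolute); relative
    powers are normalised to LF+HF so lf_rel + hf_rel = 1; lf_hf is
    their ratio.  Spans under 120 s are flagged (``reliable`` False)
    because LF cannot be resolved.
    """
    cfg = cfg or CardiacConfig()
    out = {k: float("nan") for k in
           ("lf_abs", "lf_rel", "hf_abs", "hf_rel", "lf_hf")}
    out["reliable"] = False
    if beats.n_beats < 5:
        return out
    t = beats.event_times_s[1:]
    rr = beats.rr_ms
    span = t[-1] - t[0]
    out["reliable"] = bool(span >= 120.0)
    if span < 20.0:
        return out
    fs = cfg.tachogram_rate_hz
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    tach = interpolate.CubicSpline(t, rr)(grid)
    tach = sps.detrend(tach)
    nper = min(int(fs * 120), tach.size)
    f, psd = sps.welch(tach, fs=fs, nperseg=nper)
    df = f[1] - f[0]
    lf = float(psd[(f >= cfg.hrv_lf_lo_hz) & (f < cfg.hrv_lf_hi_hz)].sum() * df)
    hf = float(psd[(f >= cfg.hrv_hf_lo_hz) & (f < cfg.hrv_hf_hi_hz)].sum() * df)
    out["lf_abs"], out["hf_abs"] = lf, hf
    tot = lf + hf
    if tot > 0:
        out["lf_rel"] = lf / tot
        out["hf_rel"] = hf / tot
    if hf > 0:
        out["lf_hf"] = lf / hf
    return out


def detect_pulses(
    ppg: Recording, cfg: CardiacConfig | None = None
) -> tuple[BeatSeries, PulseMorphology]:
    """PPG pulse detection and morphology.

    Band-pass 0.1-10 Hz (order 7), then peak picking with a minimum
    prominence and a minimum distance of 0.6 x the running median
    inter-pulse interval — the false-peak correction that keeps
    dicrotic notches from being counted.  Morphology: mean full width
    at half prominence (s) and mean peak amplitude.
    """
    cfg = cfg or CardiacConfig()
    fs = ppg.sample_rate_hz
    if fs < 25:
        raise ValueError("PPG sample rate must be >= 25 Hz")
    x = ppg.samples[0]
    if np.ptp(x) == 0:
        warnings.warn("flat PPG signal: no pulses detected")
        return (
            BeatSeries(np.zeros(0), source="ppg"),
            PulseMorphology(float("nan"), float("nan")),
        )
    hi = min(cfg.ppg_bandpass_hi_hz, 0.45 * fs)
    sos = sps.butter(cfg.ppg_bandpass_order, [cfg.ppg_bandpass_lo_hz, hi],
                     btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, x)
    min_prom = 0.3 * np.quantile(np.abs(filt), 0.95)

    # first pass to estimate the typical inter-pulse interval
    p0, _ = sps.find_peaks(filt, prominence=min_prom,
                           distance=max(int(0.3 * fs), 1))
    if p0.size < 2:
        warnings.warn("no pulses found")
        return (
            BeatSeries(np.zeros(0), source="ppg"),
            PulseMorphology(float("nan"), float("nan")),
        )
    med_ipi = np.median(np.diff(p0))
    peaks, props = sps.find_peaks(
        filt, prominence=min_prom, distance=max(int(0.6 * med_ipi), 1)
    )
    widths = sps.peak_widths(filt, peaks, rel_height=0.5)[0] / fs
    morph = PulseMorphology(
        mean_width_s=float(np.mean(widths)),
        mean_peak_amplitude=float(np.mean(props["prominences"])),
    )
    times = ppg.t0_s + peaks / fs
    return _correct_intervals(times, "ppg", cfg), morph


def _interval_measures(
    beats: BeatSeries, interval: tuple[float, float], cfg: CardiacConfig
) -> dict[str, float]:
    sub = beats.within(*interval)
    out = rr_time_metrics(sub)
    spec = rr_spectrum(sub, cfg)
    spec.pop("reliable", None)
    out.update(spec)
    return out


def process(
    ecg: Recording | None,
    ppg: Recording | None,
    design: list[BlockDesign],
    cfg: CardiacConfig | None = None,
    per_block: bool = True,
) -> list[dict]:
    """Cardiac features for one task-session.

    By default measures are computed per block interval; spectral HRV
    on short blocks is numerically defined but flagged unreliable by
    :func:`rr_spectrum` (LF needs >= 120 s).  ``per_block=False``
    computes every measure once over the whole task span instead.
    """
    cfg = cfg or CardiacConfig()
    rows: list[dict] = []
    task_span = (min(b.t_start_s for b in design), max(b.t_end_s for b in design))
    for rec, source in ((ecg, "ecg"), (ppg, "ppg")):
        if rec is None:
            continue
        if source == "ecg":
            beats = detect_rpeaks(rec, cfg)
            morph = None
        else:
            beats, morph = detect_pulses(rec, cfg)
        for block in design:
            interval = block.interval if per_block else task_span
            vals = _interval_measures(beats, interval, cfg)
            named = {f"{source}.{k}": v for k, v in vals.items()}
            if morph is not None:
                named[f"{source}.mean_width"] = morph.mean_width_s
                named[f"{source}.mean_peak"] = morph.mean_peak_amplitude
            rows += feature_rows(block, source, named)
    return rows
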