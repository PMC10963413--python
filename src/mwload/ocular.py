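"""Ocular processing: EOG saccade detection, gaze fixation/saccade
segmentation, and pupil features.

EOG saccades follow an adaptive acceleration-threshold scheme: the
horizontal/vertical channels are scaled to degrees by the calibration
constant, Savitzky-Golay smoothed (~20 ms), differentiated centrally,
and an event is a pair of opposite-sign acceleration peaks exceeding
k x the trailing acceleration SD within 100 ms; events closer than
80 ms are merged.  Gaze fixations use the dispersion-threshold (I-DT)
algorithm; the gaze shifts between fixations are emitted as
gaze-source saccades.  Block features: 3 EOG measures (mean peak
velocity, duration, amplitude) and 7 eye-tracking measures (pupil
diameter, saccade velocity, saccade length, fixation count, mean
fixation duration, fixation rate, fixation/saccade time ratio).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import OcularConfig
from .types import BlockDesign, FixationEvent, Recording, SaccadeEvent, feature_rows

EOG_MEASURES = ("peak_velocity_mean", "duration_mean", "amplitude_mean")
GAZE_MEASURES = (
    "pupil_diameter_mean", "saccade_velocity_mean", "saccade_length_mean",
    "fixation_count", "fixation_duration_mean", "fixation_rate_per_s",
    "fixation_saccade_ratio",
)


def detect_saccades_eog(
    eog_h: Recording,
    eog_v: Recording,
    calib_deg_per_uv: float | None = None,
    cfg: OcularConfig | None = None,
) -> list[SaccadeEvent]:
    """Adaptive acceleration-threshold saccade detection on 2-D EOG."""
    cfg = cfg or OcularConfig()
    if calib_deg_per_uv is None:
        calib_deg_per_uv = 1.0 / cfg.eog_uv_per_deg
    if calib_deg_per_uv <= 0:
        raise ValueError("calibration constant must be positive")
    if eog_h.n_samples != eog_v.n_samples:
        raise ValueError("EOG channels must be synchronized")
    fs = eog_h.sample_rate_hz
    pos = np.vstack([eog_h.samples[0], eog_v.samples[0]]) * calib_deg_per_uv

    # skip NaN/saturated spans (interpolate over them, log)
    bad = ~np.isfinite(pos).all(axis=0)
    if bad.any():
        warnings.warn(f"EOG: {int(bad.sum())} non-finite samples interpolated")
        idx = np.arange(pos.shape[1])
        for d in range(2):
            good = np.isfinite(pos[d])
            pos[d] = np.interp(idx, idx[good], pos[d, good])

    win = max(int(round(cfg.sg_window_ms / 1000.0 * fs)) | 1, 5)
    smooth = sps.savgol_filter(pos, win, polyorder=3, axis=1)
    vel = np.gradient(smooth, axis=1) * fs  # deg/s per axis
    speed = np.linalg.norm(vel, axis=0)
    # smooth the speed trace before differentiating: acceleration is a
    # second derivative and would otherwise be noise-dominated
    speed_s = sps.savgol_filter(speed, win, polyorder=2)
    accel = np.gradient(speed_s) * fs

    # trailing-window noise SD of acceleration -> adaptive threshold.
    # A robust (median-based) scale keeps the sparse, huge saccadic
    # accelerations themselves from inflating the threshold.
    import pandas as pd

    w = max(int(round(cfg.accel_sd_window_s * fs)), 10)
    med_abs = (
        pd.Series(np.abs(accel))
        .rolling(w, min_periods=10)
        .median()
        .bfill()
        .to_numpy()
    )
    sd = 1.4826 * np.maximum(med_abs, 1e-9)
    thr = cfg.accel_threshold_k * sd

    above = np.abs(accel) > thr
    peaks, _ = sps.find_peaks(np.abs(accel) * above)
    peaks = peaks[np.abs(accel[peaks]) > thr[peaks]]

    max_gap = int(round(cfg.pair_max_gap_ms / 1000.0 * fs))
    events: list[SaccadeEvent] = []
    i = 0
    while i < len(peaks) - 1:
        p0 = peaks[i]
        if accel[p0] <= 0:  # onset must be an acceleration (positive) peak
            i += 1
            continue
        # find the matching deceleration peak within the allowed gap
        j = i + 1
        found = None
        while j < len(peaks) and peaks[j] - p0 <= max_gap:
            if accel[peaks[j]] < 0:
                found = j
            j += 1
        if found is None:
            i += 1
            continue
        p1 = peaks[found]
        onset = max(p0 - 2, 0)
        offset = min(p1 + 2, pos.shape[1] - 1)
        amp_vec = smooth[:, offset] - smooth[:, onset]
        amp = float(np.linalg.norm(amp_vec))
        dur_ms = (offset - onset) / fs * 1000.0
        pv = float(speed[onset: offset + 1].max())
        if amp >= 0.3 and dur_ms >= 6.0:
            events.append(
                SaccadeEvent(
                    onset_s=eog_h.t0_s + onset / fs,
                    duration_ms=dur_ms,
                    amplitude_deg=amp,
                    peak_velocity_deg_s=pv,
                    source="eog",
                )
            )
        i = found + 1

    return _merge_close(events, cfg.merge_gap_ms)


def _merge_close(events: list[SaccadeEvent], gap_ms: float) -> list[SaccadeEvent]:
    """Merge events whose onsets are closer than gap_ms (keep one span)."""
    if not events:
        return events
    events = sorted(events, key=lambda e: e.onset_s)
    out = [events[0]]
    for e in events[1:]:
        prev = out[-1]
        if (e.onset_s - prev.onset_s) * 1000.0 < gap_ms:
            end = max(
                prev.onset_s + prev.duration_ms / 1000.0,
                e.onset_s + e.duration_ms / 1000.0,
            )
            out[-1] = SaccadeEvent(
                onset_s=prev.onset_s,
                duration_ms=(end - prev.onset_s) * 1000.0,
                amplitude_deg=max(prev.amplitude_deg, e.amplitude_deg),
                peak_velocity_deg_s=max(
                    prev.peak_velocity_deg_s, e.peak_velocity_deg_s
                ),
                source=prev.source,
            )
        else:
            out.append(e)
    return out


def saccade_block_features(
    events: list[SaccadeEvent], interval: tuple[float, float]
) -> dict[str, float]:
    """Arithmetic means of peak velocity, duration and amplitude over the
    events whose onset falls in ``interval``; empty -> NaNs."""
    t0, t1 = interval
    sel = [e for e in events if t0 <= e.onset_s < t1]
    if not sel:
        return {k: float("nan") for k in EOG_MEASURES}
    return {
        "peak_velocity_mean": float(
            np.mean([e.peak_velocity_deg_s for e in sel])
        ),
        "duration_mean": float(np.mean([e.duration_ms for e in sel])),
        "amplitude_mean": float(np.mean([e.amplitude_deg for e in sel])),
    }


def detect_fixations(
    gaze: Recording,
    dispersion_deg: float = 1.0,
    min_duration_ms: float = 100.0,
) -> tuple[list[FixationEvent], list[SaccadeEvent]]:
    """Dispersion-threshold (I-DT) fixation detection.

    A window grows while its dispersion (max x-range + max y-range over
    the window) stays within the threshold; windows at least
    ``min_duration_ms`` long become fixations.  Gaze shifts between
    consecutive fixations are emitted as gaze-source saccades with
    amplitude equal to the centroid distance.
    """
    fs = gaze.sample_rate_hz
    x = gaze.samples[0]
    y = gaze.samples[1]
    finite = np.isfinite(x) & np.isfinite(y)
    n = x.size
    min_len = max(int(round(min_duration_ms / 1000.0 * fs)), 2)

    fixations: list[FixationEvent] = []
    i = 0
    while i < n - min_len:
        if not finite[i: i + min_len].all():
            i += 1
            continue
        j = i + min_len
        if _dispersion(x[i:j], y[i:j]) > dispersion_deg:
            i += 1
            continue
        while j < n and finite[j] and _dispersion(x[i: j + 1], y[i: j + 1]) <= dispersion_deg:
            j += 1
        fixations.append(
            FixationEvent(
                onset_s=gaze.t0_s + i / fs,
                duration_ms=(j - i) / fs * 1000.0,
                centroid_x_deg=float(np.mean(x[i:j])),
                centroid_y_deg=float(np.mean(y[i:j])),
                dispersion_deg=float(_dispersion(x[i:j], y[i:j])),
            )
        )
        i = j

    saccades: list[SaccadeEvent] = []
    for a, b in zip(fixations, fixations[1:]):
        end_a = a.onset_s + a.duration_ms / 1000.0
        dur_ms = max((b.onset_s - end_a) * 1000.0, 1000.0 / fs)
        amp = float(
            np.hypot(
                b.centroid_x_deg - a.centroid_x_deg,
                b.centroid_y_deg - a.centroid_y_deg,
            )
        )
        saccades.append(
            SaccadeEvent(
                onset_s=end_a,
                duration_ms=dur_ms,
                amplitude_deg=amp,
                peak_velocity_deg_s=amp / (dur_ms / 1000.0),
                source="gaze",
            )
        )
    return fixations, saccades


def _dispersion(x: np.ndarray, y: np.ndarray) -> float:
    return float((x.max() - x.min()) + (y.max() - y.min()))


def interpolate_blinks(
    pupil: Recording, max_gap_ms: float = 500.0
) -> Recording:
    """Linearly interpolate NaN runs up to ``max_gap_ms``; longer gaps
    stay NaN and are excluded from means."""
    fs = pupil.sample_rate_hz
    x = pupil.samples[0].copy()
    isnan = ~np.isfinite(x)
    if not isnan.any():
        return pupil.copy()
    max_len = int(round(max_gap_ms / 1000.0 * fs))
    idx = np.arange(x.size)
    # find NaN runs
    edges = np.flatnonzero(np.diff(np.concatenate([[0], isnan.view(np.int8), [0]])))
    good = ~isnan
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s <= max_len and s > 0 and e < x.size:
            x[s:e] = np.interp(idx[s:e], idx[good], x[good])
    return pupil.copy(samples=x[None, :])


def gaze_block_features(
    fixations: list[FixationEvent],
    saccades: list[SaccadeEvent],
    pupil: Recording,
    interval: tuple[float, float],
    max_blink_interp_ms: float = 500.0,
) -> dict[str, float]:
    """The seven eye-tracking block features.

    fixation_rate = fixation count / interval length;
    fixation_saccade_ratio = total fixation time / total saccade time.
    Pupil blinks are interpolated first; an interval more than half NaN
    is emitted as missing (low quality).
    """
    t0, t1 = interval
    out = {k: float("nan") for k in GAZE_MEASURES}
    p = interpolate_blinks(pupil, max_blink_interp_ms)
    seg = p.slice(t0, t1)[0]
    if seg.size:
        frac_bad = float(np.mean(~np.isfinite(seg)))
        if frac_bad <= 0.5:
            out["pupil_diameter_mean"] = float(np.nanmean(seg))
    fx = [f for f in fixations if t0 <= f.onset_s < t1]
    sc = [s for s in saccades if t0 <= s.onset_s < t1]
    if sc:
        out["saccade_velocity_mean"] = float(
            np.mean([s.peak_velocity_deg_s for s in sc])
        )
        out["saccade_length_mean"] = float(
            np.mean([s.amplitude_deg for s in sc])
        )
    out["fixation_count"] = float(len(fx))
    if fx:
        out["fixation_duration_mean"] = float(
            np.mean([f.duration_ms for f in fx])
        )
    out["fixation_rate_per_s"] = len(fx) / (t1 - t0)
    sacc_time = sum(s.duration_ms for s in sc)
    fix_time = sum(f.duration_ms for f in fx)
    if sacc_time > 0:
        out["fixation_saccade_ratio"] = fix_time / sacc_time
    return out


def process(
    eog_h: Recording | None,
    eog_v: Recording | None,
    gaze: Recording | None,
    pupil: Recording | None,
    design: list[BlockDesign],
    cfg: OcularConfig | None = None,
) -> list[dict]:
    """Ocular features for one task-session: 3 EOG + 7 eye-tracking
    measures per block, long-format rows."""
    cfg = cfg or OcularConfig()
    rows: list[dict] = []
    if eog_h is not None and eog_v is not None:
        events = detect_saccades_eog(eog_h, eog_v, cfg=cfg)
        for block in design:
            vals = saccade_block_features(events, block.interval)
            rows += feature_rows(
                block, "eog", {f"eog.{k}": v for k, v in vals.items()}
            )
    if gaze is not None and pupil is not None:
        fixations, saccades = detect_fixations(
            gaze, cfg.idt_dispersion_deg, cfg.idt_min_duration_ms
        )
        for block in design:
            vals = gaze_block_features(
                fixations, saccades, pupil, block.interval,
                cfg.blink_max_interp_ms,
            )
            rows += feature_rows(
                block, "eyetracking", {f"eye.{k}": v for k, v in vals.items()}
            )
    return rows
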