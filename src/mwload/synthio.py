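"""Synthetic six-modality protocol data with known ground truth.

Emulates a four-session study in which each of six cognitive tasks
(working memory, vigilance, risk assessment, shifting attention,
situation awareness, inhibitory control) is seen three times per
subject: sessions 1-3 hold four tasks each and the final session holds
all six.  Each task-session contains easy and hard blocks; the
generator injects session (learning) and condition (workload) effects
into prefrontal hemodynamics, EEG band powers, RR-interval dynamics,
saccades, pupil diameter and behavioural performance, and records the
injected parameters per block so recovery can be tested exactly.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.special import gammaln

from .config import SynthConfig
from .types import (
    BlockDesign,
    Recording,
    SaccadeEvent,
    TASKS,
    check_nonoverlapping,
    feature_rows,
)

FNIRS_RATE_HZ = 2.0
EEG_RATE_HZ = 500.0
ECG_RATE_HZ = 500.0
PPG_RATE_HZ = 100.0
EOG_RATE_HZ = 500.0
GAZE_RATE_HZ = 60.0

FNIRS_CHANNELS = [f"opt{i:02d}" for i in range(1, 17)]
EEG_CHANNELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FCz",
    "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8", "CP5", "CP1", "CP2",
    "CP6", "P7", "P3", "Pz", "P4", "P8", "PO3", "POz", "PO4", "O1",
    "Oz", "O2",
]
EEG_BANDS = ("delta", "theta", "alpha", "beta", "gamma")

# easy/hard block counts per task-session; vigilance is one continuous
# 5-min run split into 8 segments (first four easy, last four hard)
TASK_LAYOUT: dict[str, dict] = {
    "WorkingMemory": {"n_per_cond": 3, "duration_s": None, "gap_s": None,
                      "contiguous": False},
    "Vigilance": {"n_per_cond": 4, "duration_s": 37.5, "gap_s": 0.0,
                  "contiguous": True},
    "RiskAssessment": {"n_per_cond": 3, "duration_s": None, "gap_s": None,
                       "contiguous": False},
    "ShiftingAttention": {"n_per_cond": 3, "duration_s": 30.0, "gap_s": None,
                          "contiguous": False},
    "SituationAwareness": {"n_per_cond": 2, "duration_s": 30.0, "gap_s": None,
                           "contiguous": False},
    "InhibitoryControl": {"n_per_cond": 3, "duration_s": None, "gap_s": None,
                          "contiguous": False},
}


# ---------------------------------------------------------------------------
# protocol scheduling
# ---------------------------------------------------------------------------

@dataclass
class ProtocolEntry:
    session_index: int  # 1-4 (calendar session)
    task_name: str
    task_order: int  # position within the session, 1-based


@dataclass
class ProtocolSchedule:
    subject_id: str
    entries: list[ProtocolEntry]

    def tasks_in_session(self, session_index: int) -> list[str]:
        out = [e for e in self.entries if e.session_index == session_index]
        return [e.task_name for e in sorted(out, key=lambda e: e.task_order)]

    def task_session_number(self, session_index: int, task_name: str) -> int:
        """nth exposure (1-3) of ``task_name`` as of calendar session."""
        seen = sorted(
            e.session_index for e in self.entries if e.task_name == task_name
        )
        return seen.index(session_index) + 1


def generate_protocol(n_subjects: int, seed: int) -> list[ProtocolSchedule]:
    """Counterbalanced task schedules.

    Each task is omitted from exactly one of sessions 1-3 (so it is seen
    twice there plus once in session 4, three exposures total); the
    omitted session rotates with subject index so per-task session
    appearances differ by at most one across any cohort.  Order within a
    session is a seeded shuffle.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    schedules = []
    for s in range(n_subjects):
        subject_id = f"sub{s + 1:03d}"
        entries: list[ProtocolEntry] = []
        omit = {task: (i + s) % 3 + 1 for i, task in enumerate(TASKS)}
        for sess in (1, 2, 3):
            tasks = [t for t in TASKS if omit[t] != sess]
            rng.shuffle(tasks)
            entries += [
                ProtocolEntry(sess, t, k + 1) for k, t in enumerate(tasks)
            ]
        final = list(TASKS)
        rng.shuffle(final)
        entries += [ProtocolEntry(4, t, k + 1) for k, t in enumerate(final)]
        schedules.append(ProtocolSchedule(subject_id, entries))
    return schedules


def build_block_design(
    subject_id: str,
    task_name: str,
    task_session: int,
    cfg: SynthConfig | None = None,
) -> list[BlockDesign]:
    """Block intervals for one task-session recording.

    The recording clock starts at 0 with ``cfg.baseline_s`` of rest
    before the first block.  Non-contiguous tasks alternate easy/hard
    blocks separated by ``cfg.block_gap_s``.
    """
    cfg = cfg or SynthConfig()
    layout = TASK_LAYOUT[task_name]
    n = layout["n_per_cond"]
    dur = layout["duration_s"] or cfg.block_duration_s
    gap = cfg.block_gap_s if layout["gap_s"] is None else layout["gap_s"]
    if layout["contiguous"]:
        conds = ["easy"] * n + ["hard"] * n
    else:
        conds = ["easy", "hard"] * n
    t = cfg.baseline_s
    blocks = []
    for k, cond in enumerate(conds):
        blocks.append(
            BlockDesign(
                subject_id=subject_id,
                task_name=task_name,
                task_session=task_session,
                condition=cond,
                block_index=k + 1,
                t_start_s=t,
                t_end_s=t + dur,
            )
        )
        t += dur + gap
    check_nonoverlapping(blocks)
    return blocks


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Injected per-block parameters (the recovery-test bookkeeping)."""

    hemo_amplitude_uM: float
    band_power_scale: dict[str, float]
    mean_rr_ms: float
    rr_lf_hf_ratio: float
    saccade_rate_hz: float
    saccade_amplitude_mean_deg: float
    pupil_mean_mm: float
    reaction_time_mean_s: float
    accuracy_prob: float

    def __post_init__(self) -> None:
        for name in (
            "hemo_amplitude_uM", "mean_rr_ms", "rr_lf_hf_ratio",
            "saccade_rate_hz", "saccade_amplitude_mean_deg",
            "pupil_mean_mm", "reaction_time_mean_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(v < 0 for v in self.band_power_scale.values()):
            raise ValueError("band power scales must be non-negative")
        unknown = set(self.band_power_scale) - set(EEG_BANDS)
        if unknown:
            raise ValueError(f"unknown EEG bands: {sorted(unknown)}")


def make_ground_truth(
    design: list[BlockDesign], cfg: SynthConfig, seed: int
) -> list[GroundTruth]:
    """One GroundTruth per block, with session/condition effects applied
    on top of a per-subject random baseline shift."""
    out = []
    for b in design:
        # subject-level effects are a deterministic function of the id so
        # blocks of one subject share them regardless of call grouping
        srng = np.random.default_rng(
            (seed * 1_000_003 + zlib.crc32(b.subject_id.encode())) % (2**31)
        )
        subj_gain = float(np.exp(srng.normal(0.0, 0.10)))
        subj_rr = float(srng.normal(0.0, 30.0))
        subj_pupil = float(srng.normal(0.0, 0.15))
        hard = 1.0 if b.condition == "hard" else 0.0
        sess = b.task_session - 1
        hemo = (
            cfg.hemo_amplitude_uM
            * max(1.0 + cfg.hemo_session_slope * sess, 0.1)
            * (1.0 + cfg.hemo_condition_boost * hard)
            * subj_gain
        )
        scales = {
            "delta": 1.0,
            "theta": (1.0 + cfg.eeg_theta_condition_boost * hard)
            * (1.0 + 0.10 * sess),
            "alpha": (1.0 + cfg.eeg_alpha_session_slope * sess)
            * (1.0 - 0.15 * hard),
            "beta": 1.0 + 0.10 * hard,
            "gamma": 1.0,
        }
        out.append(
            GroundTruth(
                hemo_amplitude_uM=hemo,
                band_power_scale=scales,
                mean_rr_ms=cfg.mean_rr_ms
                + cfg.rr_condition_shift_ms * hard
                + 10.0 * sess
                + subj_rr,
                rr_lf_hf_ratio=cfg.rr_lf_hf_ratio * (1.0 + 0.2 * hard),
                saccade_rate_hz=cfg.saccade_rate_hz * (1.0 + 0.15 * hard),
                saccade_amplitude_mean_deg=cfg.saccade_amplitude_mean_deg,
                pupil_mean_mm=cfg.pupil_mean_mm
                + cfg.pupil_condition_boost_mm * hard
                + subj_pupil,
                reaction_time_mean_s=cfg.rt_mean_s
                * max(1.0 + cfg.rt_session_slope * sess, 0.2)
                * (1.0 + cfg.rt_condition_boost * hard)
                * subj_gain,
                accuracy_prob=float(
                    np.clip(
                        cfg.accuracy_base + cfg.accuracy_condition_drop * hard,
                        0.05,
                        0.99,
                    )
                ),
            )
        )
    return out


def _recording_span(design: list[BlockDesign], tail_s: float = 15.0) -> float:
    return max(b.t_end_s for b in design) + tail_s


def double_gamma_hrf(t: np.ndarray, peak_s: float = 6.0,
                     undershoot_s: float = 16.0,
                     undershoot_ratio: float = 1 / 6) -> np.ndarray:
    """Canonical double-gamma hemodynamic impulse response (peak-normalised)."""
    t = np.asarray(t, dtype=float)

    def g(tt, shape):  # unit-rate gamma pdf
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.exp(
                (shape - 1) * np.log(np.maximum(tt, 1e-12)) - tt
                - gammaln(shape)
            )
        return np.where(tt > 0, out, 0.0)

    h = g(t, peak_s) - undershoot_ratio * g(t, undershoot_s)
    m = h.max()
    return h / m if m > 0 else h


def _block_response(
    design: list[BlockDesign],
    amplitudes: np.ndarray,
    rate_hz: float,
    n_samples: int,
) -> np.ndarray:
    """Sum of per-block boxcar (x) HRF responses, each peak-normalised so a
    block's maximum response equals its injected amplitude."""
    t_h = np.arange(0, 32.0, 1.0 / rate_hz)
    hrf = double_gamma_hrf(t_h)
    total = np.zeros(n_samples)
    for b, amp in zip(design, amplitudes):
        box = np.zeros(n_samples)
        i0 = int(round(b.t_start_s * rate_hz))
        i1 = int(round(b.t_end_s * rate_hz))
        box[i0:i1] = 1.0
        resp = np.convolve(box, hrf)[:n_samples]
        m = resp.max()
        if m > 0:
            total += amp * resp / m
    return total


# ---------------------------------------------------------------------------
# fNIRS forward model
# ---------------------------------------------------------------------------

@dataclass
class FnirsSimParams:
    intensity_baseline: float = 1000.0  # a.u.
    hbr_ratio: float = -1 / 3  # HbR amplitude relative to HbO
    physio_od: float = 1e-3  # 0.1 + 0.25 Hz oscillation amplitude (OD)
    white_od: float = 3e-4
    spike_rate_per_min: float = 0.0
    spike_od: float = 0.05
    # forward MBLL constants; must match the inverse step's defaults
    ext: tuple = ((0.446, 1.1022), (1.058, 0.6917))  # rows 730/850, cols HbO/HbR
    dpf: tuple = (6.0, 6.0)
    separation_cm: float = 2.5


def simulate_fnirs(
    design: list[BlockDesign],
    truth: list[GroundTruth],
    params: FnirsSimParams | None = None,
    seed: int = 0,
) -> tuple[Recording, Recording]:
    """Two-wavelength raw intensities from a forward modified Beer-Lambert
    model: block-locked HbO/HbR responses plus physiological oscillations
    and white noise in optical density, exponentiated around a flat
    baseline intensity."""
    if not design:
        raise ValueError("design must be non-empty")
    check_nonoverlapping(design)
    params = params or FnirsSimParams()
    rng = np.random.default_rng(seed)
    n = int(round(_recording_span(design) * FNIRS_RATE_HZ))
    t = np.arange(n) / FNIRS_RATE_HZ

    amps = np.array([g.hemo_amplitude_uM for g in truth])
    hbo_uM = _block_response(design, amps, FNIRS_RATE_HZ, n)
    hbr_uM = params.hbr_ratio * hbo_uM

    E = np.asarray(params.ext)
    L = params.separation_cm * np.asarray(params.dpf)
    # concentrations in mM for 1/(mM*cm) coefficients
    d_od = np.empty((2, n))
    for w in range(2):
        d_od[w] = (E[w, 0] * hbo_uM + E[w, 1] * hbr_uM) * 1e-3 * L[w]

    out = []
    for w, modality in enumerate(("fnirs_730", "fnirs_850")):
        samples = np.empty((len(FNIRS_CHANNELS), n))
        for c in range(len(FNIRS_CHANNELS)):
            od = d_od[w].copy()
            if params.physio_od > 0:
                ph = rng.uniform(0, 2 * np.pi, size=2)
                od += params.physio_od * (
                    np.sin(2 * np.pi * 0.1 * t + ph[0])
                    + 0.5 * np.sin(2 * np.pi * 0.25 * t + ph[1])
                )
            if params.white_od > 0:
                od += rng.normal(0.0, params.white_od, size=n)
            if params.spike_rate_per_min > 0:
                n_spikes = rng.poisson(
                    params.spike_rate_per_min * t[-1] / 60.0
                )
                for _ in range(n_spikes):
                    i = rng.integers(0, n)
                    od[i: i + 3] += params.spike_od * rng.choice([-1, 1])
            samples[c] = params.intensity_baseline * 10.0 ** (-od)
        out.append(
            Recording(modality, FNIRS_RATE_HZ, list(FNIRS_CHANNELS), samples)
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

@dataclass
class EegSimParams:
    band_sd_uv: dict = field(
        default_factory=lambda: {
            "delta": 4.0, "theta": 3.0, "alpha": 5.0, "beta": 2.5,
            "gamma": 1.5,
        }
    )
    pink_rms_uv: float = 1.0
    line_amp_uv: float = 20.0
    blink_amp_uv: float = 100.0
    blink_duration_s: float = 0.25


_BAND_EDGES = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 59.0),
}


def simulate_eeg(
    design: list[BlockDesign],
    truth: list[GroundTruth],
    params: EegSimParams | None = None,
    seed: int = 0,
    blink_times_s: np.ndarray | None = None,
) -> Recording:
    """32-channel EEG: per band, band-limited Gaussian noise whose variance
    is scaled block-wise by the injected band_power_scale, plus a 1/f
    background, 60 Hz line component and optional blink templates."""
    params = params or EegSimParams()
    for g in truth:
        unknown = set(g.band_power_scale) - set(EEG_BANDS)
        if unknown:
            raise ValueError(f"unknown EEG bands: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    n = int(round(_recording_span(design) * EEG_RATE_HZ))
    t = np.arange(n) / EEG_RATE_HZ
    n_ch = len(EEG_CHANNELS)
    samples = np.zeros((n_ch, n))

    # block-wise amplitude envelope per band (sqrt of the power scale)
    envelopes = {}
    for band in EEG_BANDS:
        env = np.ones(n)
        for b, g in zip(design, truth):
            i0 = int(round(b.t_start_s * EEG_RATE_HZ))
            i1 = int(round(b.t_end_s * EEG_RATE_HZ))
            env[i0:i1] = math.sqrt(g.band_power_scale.get(band, 1.0))
        envelopes[band] = env

    sos_cache = {
        band: sps.butter(
            4, _BAND_EDGES[band], btype="bandpass", fs=EEG_RATE_HZ,
            output="sos",
        )
        for band in EEG_BANDS
    }
    for c in range(n_ch):
        x = np.zeros(n)
        for band in EEG_BANDS:
            sd = params.band_sd_uv.get(band, 0.0)
            if sd <= 0:
                continue
            white = rng.standard_normal(n)
            nb = sps.sosfiltfilt(sos_cache[band], white)
            rms = np.sqrt(np.mean(nb**2))
            if rms > 0:
                nb *= sd / rms
            x += nb * envelopes[band]
        if params.pink_rms_uv > 0:
            white = rng.standard_normal(n)
            spec = np.fft.rfft(white)
            f = np.fft.rfftfreq(n, 1 / EEG_RATE_HZ)
            spec[1:] /= np.sqrt(f[1:])
            spec[0] = 0
            pink = np.fft.irfft(spec, n)
            pink *= params.pink_rms_uv / np.sqrt(np.mean(pink**2))
            x += pink
        if params.line_amp_uv > 0:
            x += params.line_amp_uv * np.sin(
                2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi)
            )
        samples[c] = x

    if blink_times_s is not None and params.blink_amp_uv > 0:
        w = int(round(params.blink_duration_s * EEG_RATE_HZ))
        template = params.blink_amp_uv * np.hanning(w)
        frontal_gain = np.linspace(1.0, 0.1, n_ch)  # strongest at Fp sites
        for bt in np.asarray(blink_times_s):
            i0 = int(round(bt * EEG_RATE_HZ))
            if 0 <= i0 < n - w:
                samples[:, i0: i0 + w] += np.outer(frontal_gain, template)

    return Recording("eeg", EEG_RATE_HZ, list(EEG_CHANNELS), samples)


# ---------------------------------------------------------------------------
# cardiac (ECG + PPG)
# ---------------------------------------------------------------------------

@dataclass
class CardiacSimParams:
    rr_mod_sd_ms: float = 30.0  # total LF+HF modulation SD
    rr_jitter_ms: float = 3.0
    ecg_noise_mv: float = 0.02
    ecg_r_amp_mv: float = 1.0
    ppg_noise: float = 0.02
    ppg_delay_s: float = 0.25
    ppg_pulse_width_s: float = 0.25
    ppg_pulse_amp: float = 1.0
    ppg_dicrotic_frac: float = 0.0  # secondary bump amplitude fraction


def _rr_at(t_s: float, design, truth, default_rr_ms: float) -> float:
    for b, g in zip(design, truth):
        if b.t_start_s <= t_s < b.t_end_s:
            return g.mean_rr_ms
    return default_rr_ms


def simulate_cardiac(
    design: list[BlockDesign],
    truth: list[GroundTruth],
    params: CardiacSimParams | None = None,
    seed: int = 0,
) -> tuple[Recording, Recording, np.ndarray]:
    """ECG as a QRS-template train and PPG as a delayed smooth pulse train,
    both driven by one RR series: block-wise mean RR modulated by 0.1 Hz
    ("LF") and 0.25 Hz ("HF") sinusoids whose variance split follows the
    injected LF/HF ratio, plus white jitter.  Returns the true R-peak
    times for recovery tests."""
    params = params or CardiacSimParams()
    rng = np.random.default_rng(seed)
    span = _recording_span(design)
    default_rr = truth[0].mean_rr_ms if truth else 850.0
    ratio = truth[0].rr_lf_hf_ratio if truth else 1.5
    var_total = params.rr_mod_sd_ms**2
    var_lf = var_total * ratio / (1.0 + ratio)
    var_hf = var_total / (1.0 + ratio)
    a_lf = math.sqrt(2 * var_lf)
    a_hf = math.sqrt(2 * var_hf)
    ph = rng.uniform(0, 2 * np.pi, size=2)

    beat_times = []
    t = 0.0
    while t < span:
        beat_times.append(t)
        rr = _rr_at(t, design, truth, default_rr)
        rr += a_lf * math.sin(2 * np.pi * 0.1 * t + ph[0])
        rr += a_hf * math.sin(2 * np.pi * 0.25 * t + ph[1])
        if params.rr_jitter_ms > 0:
            rr += rng.normal(0.0, params.rr_jitter_ms)
        t += max(rr, 300.0) / 1000.0
    beat_times = np.array(beat_times)

    # ECG: R spike (narrow gaussian) with small Q/S deflections and T wave
    n_ecg = int(round(span * ECG_RATE_HZ))
    t_ecg = np.arange(n_ecg) / ECG_RATE_HZ
    ecg = np.zeros(n_ecg)

    def add_bump(center_s, width_s, amp):
        i0 = max(int((center_s - 4 * width_s) * ECG_RATE_HZ), 0)
        i1 = min(int((center_s + 4 * width_s) * ECG_RATE_HZ), n_ecg)
        if i0 < i1:
            tt = t_ecg[i0:i1] - center_s
            ecg[i0:i1] += amp * np.exp(-0.5 * (tt / width_s) ** 2)

    for bt in beat_times:
        add_bump(bt - 0.025, 0.012, -0.15 * params.ecg_r_amp_mv)  # Q
        add_bump(bt, 0.012, params.ecg_r_amp_mv)  # R
        add_bump(bt + 0.030, 0.015, -0.20 * params.ecg_r_amp_mv)  # S
        add_bump(bt + 0.25, 0.06, 0.25 * params.ecg_r_amp_mv)  # T
    if params.ecg_noise_mv > 0:
        ecg += rng.normal(0.0, params.ecg_noise_mv, size=n_ecg)
    ecg_rec = Recording("ecg", ECG_RATE_HZ, ["ecg"], ecg[None, :])

    # PPG: asymmetric smooth pulse delayed after each R peak
    n_ppg = int(round(span * PPG_RATE_HZ))
    t_ppg = np.arange(n_ppg) / PPG_RATE_HZ
    ppg = np.zeros(n_ppg)
    w = params.ppg_pulse_width_s
    for bt in beat_times:
        c = bt + params.ppg_delay_s
        i0 = max(int((c - 2 * w) * PPG_RATE_HZ), 0)
        i1 = min(int((c + 3 * w) * PPG_RATE_HZ), n_ppg)
        if i0 >= i1:
            continue
        tt = t_ppg[i0:i1] - c
        sigma_r, sigma_f = 0.35 * w, 0.65 * w  # fast rise, slow fall
        pulse = np.where(
            tt < 0,
            np.exp(-0.5 * (tt / sigma_r) ** 2),
            np.exp(-0.5 * (tt / sigma_f) ** 2),
        )
        if params.ppg_dicrotic_frac > 0:
            pulse += params.ppg_dicrotic_frac * np.exp(
                -0.5 * ((tt - 1.4 * w) / sigma_f) ** 2
            )
        ppg[i0:i1] += params.ppg_pulse_amp * pulse
    if params.ppg_noise > 0:
        ppg += rng.normal(0.0, params.ppg_noise, size=n_ppg)
    ppg_rec = Recording("ppg", PPG_RATE_HZ, ["ppg"], ppg[None, :])
    return ecg_rec, ppg_rec, beat_times


# ---------------------------------------------------------------------------
# ocular (EOG + gaze + pupil)
# ---------------------------------------------------------------------------

@dataclass
class OcularSimParams:
    eog_uv_per_deg: float = 10.0
    eog_noise_uv: float = 2.0
    gaze_noise_deg: float = 0.05
    pupil_noise_mm: float = 0.02
    blink_rate_hz: float = 0.05
    blink_duration_s: float = 0.20
    main_seq_vmax_deg_s: float = 500.0
    main_seq_a0_deg: float = 8.0
    field_limit_deg: float = 12.0
    min_fixation_s: float = 0.15


def _saccade_duration_s(amplitude_deg: float, p: OcularSimParams) -> float:
    vp = p.main_seq_vmax_deg_s * (
        1.0 - math.exp(-amplitude_deg / p.main_seq_a0_deg)
    )
    # raised-cosine profile: peak velocity = pi * amplitude / (2 * duration)
    return math.pi * amplitude_deg / (2.0 * vp)


def simulate_ocular(
    design: list[BlockDesign],
    truth: list[GroundTruth],
    params: OcularSimParams | None = None,
    seed: int = 0,
) -> tuple[Recording, Recording, Recording, Recording, list[SaccadeEvent]]:
    """Fixation-saccade alternation with main-sequence kinematics.

    Gaze (60 Hz, degrees) and EOG (500 Hz, gaze scaled by the deg-to-uV
    calibration constant plus noise) are generated from one continuous
    eye-position trace; pupil diameter carries the injected block means
    plus slow drift; blinks appear as NaN dropouts in pupil and spikes in
    vertical EOG.  Returns (eog_h, eog_v, gaze, pupil, true_saccades).
    """
    params = params or OcularSimParams()
    rng = np.random.default_rng(seed)
    span = _recording_span(design)

    # build the continuous eye trace on a fine clock, then resample
    fine_hz = EOG_RATE_HZ
    n_fine = int(round(span * fine_hz))
    t_fine = np.arange(n_fine) / fine_hz
    pos = np.zeros((2, n_fine))
    true_events: list[SaccadeEvent] = []

    def rate_at(ts: float) -> float:
        for b, g in zip(design, truth):
            if b.t_start_s <= ts < b.t_end_s:
                return g.saccade_rate_hz
        return 0.6 * (truth[0].saccade_rate_hz if truth else 2.0)

    def amp_at(ts: float) -> float:
        for b, g in zip(design, truth):
            if b.t_start_s <= ts < b.t_end_s:
                return g.saccade_amplitude_mean_deg
        return truth[0].saccade_amplitude_mean_deg if truth else 5.0

    cur = np.zeros(2)
    t = 0.3
    while t < span - 0.5:
        rate = rate_at(t)
        if rate <= 0:
            # no saccades scheduled in this block: hold fixation past it
            nxt = next(
                (b.t_end_s for b in design if b.t_start_s <= t < b.t_end_s),
                None,
            )
            t = (nxt + 0.01) if nxt is not None else t + 1.0
            continue
        t += max(rng.exponential(1.0 / rate), params.min_fixation_s)
        if t >= span - 0.5:
            break
        amp = float(
            np.clip(amp_at(t) * rng.lognormal(0.0, 0.35), 0.5, 25.0)
        )
        theta = rng.uniform(0, 2 * np.pi)
        step = amp * np.array([math.cos(theta), math.sin(theta)])
        target = cur + step
        # keep gaze on screen: reflect the step toward centre if needed
        for d in range(2):
            if abs(target[d]) > params.field_limit_deg:
                target[d] = cur[d] - step[d]
        amp_actual = float(np.linalg.norm(target - cur))
        if amp_actual < 0.3:
            continue
        dur = _saccade_duration_s(amp_actual, params)
        i0 = int(round(t * fine_hz))
        i1 = min(int(round((t + dur) * fine_hz)) + 1, n_fine)
        if i1 <= i0 + 1:
            i1 = i0 + 2
        phase = (t_fine[i0:i1] - t) / dur
        prof = 0.5 * (1 - np.cos(np.pi * np.clip(phase, 0, 1)))
        for d in range(2):
            pos[d, i0:i1] = cur[d] + (target[d] - cur[d]) * prof
        pos[:, i1:] = target[:, None]
        vp = params.main_seq_vmax_deg_s * (
            1.0 - math.exp(-amp_actual / params.main_seq_a0_deg)
        )
        true_events.append(
            SaccadeEvent(
                onset_s=t,
                duration_ms=dur * 1000.0,
                amplitude_deg=amp_actual,
                peak_velocity_deg_s=vp,
                source="truth",
            )
        )
        cur = target
        t += dur

    # gaze recording (60 Hz)
    n_gaze = int(round(span * GAZE_RATE_HZ))
    idx = np.minimum(
        (np.arange(n_gaze) / GAZE_RATE_HZ * fine_hz).astype(int), n_fine - 1
    )
    gaze_samples = pos[:, idx] + rng.normal(
        0.0, params.gaze_noise_deg, size=(2, n_gaze)
    )
    gaze = Recording("gaze", GAZE_RATE_HZ, ["gaze_x", "gaze_y"], gaze_samples)

    # EOG (500 Hz)
    eog_h_x = params.eog_uv_per_deg * pos[0] + rng.normal(
        0.0, params.eog_noise_uv, size=n_fine
    )
    eog_v_x = params.eog_uv_per_deg * pos[1] + rng.normal(
        0.0, params.eog_noise_uv, size=n_fine
    )

    # pupil (60 Hz): injected block means + slow drift
    t_gz = np.arange(n_gaze) / GAZE_RATE_HZ
    base = truth[0].pupil_mean_mm if truth else 4.0
    pupil_x = np.full(n_gaze, base - 0.15)
    for b, g in zip(design, truth):
        m = (t_gz >= b.t_start_s) & (t_gz < b.t_end_s)
        pupil_x[m] = g.pupil_mean_mm
    # smooth block transitions and add drift + noise
    k = int(GAZE_RATE_HZ)  # 1 s smoothing
    kernel = np.hanning(k)
    kernel /= kernel.sum()
    pupil_x = np.convolve(pupil_x, kernel, mode="same")
    pupil_x += 0.10 * np.sin(2 * np.pi * 0.02 * t_gz + rng.uniform(0, 2 * np.pi))
    pupil_x += rng.normal(0.0, params.pupil_noise_mm, size=n_gaze)

    # blinks: NaN dropouts in pupil, spikes in vertical EOG
    if params.blink_rate_hz > 0:
        n_blinks = rng.poisson(params.blink_rate_hz * span)
        blink_times = np.sort(rng.uniform(1.0, span - 1.0, size=n_blinks))
        for bt in blink_times:
            g0 = int(bt * GAZE_RATE_HZ)
            g1 = g0 + int(params.blink_duration_s * GAZE_RATE_HZ)
            pupil_x[g0:g1] = np.nan
            e0 = int(bt * fine_hz)
            w = int(params.blink_duration_s * fine_hz)
            if e0 + w < n_fine:
                eog_v_x[e0: e0 + w] += 150.0 * np.hanning(w)
    else:
        blink_times = np.zeros(0)

    eog_h = Recording("eog_h", EOG_RATE_HZ, ["eog_h"], eog_h_x[None, :])
    eog_v = Recording("eog_v", EOG_RATE_HZ, ["eog_v"], eog_v_x[None, :])
    pupil = Recording("pupil", GAZE_RATE_HZ, ["pupil"], pupil_x[None, :])
    pupil.blink_times_s = blink_times  # ad hoc channel for the EEG blink lock
    return eog_h, eog_v, gaze, pupil, true_events


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

def simulate_behavior(
    design: list[BlockDesign],
    truth: list[GroundTruth],
    seed: int = 0,
    n_trials: int = 20,
) -> list[dict]:
    """Per-block behavioural measures: block-mean reaction time (lognormal
    around the injected mean) and accuracy (binomial proportion).  Returns
    long-format feature-table rows."""
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for b, g in zip(design, truth):
        mu = math.log(g.reaction_time_mean_s)
        rts = rng.lognormal(mu, 0.2, size=n_trials)
        acc = rng.binomial(n_trials, g.accuracy_prob) / n_trials
        rows += feature_rows(
            b,
            "performance",
            {
                "perf.reaction_time": float(np.mean(rts)),
                "perf.accuracy": float(acc),
            },
        )
    return rows


# ---------------------------------------------------------------------------
# one task-session, all modalities
# ---------------------------------------------------------------------------

@dataclass
class TaskSessionData:
    subject_id: str
    task_name: str
    task_session: int
    design: list[BlockDesign]
    truth: list[GroundTruth]
    recordings: dict[str, Recording]
    true_rpeak_times_s: np.ndarray
    true_saccades: list[SaccadeEvent]
    behavior_rows: list[dict]


def simulate_task_session(
    subject_id: str,
    task_name: str,
    task_session: int,
    cfg: SynthConfig | None = None,
    seed: int = 0,
    modalities: tuple[str, ...] = ("fnirs", "eeg", "cardiac", "ocular"),
) -> TaskSessionData:
    """Generate all requested modality recordings for one task-session."""
    cfg = cfg or SynthConfig()
    design = build_block_design(subject_id, task_name, task_session, cfg)
    truth = make_ground_truth(design, cfg, seed)
    ss = np.random.SeedSequence(
        [seed, zlib.crc32(subject_id.encode()), TASKS.index(task_name),
         task_session]
    )
    seeds = ss.generate_state(4)
    recordings: dict[str, Recording] = {}
    rpeaks = np.zeros(0)
    saccades: list[SaccadeEvent] = []
    if "fnirs" in modalities:
        r730, r850 = simulate_fnirs(design, truth, seed=int(seeds[0] % 2**31))
        recordings["fnirs_730"] = r730
        recordings["fnirs_850"] = r850
    blink_times = None
    if "ocular" in modalities:
        eog_h, eog_v, gaze, pupil, saccades = simulate_ocular(
            design, truth, seed=int(seeds[1] % 2**31)
        )
        recordings.update(
            {"eog_h": eog_h, "eog_v": eog_v, "gaze": gaze, "pupil": pupil}
        )
        blink_times = getattr(pupil, "blink_times_s", None)
    if "eeg" in modalities:
        recordings["eeg"] = simulate_eeg(
            design, truth, seed=int(seeds[2] % 2**31),
            blink_times_s=blink_times,
        )
    if "cardiac" in modalities:
        ecg, ppg, rpeaks = simulate_cardiac(
            design, truth, seed=int(seeds[3] % 2**31)
        )
        recordings["ecg"] = ecg
        recordings["ppg"] = ppg
    behavior = simulate_behavior(design, truth, seed=int(seeds[0] % 2**31))
    return TaskSessionData(
        subject_id=subject_id,
        task_name=task_name,
        task_session=task_session,
        design=design,
        truth=truth,
        recordings=recordings,
        true_rpeak_times_s=rpeaks,
        true_saccades=saccades,
        behavior_rows=behavior,
    )
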