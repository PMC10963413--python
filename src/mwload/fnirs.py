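"""fNIRS processing: raw two-wavelength intensity to hemoglobin features.

Chain order: intensity -> low-pass FIR (Hamming, order 20, 0.1 Hz) ->
sliding-window motion-artifact rejection -> modified Beer-Lambert
inversion into HbO/HbR (micromolar), from which oxygenation
(Oxy = HbO - HbR) and total hemoglobin (HbT = HbO + HbR) follow.  Block
features per optode and chromophore are mean, slope, peak, time-to-peak
and sum of changes: with 16 optodes that is 16 x 4 x 5 = 320 measures
per task-session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import FnirsConfig
from .types import BlockDesign, Recording, feature_rows

CHROMOPHORES = ("HbO", "HbR", "Oxy", "HbT")
FEATURE_STATS = ("mean", "slope", "peak", "time_to_peak", "sum")


@dataclass
class MbllParams:
    """Constants of the modified Beer-Lambert inversion.

    ``extinction`` is a 2x2 matrix (rows = wavelengths 730/850 nm,
    columns = chromophores HbO/HbR) in 1/(mM*cm); the effective optical
    pathlength per wavelength is ``separation_cm * dpf``.
    """

    extinction: np.ndarray
    dpf_730: float = 6.0
    dpf_850: float = 6.0
    separation_cm: float = 2.5

    def __post_init__(self) -> None:
        self.extinction = np.asarray(self.extinction, dtype=float)
        if self.extinction.shape != (2, 2):
            raise ValueError("extinction must be 2x2")
        if np.any(self.extinction <= 0):
            raise ValueError("extinction coefficients must be positive")
        if not np.isfinite(np.linalg.cond(self.extinction)):
            raise ValueError("extinction matrix is singular")

    @classmethod
    def from_config(cls, cfg: FnirsConfig) -> "MbllParams":
        return cls(
            extinction=np.array(
                [
                    [cfg.ext_730_hbo, cfg.ext_730_hbr],
                    [cfg.ext_850_hbo, cfg.ext_850_hbr],
                ]
            ),
            dpf_730=cfg.dpf_730,
            dpf_850=cfg.dpf_850,
            separation_cm=cfg.separation_cm,
        )


@dataclass
class HemoSeries:
    """Per-optode HbO/HbR/Oxy/HbT concentration-change series (micromolar).

    ``quality_mask`` is True where the sample is retained; masked samples
    are excluded from all block statistics.  The identities
    Oxy = HbO - HbR and HbT = HbO + HbR hold exactly at every sample.
    """

    channel_labels: list[str]
    hbo: np.ndarray  # (channels, time), uM
    hbr: np.ndarray
    sample_rate_hz: float = 2.0
    quality_mask: np.ndarray = None
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        if self.quality_mask is None:
            self.quality_mask = np.ones_like(self.hbo, dtype=bool)

    @property
    def oxy(self) -> np.ndarray:
        return self.hbo - self.hbr

    @property
    def hbt(self) -> np.ndarray:
        return self.hbo + self.hbr

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.hbo.shape[1]) / self.sample_rate_hz

    def series(self, chromophore: str) -> np.ndarray:
        return {
            "HbO": self.hbo, "HbR": self.hbr,
            "Oxy": self.oxy, "HbT": self.hbt,
        }[chromophore]


def lowpass_fir(
    rec: Recording, order: int = 20, cutoff_hz: float = 0.1
) -> Recording:
    """Linear-phase Hamming-window FIR low-pass with group-delay
    compensation (single pass, delay of order/2 samples removed)."""
    nyq = rec.sample_rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    if abs(rec.sample_rate_hz - 2.0) > 1e-9:
        warnings.warn(
            f"fNIRS low-pass designed for 2 Hz data, got "
            f"{rec.sample_rate_hz} Hz"
        )
    taps = sps.firwin(order + 1, cutoff_hz, window="hamming", fs=rec.sample_rate_hz)
    delay = order // 2
    out = np.empty_like(rec.samples)
    for c in range(rec.n_channels):
        x = rec.samples[c]
        # constant padding at both edges tames start-up transients;
        # the linear-phase group delay (order/2 samples) is removed
        padded = np.concatenate(
            [np.full(order, x[0]), x, np.full(delay, x[-1])]
        )
        y = sps.lfilter(taps, 1.0, padded)
        out[c] = y[order + delay:]
    return rec.copy(samples=out)


def fir_attenuation(order: int, cutoff_hz: float, freq_hz: float,
                    sample_rate_hz: float = 2.0) -> float:
    """|H(f)| of the designed FIR at freq_hz (for verification)."""
    taps = sps.firwin(order + 1, cutoff_hz, window="hamming", fs=sample_rate_hz)
    _, h = sps.freqz(taps, worN=[freq_hz], fs=sample_rate_hz)
    return float(np.abs(h[0]))


def smar_reject(
    rec: Recording,
    window_s: float = 4.0,
    spike_sd: float = 3.0,
    saturation_limits: tuple[float, float] = (1e-6, 4000.0),
) -> tuple[Recording, np.ndarray]:
    """Sliding-window motion-artifact rejection.

    Per optode, a sliding-window standard-deviation profile is computed;
    samples whose window SD exceeds ``spike_sd`` times the running median
    window SD, or whose raw intensity is outside ``saturation_limits``,
    are masked (mask=False).  Returns the unchanged recording and the
    retain-mask; an all-masked channel is reported via a warning.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    w = max(int(round(window_s * rec.sample_rate_hz)), 2)
    n = rec.n_samples
    mask = np.ones((rec.n_channels, n), dtype=bool)
    for c in range(rec.n_channels):
        x = rec.samples[c]
        # window SD centred on each sample via cumulative sums
        pad = w // 2
        xp = np.pad(x, pad, mode="edge")
        kernel = np.ones(w) / w
        m1 = np.convolve(xp, kernel, mode="same")[pad: pad + n]
        m2 = np.convolve(xp**2, kernel, mode="same")[pad: pad + n]
        sd = np.sqrt(np.maximum(m2 - m1**2, 0.0))
        med = np.median(sd)
        if med <= 0:
            med = np.mean(sd) if np.mean(sd) > 0 else 1.0
        bad = sd > spike_sd * med
        bad |= (x <= saturation_limits[0]) | (x >= saturation_limits[1])
        mask[c] = ~bad
        if not mask[c].any():
            warnings.warn(
                f"SMAR: channel {rec.channel_labels[c]} fully masked; "
                "excluded downstream"
            )
    return rec, mask


def mbll(
    i730: Recording,
    i850: Recording,
    baseline_interval: tuple[float, float],
    params: MbllParams,
    quality_mask: np.ndarray | None = None,
) -> HemoSeries:
    """Modified Beer-Lambert inversion.

    Optical-density change per wavelength is
    dOD(t) = -log10(I(t) / mean(I over baseline)); concentration changes
    solve [dHbO, dHbR] = (E * L)^-1 dOD with L = separation * DPF,
    returned in micromolar.
    """
    if i730.n_samples != i850.n_samples or i730.sample_rate_hz != i850.sample_rate_hz:
        raise ValueError("730/850 nm recordings must share length and rate")
    if np.any(i730.samples <= 0) or np.any(i850.samples <= 0):
        raise ValueError("non-positive raw intensity")
    b0, b1 = baseline_interval
    if b1 - b0 < 10.0:
        raise ValueError("baseline interval must span at least 10 s")
    s0, s1 = i730.index_of(b0), i730.index_of(b1)
    if s1 - s0 < 2:
        raise ValueError("baseline interval contains too few samples")

    L = params.separation_cm * np.array([params.dpf_730, params.dpf_850])
    EL = params.extinction * L[:, None]
    inv = np.linalg.inv(EL)

    n_ch, n = i730.n_channels, i730.n_samples
    hbo = np.empty((n_ch, n))
    hbr = np.empty((n_ch, n))
    for c in range(n_ch):
        d_od = np.stack(
            [
                -np.log10(i730.samples[c] / i730.samples[c, s0:s1].mean()),
                -np.log10(i850.samples[c] / i850.samples[c, s0:s1].mean()),
            ]
        )
        conc_mM = inv @ d_od
        hbo[c] = conc_mM[0] * 1e3
        hbr[c] = conc_mM[1] * 1e3
    mask = (
        np.ones((n_ch, n), dtype=bool) if quality_mask is None
        else quality_mask.copy()
    )
    return HemoSeries(
        channel_labels=list(i730.channel_labels),
        hbo=hbo,
        hbr=hbr,
        sample_rate_hz=i730.sample_rate_hz,
        quality_mask=mask,
        t0_s=i730.t0_s,
    )


def block_features(
    values: np.ndarray,
    times_s: np.ndarray,
    interval: tuple[float, float],
    mask: np.ndarray | None = None,
) -> dict[str, float]:
    """Block summary of one scalar series over ``interval``.

    mean, OLS slope vs time (units/s), signed maximum (peak), seconds
    from block start to the peak, and the plain sum of samples.  Masked
    samples are excluded; fewer than 4 retained samples yields NaNs.
    """
    t0, t1 = interval
    sel = (times_s >= t0) & (times_s < t1)
    if mask is not None:
        sel &= mask
    sel &= np.isfinite(values)
    x = values[sel]
    t = times_s[sel]
    if x.size < 4:
        return {k: float("nan") for k in FEATURE_STATS}
    slope = float(np.polyfit(t, x, 1)[0])
    ipeak = int(np.argmax(x))
    return {
        "mean": float(np.mean(x)),
        "slope": slope,
        "peak": float(x[ipeak]),
        "time_to_peak": float(t[ipeak] - t0),
        "sum": float(np.sum(x)),
    }


def process(
    i730: Recording,
    i850: Recording,
    design: list[BlockDesign],
    cfg: FnirsConfig | None = None,
) -> tuple[HemoSeries, list[dict]]:
    """Full chain for one task-session: FIR -> SMAR -> MBLL -> block
    features.  Baseline is the pre-task rest (start of recording to the
    first block) unless ``cfg.baseline_mode == 'block'``.

    Returns the hemoglobin series and long-format feature rows
    (16 optodes x 4 chromophores x 5 statistics = 320 measures/block).
    """
    cfg = cfg or FnirsConfig()
    f730 = lowpass_fir(i730, cfg.fir_order, cfg.fir_cutoff_hz)
    f850 = lowpass_fir(i850, cfg.fir_order, cfg.fir_cutoff_hz)
    _, m730 = smar_reject(
        f730, cfg.smar_window_s, cfg.smar_spike_sd,
        (cfg.saturation_low, cfg.saturation_high),
    )
    _, m850 = smar_reject(
        f850, cfg.smar_window_s, cfg.smar_spike_sd,
        (cfg.saturation_low, cfg.saturation_high),
    )
    mask = m730 & m850
    first_block = min(b.t_start_s for b in design)
    baseline = (i730.t0_s, i730.t0_s + max(first_block, 10.0))
    hemo = mbll(f730, f850, baseline, MbllParams.from_config(cfg), mask)

    rows: list[dict] = []
    times = hemo.times
    for block in design:
        vals: dict[str, float] = {}
        for chrom in CHROMOPHORES:
            arr = hemo.series(chrom)
            for c, label in enumerate(hemo.channel_labels):
                if cfg.baseline_mode == "block":
                    i0 = hemo.quality_mask[c] & (times < block.t_start_s)
                    ref_sel = i0 & (times >= block.t_start_s - 10.0)
                    offset = (
                        float(np.mean(arr[c][ref_sel])) if ref_sel.any() else 0.0
                    )
                else:
                    offset = 0.0
                feats = block_features(
                    arr[c] - offset, times, block.interval,
                    hemo.quality_mask[c],
                )
                for stat, v in feats.items():
                    vals[f"fnirs.{chrom}.{label}.{stat}"] = v
        rows += feature_rows(block, "fnirs", vals)
    return hemo, rows
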