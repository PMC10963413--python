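"""EEG processing: notch + band-pass filtering, artifact removal,
moving-window Welch band powers and workload ratio indices.

Chain: order-8 Butterworth notch at 60 Hz -> order-7 Butterworth
band-pass 1-59 Hz -> ocular-artifact removal (EOG regression by
default, correlation-thresholded ICA optional) -> optional
artifact-subspace cleaning -> Welch band power in 2 s moving windows
for delta/theta/alpha/beta/gamma -> ratio indices, including the
engagement ratio beta/(alpha+theta).  With 32 channels the block-mean
feature set is 32 x (5 bands + 4 ratios) = 288 measures.

All IIR filters are applied forward-backward (zero phase) so
block-locked features are not delayed; "order" refers to the analog
prototype order of the design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import EegConfig
from .types import BlockDesign, Recording, feature_rows

DEFAULT_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 59.0),  # ">30 Hz", bounded by the band-pass edge
}

RATIO_NAMES = ("engagement", "theta_alpha", "theta_beta", "ta_ba")


@dataclass
class BandPowerSeries:
    """channel x band x window power array (uV^2) on a moving-window grid."""

    channel_labels: list[str]
    band_names: list[str]
    power: np.ndarray  # (channels, bands, windows)
    window_times_s: np.ndarray  # centre of each window
    window_s: float
    hop_s: float

    def band(self, name: str) -> np.ndarray:
        return self.power[:, self.band_names.index(name), :]


def notch_filter(rec: Recording, freq_hz: float = 60.0, order: int = 8,
                 halfwidth_hz: float = 2.0) -> Recording:
    """Zero-phase Butterworth band-stop centred on the line frequency
    (default stop band 58-62 Hz)."""
    nyq = rec.sample_rate_hz / 2.0
    if freq_hz >= nyq:
        raise ValueError(f"notch {freq_hz} Hz >= Nyquist {nyq} Hz")
    if rec.sample_rate_hz <= 120.0:
        raise ValueError("sample rate must exceed 120 Hz for a 60 Hz notch")
    sos = sps.butter(
        order, [freq_hz - halfwidth_hz, freq_hz + halfwidth_hz],
        btype="bandstop", fs=rec.sample_rate_hz, output="sos",
    )
    return rec.copy(samples=sps.sosfiltfilt(sos, rec.samples, axis=1))


def bandpass_filter(rec: Recording, lo_hz: float = 1.0, hi_hz: float = 59.0,
                    order: int = 7) -> Recording:
    """Zero-phase Butterworth band-pass (default 1-59 Hz, order 7)."""
    nyq = rec.sample_rate_hz / 2.0
    if not 0 < lo_hz < hi_hz < nyq:
        raise ValueError("band edges must satisfy 0 < lo < hi < Nyquist")
    sos = sps.butter(order, [lo_hz, hi_hz], btype="bandpass",
                     fs=rec.sample_rate_hz, output="sos")
    return rec.copy(samples=sps.sosfiltfilt(sos, rec.samples, axis=1))


def remove_ocular_artifacts(
    rec: Recording,
    eog: Recording,
    method: str = "regression",
    corr_threshold: float = 0.7,
) -> Recording:
    """Remove eye-movement contamination using the EOG reference.

    ``regression`` (default, suited to short recordings) subtracts each
    channel's least-squares projection onto the EOG channels.  ``ica``
    computes a linear decomposition (FastICA) and zeroes components whose
    absolute correlation with any EOG channel exceeds ``corr_threshold``
    before reconstruction.
    """
    if eog.n_samples != rec.n_samples:
        raise ValueError("EEG/EOG length mismatch")
    E = eog.samples - eog.samples.mean(axis=1, keepdims=True)
    if not np.any(np.std(E, axis=1) > 0):
        return rec.copy()
    X = rec.samples
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    if method == "regression":
        # beta = Xc E' (E E')^-1 ; remove beta E
        G = E @ E.T
        beta = Xc @ E.T @ np.linalg.pinv(G)
        return rec.copy(samples=Xc - beta @ E + mean)
    if method == "ica":
        from sklearn.decomposition import FastICA

        n_comp = min(rec.n_channels, 20)
        ica = FastICA(n_components=n_comp, random_state=0, max_iter=500,
                      whiten="unit-variance")
        sources = ica.fit_transform(Xc.T)  # (time, comp)
        keep = np.ones(n_comp, dtype=bool)
        for k in range(n_comp):
            for e in range(E.shape[0]):
                se = np.std(E[e])
                if se == 0:
                    continue
                r = np.corrcoef(sources[:, k], E[e])[0, 1]
                if abs(r) > corr_threshold:
                    keep[k] = False
        sources[:, ~keep] = 0.0
        rebuilt = ica.inverse_transform(sources).T
        return rec.copy(samples=rebuilt + mean)
    raise ValueError(f"unknown method {method!r}")


def asr_clean(
    rec: Recording,
    calibration_interval: tuple[float, float],
    cutoff_sd: float = 20.0,
    window_s: float = 1.0,
) -> Recording:
    """Simplified artifact-subspace reconstruction.

    Calibration statistics (channel covariance) come from the given
    interval; in each sliding window, principal directions whose variance
    exceeds (cutoff_sd x calibration SD)^2 are removed and the window is
    reconstructed from the retained subspace.
    """
    c0, c1 = calibration_interval
    if c1 - c0 < 10.0:
        raise ValueError("calibration window must span at least 10 s")
    i0, i1 = rec.index_of(c0), rec.index_of(c1)
    calib = rec.samples[:, i0:i1]
    mean = calib.mean(axis=1, keepdims=True)
    cov = np.cov(calib - mean)
    evals, evecs = np.linalg.eigh(cov)
    # calibration SD along each principal direction
    calib_sd = np.sqrt(np.maximum(evals, 1e-12))

    w = max(int(round(window_s * rec.sample_rate_hz)), 4)
    out = rec.samples.copy()
    n = rec.n_samples
    for start in range(0, n, w):
        seg = out[:, start: start + w] - mean
        proj = evecs.T @ seg  # (k, t)
        seg_sd = proj.std(axis=1)
        bad = seg_sd > cutoff_sd * calib_sd
        if bad.any():
            proj[bad] = 0.0
            out[:, start: start + w] = evecs @ proj + mean
    return rec.copy(samples=out)


def welch_bandpower(
    rec: Recording,
    bands: dict[str, tuple[float, float]] | None = None,
    window_s: float = 2.0,
    hop_s: float = 1.0,
) -> BandPowerSeries:
    """Moving-window Welch band power.

    Per 2 s window, a Welch PSD (Hamming sub-segments, 50% overlap) is
    integrated over each band's [lo, hi) to give power in uV^2.
    """
    bands = dict(bands or DEFAULT_BANDS)
    fs = rec.sample_rate_hz
    nyq = fs / 2.0
    for name, (lo, hi) in bands.items():
        if hi > nyq or lo < 0 or lo >= hi:
            raise ValueError(f"band {name} [{lo}, {hi}) outside (0, Nyquist]")
    win = int(round(window_s * fs))
    if win < 2:
        raise ValueError("window too short")
    hop = max(int(round(hop_s * fs)), 1)
    n = rec.n_samples
    n_win = max((n - win) // hop + 1, 0)
    nperseg = max(win // 2, 8)
    centres = (np.arange(n_win) * hop + win / 2) / fs + rec.t0_s
    power = np.zeros((rec.n_channels, len(bands), n_win))
    band_items = list(bands.items())
    for wi in range(n_win):
        seg = rec.samples[:, wi * hop: wi * hop + win]
        f, psd = sps.welch(
            seg, fs=fs, window="hamming", nperseg=nperseg,
            noverlap=nperseg // 2, axis=1,
        )
        df = f[1] - f[0]
        for bi, (_, (lo, hi)) in enumerate(band_items):
            sel = (f >= lo) & (f < hi)
            power[:, bi, wi] = psd[:, sel].sum(axis=1) * df
    return BandPowerSeries(
        channel_labels=list(rec.channel_labels),
        band_names=[name for name, _ in band_items],
        power=power,
        window_times_s=centres,
        window_s=window_s,
        hop_s=hop_s,
    )


def ratio_features(bp: BandPowerSeries) -> dict[str, np.ndarray]:
    """Window-wise workload indices per channel.

    engagement = beta/(alpha+theta); theta_alpha = theta/alpha;
    theta_beta = theta/beta; ta_ba = (theta+alpha)/(beta+alpha).
    Windows with zero denominators come out NaN.
    """
    for required in ("theta", "alpha", "beta"):
        if required not in bp.band_names:
            raise ValueError(f"band {required} missing")
    theta, alpha, beta = bp.band("theta"), bp.band("alpha"), bp.band("beta")

    def safe_div(a, b):
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(b > 0, a / np.where(b > 0, b, 1.0), np.nan)

    return {
        "engagement": safe_div(beta, alpha + theta),
        "theta_alpha": safe_div(theta, alpha),
        "theta_beta": safe_div(theta, beta),
        "ta_ba": safe_div(theta + alpha, beta + alpha),
    }


def process(
    rec: Recording,
    design: list[BlockDesign],
    cfg: EegConfig | None = None,
    eog: Recording | None = None,
) -> tuple[BandPowerSeries, list[dict]]:
    """Full EEG chain for one task-session; returns the band-power series
    and long-format block-mean feature rows (288 measures/block)."""
    cfg = cfg or EegConfig()
    x = notch_filter(rec, cfg.notch_hz, cfg.notch_order, cfg.notch_halfwidth_hz)
    x = bandpass_filter(x, cfg.bandpass_lo_hz, cfg.bandpass_hi_hz,
                        cfg.bandpass_order)
    if eog is not None:
        x = remove_ocular_artifacts(
            x, eog, method=cfg.ocular_method,
            corr_threshold=cfg.ocular_corr_threshold,
        )
    if cfg.asr_enabled:
        first_block = min(b.t_start_s for b in design)
        x = asr_clean(x, (x.t0_s, x.t0_s + max(first_block, 10.0)),
                      cfg.asr_cutoff_sd)
    bp = welch_bandpower(x, window_s=cfg.welch_window_s, hop_s=cfg.welch_hop_s)
    ratios = ratio_features(bp)

    rows: list[dict] = []
    for block in design:
        sel = (bp.window_times_s >= block.t_start_s) & (
            bp.window_times_s < block.t_end_s
        )
        vals: dict[str, float] = {}
        for bi, band in enumerate(bp.band_names):
            for c, label in enumerate(bp.channel_labels):
                v = bp.power[c, bi, sel]
                vals[f"eeg.{band}.{label}"] = (
                    float(np.nanmean(v)) if v.size else float("nan")
                )
        for rname, arr in ratios.items():
            for c, label in enumerate(bp.channel_labels):
                v = arr[c, sel]
                good = np.isfinite(v)
                vals[f"eeg.{rname}.{label}"] = (
                    float(np.mean(v[good])) if good.any() else float("nan")
                )
        rows += feature_rows(block, "eeg", vals)
    return bp, rows
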