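"""Pipeline configuration.

One nested dataclass per processing stage; defaults are the published
processing parameters where the protocol states one (FIR order 20 /
0.1 Hz for fNIRS; order-8 notch at 60 Hz and order-7 1-59 Hz band-pass
for EEG; 2 s Welch windows; 0.04-0.15 / 0.15-0.4 Hz HRV bands; order-7
0.1-10 Hz PPG band-pass; alpha = 0.05) and conventional values
elsewhere.  Round-trips losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class FnirsConfig:
    fir_order: int = 20
    fir_cutoff_hz: float = 0.1
    smar_window_s: float = 4.0
    smar_spike_sd: float = 3.0
    saturation_low: float = 1e-6
    saturation_high: float = 4000.0
    # extinction coefficients in 1/(mM*cm), rows = (730, 850) nm,
    # cols = (HbO, HbR); standard adult tabulated values
    ext_730_hbo: float = 0.446
    ext_730_hbr: float = 1.1022
    ext_850_hbo: float = 1.058
    ext_850_hbr: float = 0.6917
    dpf_730: float = 6.0
    dpf_850: float = 6.0
    separation_cm: float = 2.5
    baseline_mode: str = "session"  # session | block


@dataclass
class EegConfig:
    notch_hz: float = 60.0
    notch_order: int = 8
    notch_halfwidth_hz: float = 2.0
    bandpass_lo_hz: float = 1.0
    bandpass_hi_hz: float = 59.0
    bandpass_order: int = 7
    welch_window_s: float = 2.0
    welch_hop_s: float = 1.0
    ocular_method: str = "regression"  # regression | ica
    ocular_corr_threshold: float = 0.7
    asr_enabled: bool = False
    asr_cutoff_sd: float = 20.0


@dataclass
class CardiacConfig:
    hrv_lf_lo_hz: float = 0.04
    hrv_lf_hi_hz: float = 0.15
    hrv_hf_lo_hz: float = 0.15
    hrv_hf_hi_hz: float = 0.40
    tachogram_rate_hz: float = 4.0
    ppg_bandpass_lo_hz: float = 0.1
    ppg_bandpass_hi_hz: float = 10.0
    ppg_bandpass_order: int = 7
    rr_min_ms: float = 250.0
    rr_max_ms: float = 3000.0
    rr_deviation_frac: float = 0.3


@dataclass
class OcularConfig:
    eog_uv_per_deg: float = 10.0  # shared with the generator: closes the units loop
    sg_window_ms: float = 20.0
    accel_threshold_k: float = 3.4
    accel_sd_window_s: float = 2.0
    pair_max_gap_ms: float = 100.0
    merge_gap_ms: float = 80.0
    idt_dispersion_deg: float = 1.0
    idt_min_duration_ms: float = 100.0
    blink_max_interp_ms: float = 500.0


@dataclass
class StatsConfig:
    alpha: float = 0.05
    residual_structure: str = "by_cell"  # by_cell | pooled
    pca_n_repeats: int = 30
    max_rows_per_modality: int = 5


@dataclass
class SynthConfig:
    n_subjects: int = 23
    block_duration_s: float = 40.0
    block_gap_s: float = 10.0
    baseline_s: float = 30.0
    hemo_amplitude_uM: float = 1.0
    hemo_session_slope: float = -0.15  # learning: response shrinks per session
    hemo_condition_boost: float = 0.4  # hard > easy
    eeg_theta_condition_boost: float = 0.3
    eeg_alpha_session_slope: float = 0.2
    mean_rr_ms: float = 850.0
    rr_condition_shift_ms: float = -40.0
    rr_lf_hf_ratio: float = 1.5
    saccade_rate_hz: float = 2.0
    saccade_amplitude_mean_deg: float = 5.0
    pupil_mean_mm: float = 4.0
    pupil_condition_boost_mm: float = 0.3
    rt_mean_s: float = 0.9
    rt_session_slope: float = -0.08
    rt_condition_boost: float = 0.15
    accuracy_base: float = 0.88
    accuracy_condition_drop: float = -0.10


@dataclass
class PipelineConfig:
    seed: int = 1
    synth: SynthConfig = field(default_factory=SynthConfig)
    fnirs: FnirsConfig = field(default_factory=FnirsConfig)
    eeg: EegConfig = field(default_factory=EegConfig)
    cardiac: CardiacConfig = field(default_factory=CardiacConfig)
    ocular: OcularConfig = field(default_factory=OcularConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs: dict = {"seed": d.get("seed", 1)}
        for name, sub in [
            ("synth", SynthConfig),
            ("fnirs", FnirsConfig),
            ("eeg", EegConfig),
            ("cardiac", CardiacConfig),
            ("ocular", OcularConfig),
            ("stats", StatsConfig),
        ]:
            kwargs[name] = sub(**d.get(name, {}))
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
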