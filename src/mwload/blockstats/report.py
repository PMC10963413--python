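"""Standardised report-row selection.

Mirrors the published tables' selection rule: at most five rows per
modality; fNIRS and EEG rows must survive the grouped FDR correction;
rows are ordered by partial eta^2 descending; and each factor with at
least one significant result contributes at least one row when
available.
"""

from __future__ import annotations

import pandas as pd

from .lmm import EffectResult, FACTORS

MULTICHANNEL = ("fnirs", "eeg")


def _modality(measure_name: str) -> str:
    return measure_name.split(".")[0]


def _eligible(r: EffectResult, alpha: float) -> bool:
    if _modality(r.measure_name) in MULTICHANNEL:
        return r.fdr_significant
    return r.p <= alpha


def select_report_rows(
    results: list[EffectResult],
    max_per_modality: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply the selection rule; returns a table with the published
    column layout (Measure, Factor, F-ratio, df, p-value, partial eta^2)."""
    by_mod: dict[str, list[EffectResult]] = {}
    for r in results:
        by_mod.setdefault(_modality(r.measure_name), []).append(r)

    chosen: list[EffectResult] = []
    for mod, rows in by_mod.items():
        sig = [r for r in rows if _eligible(r, alpha)]
        sig.sort(key=lambda r: r.partial_eta2, reverse=True)
        picked: list[EffectResult] = []
        # one row per significant factor first, in eta^2 order
        for factor in FACTORS:
            fac = [r for r in sig if r.factor == factor]
            if fac and len(picked) < max_per_modality:
                picked.append(fac[0])
        for r in sig:
            if len(picked) >= max_per_modality:
                break
            if r not in picked:
                picked.append(r)
        picked.sort(key=lambda r: r.partial_eta2, reverse=True)
        chosen.extend(picked)

    return pd.DataFrame(
        [
            {
                "modality": _modality(r.measure_name),
                "measure": r.measure_name,
                "factor": r.factor,
                "F": r.F,
                "df": f"{r.df_num:.0f}/{r.df_den:.1f}",
                "p": r.p,
                "partial_eta2": r.partial_eta2,
                "fdr_significant": r.fdr_significant,
            }
            for r in chosen
        ]
    )
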