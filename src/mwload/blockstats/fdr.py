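"""Benjamini-Hochberg false-discovery-rate control, grouped.

The correction is applied independently within groups (for the
multichannel modalities: one group per data-type family and factor,
i.e. all 16 optodes of "HbO peak / session" are corrected together,
all 32 electrodes of "alpha power / session" together, and so on).
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .lmm import EffectResult


def bh_fdr(
    p_values: list[float],
    alpha: float = 0.05,
    groups: list | None = None,
) -> list[bool]:
    """Step-up BH procedure within each group.

    Within a group of m p-values sorted ascending, find the largest rank
    i with p_(i) <= (i/m) * alpha and flag every rank up to i.  Ties are
    handled stably (equal p-values share a fate).  Returns flags in the
    original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if groups is None:
        groups = [0] * p.size
    if len(groups) != p.size:
        raise ValueError("groups must parallel p_values")
    flags = np.zeros(p.size, dtype=bool)
    by_group: dict = defaultdict(list)
    for i, g in enumerate(groups):
        by_group[g].append(i)
    for idxs in by_group.values():
        sub = p[idxs]
        m = sub.size
        order = np.argsort(sub, kind="stable")
        thresh = (np.arange(1, m + 1) / m) * alpha
        passed = sub[order] <= thresh
        if passed.any():
            k = int(np.max(np.flatnonzero(passed)))
            cut = sub[order][k]
            for i in idxs:
                flags[i] = p[i] <= cut
    return flags.tolist()


def fdr_group_key(measure_name: str, factor: str) -> str:
    """Group id for the grouped correction: modality + data-type family
    + factor, with the channel identifier stripped.

    Measure names are namespaced ``modality.type.channel[.stat]``
    (e.g. ``fnirs.HbO.opt02.peak`` -> ``fnirs.HbO.peak:session``;
    ``eeg.alpha.PO1`` -> ``eeg.alpha:session``).  Non-multichannel
    measures each form their own group.
    """
    parts = measure_name.split(".")
    if parts[0] == "fnirs" and len(parts) == 4:
        fam = f"{parts[0]}.{parts[1]}.{parts[3]}"
    elif parts[0] == "eeg" and len(parts) == 3:
        fam = f"{parts[0]}.{parts[1]}"
    else:
        fam = measure_name
    return f"{fam}:{factor}"


def apply_fdr(
    results: list[EffectResult], alpha: float = 0.05
) -> list[EffectResult]:
    """Annotate EffectResults in place with grouped BH flags.

    Only fNIRS and EEG families span channels and get a real grouped
    correction; other modalities form singleton groups (their flag then
    equals p <= alpha)."""
    keys = [fdr_group_key(r.measure_name, r.factor) for r in results]
    flags = bh_fdr([r.p for r in results], alpha=alpha, groups=keys)
    for r, k, f in zip(results, keys, flags):
        r.fdr_group = k
        r.fdr_significant = bool(f)
    return results
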