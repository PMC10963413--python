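"""Repeated-PCA variance partition across modalities.

All block x measure observations for a task are assembled into a wide
matrix, z-scored, and the correlation matrix eigendecomposed; the
components with eigenvalue > 1 (Kaiser criterion) are retained.  The
retained eigenvalues give the explained share of total variance, and
each modality's slice of that variance is the eigenvalue-weighted sum
of its features' squared loadings.  The procedure repeats over seeded
bootstrap resamples of the observations (rows), which is what makes the
mean component count non-integer and stabilises the shares; reported
numbers are means over the repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INDEX_COLS = ["subject_id", "task_name", "task_session", "condition",
              "block_index"]


@dataclass
class PcaSummary:
    n_components_mean: float
    total_variance_explained_pct: float
    modality_share_pct: dict[str, float]
    n_repeats: int = 30
    n_rows: int = 0
    n_features: int = 0
    #: per-repeat share traces (modality -> list of %), for diagnostics
    repeat_shares_pct: dict[str, list[float]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        total = sum(self.modality_share_pct.values())
        if self.modality_share_pct and abs(total - 100.0) > 0.1:
            raise ValueError(f"modality shares sum to {total}, not 100")


def _wide_matrix(
    table: pd.DataFrame, feature_subset: list[str] | None
) -> tuple[np.ndarray, list[str], list[str]]:
    sub = table
    if feature_subset is not None:
        sub = table[table["measure_name"].isin(feature_subset)]
    modality_of = dict(
        zip(sub["measure_name"], sub["modality"])
    )
    wide = sub.pivot_table(
        index=INDEX_COLS, columns="measure_name", values="value",
        aggfunc="mean",
    )
    # impute column means; degenerate (constant) columns are kept and
    # standardise to all-zero, contributing nothing to any component
    wide = wide.apply(lambda c: c.fillna(c.mean()))
    feats = list(wide.columns)
    mods = [modality_of[f] for f in feats]
    return wide.to_numpy(dtype=float), feats, mods


class ModalityPCA:
    """Model object for the repeated variance partition.

    Parameters
    ----------
    table : long-format feature table
    feature_subset : optional list of measure names entering the PCA
        (the multichannel modalities are typically subset before PCA)
    n_repeats : bootstrap repeats (default 30)
    """

    def __init__(self, table: pd.DataFrame,
                 feature_subset: list[str] | None = None,
                 n_repeats: int = 30):
        self.X, self.features, self.modalities = _wide_matrix(
            table, feature_subset
        )
        if self.X.shape[1] < 2:
            raise ValueError("need at least 2 usable features")
        per_mod = pd.Series(self.modalities).value_counts()
        if (per_mod < 2).any():
            small = per_mod[per_mod < 2].index.tolist()
            raise ValueError(f"modalities with <2 features: {small}")
        self.n_repeats = n_repeats

    def fit(self, seed: int = 0) -> PcaSummary:
        n, m = self.X.shape
        if m > n:
            import warnings

            warnings.warn(
                f"{m} features > {n} rows: shares computed on a "
                "rank-deficient correlation matrix"
            )
        rng = np.random.default_rng(seed)
        mods = np.asarray(self.modalities)
        uniq = sorted(set(self.modalities))
        n_comp, tot_var = [], []
        shares = {u: [] for u in uniq}
        for _ in range(self.n_repeats):
            rows = rng.integers(0, n, size=n)
            Xb = self.X[rows]
            sd = Xb.std(axis=0, ddof=0)
            sd[sd < 1e-12] = 1.0
            Z = (Xb - Xb.mean(axis=0)) / sd
            corr = (Z.T @ Z) / n
            evals, evecs = np.linalg.eigh(corr)
            order = np.argsort(evals)[::-1]
            evals, evecs = evals[order], evecs[:, order]
            retained = evals > 1.0
            k = int(retained.sum())
            if k == 0:
                retained[0] = True
                k = 1
            lam = evals[retained]
            V = evecs[:, retained]
            n_comp.append(k)
            tot_var.append(100.0 * lam.sum() / m)
            # eigenvalue-weighted squared loadings per modality
            contrib = (V**2) * lam[None, :]  # feature x component
            per_feat = contrib.sum(axis=1)
            total = per_feat.sum()
            for u in uniq:
                shares[u].append(100.0 * per_feat[mods == u].sum() / total)
        mean_shares = {u: float(np.mean(v)) for u, v in shares.items()}
        # exact normalisation against accumulated rounding
        s = sum(mean_shares.values())
        mean_shares = {u: v * 100.0 / s for u, v in mean_shares.items()}
        return PcaSummary(
            n_components_mean=float(np.mean(n_comp)),
            total_variance_explained_pct=float(np.mean(tot_var)),
            modality_share_pct=mean_shares,
            n_repeats=self.n_repeats,
            n_rows=n,
            n_features=m,
            repeat_shares_pct={u: [float(x) for x in v]
                               for u, v in shares.items()},
        )


def pca_variance_partition(
    table: pd.DataFrame,
    feature_subset: list[str] | None = None,
    n_repeats: int = 30,
    seed: int = 0,
) -> PcaSummary:
    """Functional wrapper over :class:`ModalityPCA`."""
    return ModalityPCA(table, feature_subset, n_repeats).fit(seed)
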