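"""Per-measure linear mixed models for the block feature table.

Model, for one workload measure y over blocks:

    y = intercept + session + condition + session:condition
        + subject (random intercept, variance tau^2)
        + residual,  residual ~ N(0, sigma^2_cell)

with a *diagonal* residual covariance whose variance is heterogeneous
across the session x condition cells (the "diagonal covariance
pattern"); a pooled homogeneous residual is the fallback when the
heterogeneous fit does not converge.  Estimation is REML with the
fixed effects profiled out; the per-subject block structure of V is
exploited in closed form (rank-one Woodbury update of the diagonal).

F-tests per factor use effects (sum-to-zero) coding, so each factor's
coefficients test the marginal (type-III) hypothesis, with
Satterthwaite-approximated denominator degrees of freedom: for a
multi-df factor the contrast covariance is eigendecomposed, each
1-df component gets df_i = 2 f_i^2 / (grad f_i' W grad f_i) with W the
asymptotic covariance of the variance parameters, and the components
combine through E = sum df_i/(df_i - 2), df = 2E/(E - q).

Effect size: partial eta^2 = F*df1 / (F*df1 + df2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools import numdiff

FACTORS = ("session", "condition", "interaction")


class SingularFitError(RuntimeError):
    """Raised when a measure cannot support the mixed model (for example a
    zero-variance response)."""


def partial_eta_squared(F: float, df_num: float, df_den: float) -> float:
    """partial eta^2 = F*df_num / (F*df_num + df_den)."""
    if df_num <= 0 or df_den <= 0:
        raise ValueError("degrees of freedom must be positive")
    if F < 0:
        raise ValueError("F must be non-negative")
    return F * df_num / (F * df_num + df_den)


@dataclass
class EffectResult:
    """One factor's F-test for one measure (a table row)."""

    measure_name: str
    factor: str  # session | condition | interaction
    F: float
    df_num: float
    df_den: float
    p: float
    partial_eta2: float
    fdr_significant: bool = False
    fdr_group: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.F) and self.F >= 0 and self.df_den > 0:
            expected = partial_eta_squared(self.F, self.df_num, self.df_den)
            if abs(expected - self.partial_eta2) > 1e-6:
                raise ValueError("partial_eta2 inconsistent with F and dfs")


_RESULT_COLUMNS = ("measure_name", "factor", "F", "df_num", "df_den", "p",
                   "partial_eta2", "fdr_significant", "fdr_group")


def results_to_frame(results: list[EffectResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [vars(r) for r in results], columns=list(_RESULT_COLUMNS)
    )


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _effects_code(values: np.ndarray, levels: list) -> np.ndarray:
    """Sum-to-zero coding: one column per non-reference level; the last
    level carries -1 in every column."""
    cols = []
    for lev in levels[:-1]:
        col = np.where(values == lev, 1.0, 0.0)
        col = np.where(values == levels[-1], -1.0, col)
        cols.append(col)
    return np.column_stack(cols) if cols else np.zeros((values.size, 0))


@dataclass
class _Design:
    y: np.ndarray
    X: np.ndarray
    subj_idx: np.ndarray
    cell_idx: np.ndarray
    n_cells: int
    factor_cols: dict[str, list[int]]
    subjects: list


def _build_design(df: pd.DataFrame) -> _Design:
    sessions = sorted(df["task_session"].unique())
    conditions = sorted(df["condition"].unique())
    if len(conditions) < 2:
        raise SingularFitError("both conditions required")
    if len(sessions) < 2:
        raise SingularFitError("at least two sessions required")
    S = _effects_code(df["task_session"].to_numpy(), sessions)
    C = _effects_code(df["condition"].to_numpy(), conditions)
    inter = np.column_stack(
        [S[:, i] * C[:, j] for i in range(S.shape[1]) for j in range(C.shape[1])]
    )
    X = np.column_stack([np.ones(len(df)), S, C, inter])
    p_s, p_c = S.shape[1], C.shape[1]
    factor_cols = {
        "session": list(range(1, 1 + p_s)),
        "condition": list(range(1 + p_s, 1 + p_s + p_c)),
        "interaction": list(range(1 + p_s + p_c, 1 + p_s + p_c + p_s * p_c)),
    }
    subjects = sorted(df["subject_id"].unique())
    if len(subjects) < 2:
        raise SingularFitError("at least two subjects required")
    subj_idx = df["subject_id"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
    cells = list(
        dict.fromkeys(zip(df["task_session"], df["condition"]))
    )
    cell_map = {c: i for i, c in enumerate(sorted(cells))}
    cell_idx = np.array(
        [cell_map[c] for c in zip(df["task_session"], df["condition"])]
    )
    return _Design(
        y=df["value"].to_numpy(dtype=float),
        X=X,
        subj_idx=subj_idx,
        cell_idx=cell_idx,
        n_cells=len(cell_map),
        factor_cols=factor_cols,
        subjects=subjects,
    )


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

class _Reml:
    """Profiled REML for the random-intercept + diagonal-residual model.

    theta = [log tau^2, log sigma^2_1 ... log sigma^2_C] (C=1 pooled).
    """

    def __init__(self, design: _Design, n_res: int):
        d = design
        self.d = d
        self.n_res = n_res
        self.groups = [np.flatnonzero(d.subj_idx == i)
                       for i in range(len(d.subjects))]
        self.p = d.X.shape[1]
        self.n = d.y.size

    def _res_var(self, theta: np.ndarray) -> np.ndarray:
        sig = np.exp(theta[1:])
        if self.n_res == 1:
            return np.full(self.d.n_cells, sig[0])
        return sig

    def _assemble(self, theta: np.ndarray):
        """Return (A, r, q, logdet_sum) for V = diag(sig_cell) + tau^2 J."""
        tau2 = np.exp(theta[0])
        sig = self._res_var(theta)[self.d.cell_idx]
        A = np.zeros((self.p, self.p))
        r = np.zeros(self.p)
        q = 0.0
        logdet = 0.0
        X, y = self.d.X, self.d.y
        for g in self.groups:
            di = 1.0 / sig[g]  # D^-1 diagonal
            u = di.sum()
            c = tau2 / (1.0 + tau2 * u)
            Xg, yg = X[g], y[g]
            Xd = Xg * di[:, None]
            xs = Xd.sum(axis=0)  # X' D^-1 1
            ys = float((yg * di).sum())
            A += Xg.T @ Xd - c * np.outer(xs, xs)
            r += Xd.T @ yg - c * xs * ys
            q += float((yg**2 * di).sum()) - c * ys * ys
            logdet += float(np.log(sig[g]).sum() + np.log1p(tau2 * u))
        return A, r, q, logdet

    def neg_loglik(self, theta: np.ndarray) -> float:
        try:
            A, r, q, logdet = self._assemble(theta)
            sign, logdetA = np.linalg.slogdet(A)
            if sign <= 0:
                return 1e10
            beta = np.linalg.solve(A, r)
            ypy = q - float(r @ beta)
            if ypy <= 0:
                return 1e10
            return 0.5 * (logdet + logdetA + ypy)
        except np.linalg.LinAlgError:
            return 1e10

    def beta_cov(self, theta: np.ndarray):
        A, r, _, _ = self._assemble(theta)
        C = np.linalg.inv(A)
        return C @ r, C

    def fit(self):
        d = self.d
        # moment starting values on the standardised response
        resid0 = d.y - d.X @ np.linalg.lstsq(d.X, d.y, rcond=None)[0]
        v0 = max(float(np.var(resid0)), 1e-6)
        theta0 = np.concatenate(
            [[np.log(max(0.3 * v0, 1e-6))],
             np.full(self.n_res, np.log(max(0.7 * v0, 1e-6)))]
        )
        res = optimize.minimize(
            self.neg_loglik, theta0, method="L-BFGS-B",
            bounds=[(-14.0, 8.0)] * theta0.size,
            options={"maxiter": 200},
        )
        return res


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class WorkloadLMM:
    """Mixed model for one measure of the block feature table.

    Parameters
    ----------
    data : DataFrame with columns subject_id, task_session, condition, value
    residual_structure : "by_cell" (heterogeneous diagonal, default) or
        "pooled"
    """

    def __init__(self, data: pd.DataFrame, measure_name: str = "",
                 residual_structure: str = "by_cell"):
        data = data.dropna(subset=["value"])
        if data.empty:
            raise SingularFitError("no observations")
        y = data["value"].to_numpy(dtype=float)
        if np.std(y) < 1e-12:
            raise SingularFitError(f"zero-variance response: {measure_name}")
        self.measure_name = measure_name
        self.residual_structure = residual_structure
        self.data = data.reset_index(drop=True)
        self.design = _build_design(self.data)

    @classmethod
    def from_feature_table(
        cls, table: pd.DataFrame, measure_name: str,
        residual_structure: str = "by_cell",
    ) -> "WorkloadLMM":
        sub = table[table["measure_name"] == measure_name]
        return cls(sub, measure_name, residual_structure)

    def fit(self) -> "WorkloadLMMResults":
        d = self.design
        scale = float(np.std(d.y))
        d_std = _Design(
            y=(d.y - d.y.mean()) / scale, X=d.X, subj_idx=d.subj_idx,
            cell_idx=d.cell_idx, n_cells=d.n_cells,
            factor_cols=d.factor_cols, subjects=d.subjects,
        )
        structures = (
            ["by_cell", "pooled"] if self.residual_structure == "by_cell"
            else ["pooled"]
        )
        last_exc = None
        for structure in structures:
            n_res = d.n_cells if structure == "by_cell" else 1
            reml = _Reml(d_std, n_res)
            res = reml.fit()
            if res.success or res.fun < 1e9:
                return WorkloadLMMResults(
                    model=self, reml=reml, theta=res.x,
                    converged=bool(res.success),
                    structure=structure,
                    fallback=(structure != self.residual_structure),
                    scale=scale,
                )
            last_exc = res
        raise SingularFitError(
            f"mixed model did not converge for {self.measure_name}: {last_exc}"
        )


class WorkloadLMMResults:
    """Fitted mixed model: variance components, fixed effects and the
    per-factor F-tests (Satterthwaite denominator df)."""

    def __init__(self, model: WorkloadLMM, reml: _Reml, theta: np.ndarray,
                 converged: bool, structure: str, fallback: bool,
                 scale: float):
        self.model = model
        self._reml = reml
        self.theta = theta
        self.converged = converged
        self.structure = structure
        self.fallback = fallback
        self.scale = scale
        self.params, self.cov_params = reml.beta_cov(theta)
        # asymptotic covariance of theta from the observed information
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            H = numdiff.approx_hess1(theta, reml.neg_loglik)
        try:
            self.theta_cov = np.linalg.pinv(0.5 * (H + H.T))
        except np.linalg.LinAlgError:
            self.theta_cov = np.full((theta.size, theta.size), np.nan)

    @property
    def tau2(self) -> float:
        """Subject random-intercept variance (response units^2)."""
        return float(np.exp(self.theta[0])) * self.scale**2

    @property
    def residual_variances(self) -> np.ndarray:
        return np.exp(self.theta[1:]) * self.scale**2

    # -- Satterthwaite ---------------------------------------------------
    def _vc_fun(self, ell: np.ndarray):
        reml = self._reml

        def f(th):
            _, C = reml.beta_cov(th)
            return float(ell @ C @ ell)

        return f

    def f_test(self, factor: str) -> EffectResult:
        d = self.model.design
        cols = d.factor_cols[factor]
        L = np.zeros((len(cols), d.X.shape[1]))
        for i, c in enumerate(cols):
            L[i, c] = 1.0
        q = L.shape[0]
        C = self.cov_params
        M = L @ C @ L.T
        evals, evecs = np.linalg.eigh(M)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        Lb = L @ self.params
        F = float(Lb @ np.linalg.solve(M, Lb)) / q

        # per-component Satterthwaite df
        nus = []
        for i in range(q):
            lam = evals[i]
            if lam <= 0:
                continue
            ell = evecs[:, i] @ L
            fi = self._vc_fun(ell)
            g = numdiff.approx_fprime(self.theta, fi, centered=True)
            denom = float(g @ self.theta_cov @ g)
            nu = 2.0 * lam**2 / denom if denom > 0 else np.inf
            nus.append(nu)
        if not nus:
            raise SingularFitError("degenerate contrast covariance")
        finite = [nu for nu in nus if np.isfinite(nu)]
        if q == 1:
            df_den = nus[0] if np.isfinite(nus[0]) else float(self._reml.n)
        else:
            E = sum(nu / (nu - 2.0) for nu in nus if nu > 2.0 and np.isfinite(nu))
            df_den = 2.0 * E / (E - q) if E > q else float(self._reml.n)
        if not np.isfinite(df_den) or df_den <= 0:
            df_den = float(self._reml.n - self._reml.p)
        p = float(stats.f.sf(F, q, df_den))
        return EffectResult(
            measure_name=self.model.measure_name,
            factor=factor,
            F=F,
            df_num=float(q),
            df_den=df_den,
            p=p,
            partial_eta2=partial_eta_squared(F, q, df_den),
        )

    @property
    def effects(self) -> list[EffectResult]:
        return [self.f_test(f) for f in FACTORS]

    def summary(self) -> str:
        lines = [
            f"Workload mixed model: {self.model.measure_name or '(unnamed)'}",
            f"  n obs: {self._reml.n}   subjects: {len(self.model.design.subjects)}",
            f"  residual structure: {self.structure}"
            + ("  [fallback]" if self.fallback else ""),
            f"  REML converged: {self.converged}",
            f"  subject variance tau^2: {self.tau2:.4g}",
            "  residual variances: "
            + ", ".join(f"{v:.4g}" for v in self.residual_variances),
            "",
            f"  {'factor':<12} {'F':>8} {'df':>12} {'p':>10} {'peta2':>7}",
        ]
        for r in self.effects:
            lines.append(
                f"  {r.factor:<12} {r.F:>8.2f} "
                f"{r.df_num:.0f}/{r.df_den:<8.1f} {r.p:>10.6f} "
                f"{r.partial_eta2:>7.3f}"
            )
        return "\n".join(lines)


def fit_lmm(
    table: pd.DataFrame,
    measure_name: str,
    residual_structure: str = "by_cell",
) -> list[EffectResult]:
    """Session/condition/interaction F-tests for one measure.

    Raises SingularFitError for degenerate measures (zero variance,
    missing conditions); callers iterating many measures should catch it
    and log the skip.
    """
    model = WorkloadLMM.from_feature_table(
        table, measure_name, residual_structure
    )
    return model.fit().effects


def fit_all_measures(
    table: pd.DataFrame, residual_structure: str = "by_cell",
    progress: bool = False,
) -> tuple[list[EffectResult], list[str]]:
    """Fit every measure in the table; returns (results, skipped names)."""
    results: list[EffectResult] = []
    skipped: list[str] = []
    measures = table["measure_name"].unique()
    for m in measures:
        try:
            results.extend(fit_lmm(table, m, residual_structure))
        except SingularFitError as exc:
            warnings.warn(f"skipping {m}: {exc}")
            skipped.append(m)
    return results, skipped
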