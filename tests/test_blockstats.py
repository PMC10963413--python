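"""Statistical layer: mixed models, effect sizes, FDR, PCA partition,
report-row selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mwload.blockstats import (
    EffectResult,
    ModalityPCA,
    SingularFitError,
    WorkloadLMM,
    apply_fdr,
    bh_fdr,
    fit_lmm,
    partial_eta_squared,
    pca_variance_partition,
    select_report_rows,
)
from conftest import make_lmm_table


class TestPartialEtaSquared:
    @pytest.mark.parametrize(
        "F,d1,d2,expected",
        [
            (125.63, 1, 374.9, 0.251),
            (39.59, 2, 380.4, 0.172),
            (7.81, 1, 380.0, 0.020),
            (160.49, 1, 383.2, 0.295),
        ],
    )
    def test_published_rows_reconstructed(self, F, d1, d2, expected):
        assert round(partial_eta_squared(F, d1, d2), 3) == expected

    def test_zero_effect(self):
        assert partial_eta_squared(0.0, 2, 100) == 0.0

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            partial_eta_squared(1.0, 0, 10)

    def test_effect_result_identity_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            EffectResult("m", "session", F=10.0, df_num=2, df_den=100,
                         p=0.001, partial_eta2=0.9)


class TestWorkloadLMM:
    def test_matches_anova_when_no_subject_variance(self):
        # degenerate limit: zero subject variance, balanced design ->
        # mixed-model F equals the two-way fixed-effects (type III) F
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(42)
        tbl = make_lmm_table(rng, subject_sd=0.0, condition_effect=0.5)
        res = WorkloadLMM.from_feature_table(
            tbl, "m", residual_structure="pooled"
        ).fit()
        ols = smf.ols(
            "value ~ C(task_session, Sum)*C(condition, Sum)", data=tbl
        ).fit()
        a = anova_lm(ols, typ=3)
        pairs = {
            "session": "C(task_session, Sum)",
            "condition": "C(condition, Sum)",
            "interaction": "C(task_session, Sum):C(condition, Sum)",
        }
        for factor, key in pairs.items():
            r = res.f_test(factor)
            assert r.F == pytest.approx(a.loc[key, "F"], rel=0.01)

    def test_recovers_condition_effect(self):
        rng = np.random.default_rng(1)
        tbl = make_lmm_table(rng, condition_effect=1.0)
        results = fit_lmm(tbl, "m")
        by_factor = {r.factor: r for r in results}
        assert by_factor["condition"].p < 0.01
        assert by_factor["condition"].partial_eta2 > 0.05

    def test_satterthwaite_df_fractional_and_bounded(self):
        rng = np.random.default_rng(2)
        tbl = make_lmm_table(rng, subject_sd=1.0)
        for r in fit_lmm(tbl, "m"):
            assert 2.0 < r.df_den < len(tbl)
            assert r.df_num in (1.0, 2.0)
            assert 0 <= r.partial_eta2 < 1
            assert r.partial_eta2 == pytest.approx(
                r.F * r.df_num / (r.F * r.df_num + r.df_den), abs=1e-6
            )

    def test_zero_variance_rejected(self):
        rng = np.random.default_rng(3)
        tbl = make_lmm_table(rng)
        tbl["value"] = 1.0
        with pytest.raises(SingularFitError):
            fit_lmm(tbl, "m")

    def test_requires_both_conditions(self):
        rng = np.random.default_rng(4)
        tbl = make_lmm_table(rng)
        with pytest.raises(SingularFitError):
            fit_lmm(tbl[tbl.condition == "easy"], "m")

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        tbl = make_lmm_table(rng)
        r1 = fit_lmm(tbl, "m")
        r2 = fit_lmm(tbl, "m")
        assert [(r.F, r.df_den, r.p) for r in r1] == [
            (r.F, r.df_den, r.p) for r in r2
        ]

    def test_summary_renders(self):
        rng = np.random.default_rng(6)
        tbl = make_lmm_table(rng)
        s = WorkloadLMM.from_feature_table(tbl, "m").fit().summary()
        assert "session" in s and "REML" in s


def _bh_bruteforce(p, alpha=0.05):
    """Literal step-up definition, evaluated from the largest rank down."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k_star = 0
    for k in range(m, 0, -1):
        if p[order[k - 1]] <= k / m * alpha:
            k_star = k
            break
    flags = [False] * m
    for rank in range(k_star):
        flags[order[rank]] = True
    return flags


class TestBhFdr:
    def test_textbook_examples(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == [True] * 4
        assert bh_fdr([0.9, 0.8, 0.7]) == [False] * 3
        assert bh_fdr([0.001]) == [True]
        assert bh_fdr([]) == []

    def test_matches_bruteforce_definition(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            m = int(rng.integers(1, 13))
            p = np.round(rng.random(m), 3).tolist()
            assert bh_fdr(p) == _bh_bruteforce(p)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.random(int(rng.integers(2, 40)))
            ours = bh_fdr(p.tolist())
            theirs = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert ours == theirs.tolist()

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_bruteforce_property(self, p):
        assert bh_fdr(p) == _bh_bruteforce(p)

    def test_groups_independent(self):
        p = [0.01, 0.4, 0.01, 0.9]
        flags = bh_fdr(p, groups=["a", "a", "b", "b"])
        assert flags == [True, False, True, False]
        # same values, one group: 0.01s still pass, others fail
        assert bh_fdr(p) == [True, False, True, False]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_tie_stability(self):
        p = [0.03, 0.03, 0.03, 0.9]
        flags = bh_fdr(p)
        assert flags[0] == flags[1] == flags[2]


class TestApplyFdr:
    def test_groups_by_family_and_factor(self):
        results = []
        for opt in range(16):
            for factor, p in (("session", 0.001), ("condition", 0.5)):
                F = 20.0 if p < 0.1 else 0.5
                d1 = 2.0 if factor == "session" else 1.0
                results.append(EffectResult(
                    f"fnirs.HbO.opt{opt:02d}.peak", factor, F, d1, 100.0, p,
                    partial_eta_squared(F, d1, 100.0),
                ))
        apply_fdr(results)
        groups = {r.fdr_group for r in results}
        assert groups == {"fnirs.HbO.peak:session", "fnirs.HbO.peak:condition"}
        assert all(r.fdr_significant for r in results if r.factor == "session")
        assert not any(
            r.fdr_significant for r in results if r.factor == "condition"
        )


class TestPcaPartition:
    def _table(self, var_a=3.0, var_b=1.0, n=120, seed=3, noise=0.3):
        rng = np.random.default_rng(seed)
        la = rng.normal(0, np.sqrt(var_a), n)
        lb = rng.normal(0, np.sqrt(var_b), n)
        rows = []
        for i in range(n):
            for j in range(6):
                for mod, lat in (("A", la[i]), ("B", lb[i])):
                    rows.append(dict(
                        subject_id=f"s{i % 10}", task_name="T",
                        task_session=i % 3 + 1,
                        condition="easy" if i % 2 else "hard",
                        block_index=i, modality=mod,
                        measure_name=f"{mod}{j}",
                        value=lat + rng.normal(0, noise),
                    ))
        return pd.DataFrame(rows)

    def test_shares_sum_to_100(self):
        summ = pca_variance_partition(self._table(), n_repeats=10, seed=1)
        assert sum(summ.modality_share_pct.values()) == pytest.approx(
            100.0, abs=0.1
        )

    def test_injected_variance_ordering_every_repeat(self):
        summ = pca_variance_partition(self._table(), n_repeats=30, seed=1)
        a = np.array(summ.repeat_shares_pct["A"])
        b = np.array(summ.repeat_shares_pct["B"])
        assert (a > b).all()

    def test_single_structured_modality_dominates(self):
        # modality B degenerate (constant): standardises to zero columns
        tbl = self._table(var_a=3.0, var_b=0.0, noise=0.3)
        tbl.loc[tbl.modality == "B", "value"] = 7.0
        summ = pca_variance_partition(tbl, n_repeats=10, seed=2)
        assert summ.modality_share_pct["A"] > 99.0

    def test_scale_invariance(self):
        tbl = self._table()
        summ1 = pca_variance_partition(tbl, n_repeats=10, seed=5)
        tbl2 = tbl.copy()
        tbl2.loc[tbl2.modality == "A", "value"] *= 1000.0
        summ2 = pca_variance_partition(tbl2, n_repeats=10, seed=5)
        for mod in summ1.modality_share_pct:
            assert summ1.modality_share_pct[mod] == pytest.approx(
                summ2.modality_share_pct[mod], abs=1e-6
            )

    def test_seed_determinism(self):
        tbl = self._table()
        s1 = pca_variance_partition(tbl, n_repeats=5, seed=7)
        s2 = pca_variance_partition(tbl, n_repeats=5, seed=7)
        assert s1.modality_share_pct == s2.modality_share_pct

    def test_feature_subset_respected(self):
        tbl = self._table()
        subset = [f"A{j}" for j in range(6)] + [f"B{j}" for j in range(3)]
        model = ModalityPCA(tbl, feature_subset=subset)
        assert model.X.shape[1] == 9

    def test_too_few_features_rejected(self):
        tbl = self._table()
        with pytest.raises(ValueError):
            ModalityPCA(tbl, feature_subset=["A0", "B0"])


def _mk_result(mod, i, factor, F, p, fdr=True):
    d1 = 2.0 if factor != "condition" else 1.0
    return EffectResult(
        f"{mod}.x.ch{i:02d}" + (".peak" if mod == "fnirs" else ""),
        factor, F, d1, 300.0, p,
        partial_eta_squared(F, d1, 300.0),
        fdr_significant=fdr,
    )


class TestSelectReportRows:
    def test_caps_at_five_descending(self):
        results = [
            _mk_result("eeg", i, "session", float(5 + i), 0.001)
            for i in range(10)
        ]
        rows = select_report_rows(results)
        assert len(rows) == 5
        assert list(rows.partial_eta2) == sorted(
            rows.partial_eta2, reverse=True
        )
        assert rows.partial_eta2.iloc[0] == pytest.approx(
            max(r.partial_eta2 for r in results)
        )

    def test_single_significant_factor_only(self):
        results = [
            _mk_result("ecg", i, "session", 8.0 + i, 0.001, fdr=False)
            for i in range(4)
        ] + [
            _mk_result("ecg", i, "condition", 0.1, 0.9, fdr=False)
            for i in range(4)
        ]
        rows = select_report_rows(results)
        assert set(rows.factor) == {"session"}

    def test_every_significant_factor_represented(self):
        results = (
            [_mk_result("eeg", i, "session", 30.0 + i, 1e-5) for i in range(6)]
            + [_mk_result("eeg", 10, "condition", 9.0, 0.003)]
            + [_mk_result("eeg", 11, "interaction", 7.0, 0.01)]
        )
        rows = select_report_rows(results)
        assert len(rows) == 5
        assert {"session", "condition", "interaction"} <= set(rows.factor)

    def test_fnirs_requires_fdr_flag(self):
        results = [
            _mk_result("fnirs", i, "session", 20.0, 0.0001, fdr=False)
            for i in range(3)
        ]
        assert select_report_rows(results).empty
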