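import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from seizdyn import agreement as agr
from seizdyn import synthetic as syn


class TestCohenKappa:
    def test_identical_vectors(self):
        assert agr.cohen_kappa([1, 0, 1, 2], [1, 0, 1, 2]) == 1.0

    def test_hand_computed_example(self):
        # a=[1,1,0,0], b=[1,0,0,0]: p_o = 3/4; marginals a: 1/2 each,
        # b: 1/4 and 3/4 => p_e = 1/2*1/4 + 1/2*3/4 = 1/2; kappa = 0.5
        assert agr.cohen_kappa([1, 1, 0, 0], [1, 0, 0, 0]) == pytest.approx(0.5)

    def test_symmetry_and_sklearn_cross_check(self, rng):
        a = rng.integers(0, 4, 500)
        b = rng.integers(0, 4, 500)
        k = agr.cohen_kappa(a, b)
        assert k == pytest.approx(agr.cohen_kappa(b, a))
        assert k == pytest.approx(cohen_kappa_score(a, b))

    def test_degenerate_constant_raters(self):
        with pytest.raises(ValueError):
            agr.cohen_kappa([1, 1, 1], [1, 1, 1])


class TestPermutationNull:
    def test_overall_null_mean_near_zero(self, rng):
        a = rng.integers(0, 2, 1000)
        b = rng.integers(0, 2, 1000)
        mean_k, _ = agr.permutation_null(a, b, "overall", n_perm=2000, seed=1)
        # under exchangeability the null kappa is centered at ~ -1/(n-1)
        se = 1.0 / np.sqrt(1000)
        assert abs(mean_k) < 3 * se / np.sqrt(1)  # loose 3-SE band around 0

    def test_within_seizure_exceeds_overall_for_clustered_labels(self, rng):
        # labels cluster by seizure: both raters mostly mark the same
        # per-seizure count of "clear" ICs, so within-seizure shuffles
        # agree more often than free shuffles
        n_seiz, n_ic = 150, 8
        groups = np.repeat(np.arange(n_seiz), n_ic)
        a = np.zeros(n_seiz * n_ic, dtype=int)
        b = np.zeros_like(a)
        for s in range(n_seiz):
            k = rng.integers(0, 4)
            idx = s * n_ic
            a[idx : idx + k] = 1
            b[idx : idx + k] = 1
        mean_within, _ = agr.permutation_null(
            a, b, "within_seizure", groups=groups, n_perm=500, seed=2
        )
        mean_overall, _ = agr.permutation_null(a, b, "overall", n_perm=500, seed=3)
        assert mean_within > mean_overall + 0.05

    def test_pvalue_add_one_estimator(self, rng):
        a = rng.integers(0, 3, 400)
        b = a.copy()  # perfect agreement beats every permutation
        _, p = agr.permutation_null(a, b, "overall", n_perm=10_000, seed=4)
        assert p == pytest.approx(1.0 / 10_001)

    def test_pvalue_uniform_under_null(self):
        # for independent raters the permutation p-value is uniform on its
        # support (up to tie-induced conservatism of the add-one estimator)
        from scipy import stats

        gen = np.random.default_rng(5)
        ps = []
        for i in range(100):
            a = gen.integers(0, 2, 120)
            b = gen.integers(0, 2, 120)
            _, p = agr.permutation_null(a, b, "overall", n_perm=199, seed=1000 + i)
            ps.append(p)
        ps = np.asarray(ps)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
        # super-uniformity: the test never rejects more than nominally
        assert (ps <= 0.05).mean() <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / ps.size)


def _label_table():
    rows = []
    entries = [
        # sid, ic, side, r1(clear,bifm), r2(clear,bifm)
        ("s1", 0, "onset", (True, "SNIC"), (True, "SNIC")),
        ("s1", 1, "onset", (True, "SNIC"), (True, "SupH")),
        ("s1", 2, "onset", (True, "SupH"), (False, None)),
        ("s1", 0, "offset", (True, "FLC"), (True, "FLC")),
        ("s2", 0, "onset", (False, None), (False, None)),
        ("s2", 1, "onset", (True, "SN/SubH"), (True, "SN/SubH")),
        ("s2", 0, "offset", (True, "SNIC/SH"), (True, "FLC")),
    ]
    for sid, ic, side, (c1, b1), (c2, b2) in entries:
        rows.append(dict(patient_id="P1", seizure_id=sid, ic_index=ic, side=side,
                         reviewer="R1", clear=c1, bifm=b1))
        rows.append(dict(patient_id="P1", seizure_id=sid, ic_index=ic, side=side,
                         reviewer="R2", clear=c2, bifm=b2))
    return pd.DataFrame(rows)


class TestReconcile:
    def test_rules(self):
        final = agr.reconcile_labels(_label_table())
        lookup = final.set_index(["seizure_id", "ic_index", "side"])
        assert lookup.loc[("s1", 0, "onset")].final_bifm == "SNIC"  # same class
        assert lookup.loc[("s1", 1, "onset")].final_bifm is None  # class clash
        assert lookup.loc[("s1", 2, "onset")].final_bifm is None  # clear vs not
        assert lookup.loc[("s2", 1, "onset")].final_bifm == "SN/SubH"

    def test_key_mismatch_raises(self):
        df = _label_table()
        df = df.drop(index=df.index[-1])
        with pytest.raises(ValueError, match="mismatch"):
            agr.reconcile_labels(df)

    def test_adding_disagreeing_ic_keeps_existing_categories(self):
        base = _label_table()
        final1 = agr.reconcile_labels(base)
        extra = pd.DataFrame([
            dict(patient_id="P1", seizure_id="s1", ic_index=9, side="onset",
                 reviewer="R1", clear=True, bifm="SupH"),
            dict(patient_id="P1", seizure_id="s1", ic_index=9, side="onset",
                 reviewer="R2", clear=True, bifm="SNIC"),
        ])
        final2 = agr.reconcile_labels(pd.concat([base, extra], ignore_index=True))
        agreed1 = set(final1[final1.agreed].apply(
            lambda r: (r.seizure_id, r.ic_index, r.side, r.final_bifm), axis=1))
        agreed2 = set(final2[final2.agreed].apply(
            lambda r: (r.seizure_id, r.ic_index, r.side, r.final_bifm), axis=1))
        assert agreed1 == agreed2


class TestSeizureLevel:
    def test_single_and_unanimous_ics(self):
        final = agr.reconcile_labels(_label_table())
        per_seizure, summary = agr.seizure_level_bifm(final)
        onset = per_seizure[per_seizure.side == "onset"].set_index("seizure_id")
        assert onset.loc["s1"].bifm == "SNIC"
        assert onset.loc["s2"].bifm == "SN/SubH"

    def test_earliest_anchor_wins_and_brain_score_tiebreak(self):
        rows = []
        for ic, bifm in ((0, "SNIC"), (1, "SupH")):
            for rev in ("R1", "R2"):
                rows.append(dict(patient_id="P1", seizure_id="sX", ic_index=ic,
                                 side="onset", reviewer=rev, clear=True, bifm=bifm))
        final = agr.reconcile_labels(pd.DataFrame(rows))
        om = pd.DataFrame([
            dict(seizure_id="sX", ic_index=0, side="onset", anchor_s=14.5, brain_score=0.9),
            dict(seizure_id="sX", ic_index=1, side="onset", anchor_s=12.0, brain_score=0.2),
        ])
        per_seizure, _ = agr.seizure_level_bifm(final, om)
        assert per_seizure.iloc[0].bifm == "SupH"  # earlier anchor
        om2 = om.assign(anchor_s=[12.2, 12.0])  # < 0.5 s apart: tie
        per_seizure2, _ = agr.seizure_level_bifm(final, om2)
        assert per_seizure2.iloc[0].bifm == "SNIC"  # higher brain score

    def test_summary_conservation(self):
        spec = syn.CohortSpec(n_patients=10, seizures_per_patient=4, seed=5)
        _, _, truth = syn.generate_cohort(spec)
        labels = syn.simulate_reviewer_labels(truth, seed=6)
        final = agr.reconcile_labels(labels)
        per_seizure, summary = agr.seizure_level_bifm(final)
        for side in ("onset", "offset"):
            srow = summary[summary.side == side].iloc[0]
            sub = per_seizure[per_seizure.side == side]
            assert srow.seizures_with_clear_bifm == len(sub)
            assert srow.agreed_ics == sub.n_agreed_ics.sum()
            n_agreed = final[(final.side == side) & final.agreed]
            assert srow.agreed_ics == len(n_agreed)
            assert srow.seizures_with_multiple_bifms == (sub.n_unique_bifms > 1).sum()


class TestAgreementReport:
    def test_report_structure_and_significance(self):
        spec = syn.CohortSpec(n_patients=12, seizures_per_patient=4, seed=8)
        _, _, truth = syn.generate_cohort(spec)
        labels = syn.simulate_reviewer_labels(truth, miss_rate=0.05, seed=9)
        res = agr.agreement_report(labels, n_perm=300, seed=10)
        for side in ("onset", "offset"):
            r = res[f"clear_transition_{side}"]
            assert 0.5 < r.kappa <= 1.0
            assert r.p_value["overall"] < 0.01
            assert r.perm_mean_kappa["within_seizure"] > r.perm_mean_kappa["overall"]

    def test_workbook_import_adapter(self, tmp_path):
        df = _label_table()
        csv = tmp_path / "labels.csv"
        df.rename(columns={"bifm": "label", "clear": "is_clear"}).to_csv(csv, index=False)
        back = agr.import_reviewer_workbook(
            csv, column_map={"label": "bifm", "is_clear": "clear"}
        )
        assert list(back.columns) == list(agr.REVIEWER_COLUMNS)
        assert back.loc[~back.clear, "bifm"].isna().all()
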