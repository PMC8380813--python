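import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
from statsmodels.stats.proportion import proportion_confint

from nicscall.concordance import (
    ConfusionTable,
    chrom_set_venn,
    cohen_kappa,
    confusion,
    diagnostic_summary,
    exact_mcnemar,
    exact_paired_test,
    group_table,
    karyotype_concordance,
    round_half_up,
    secondary_validation,
    wilson_ci,
)
from nicscall.fixtures import (
    CHROM_SET_REGIONS,
    load_reference_cohort,
    reference_chromosome_sets,
)

from _oracles import mcnemar_enumeration


@pytest.fixture(scope="module")
def cohort():
    return load_reference_cohort().set_index("embryo_id")


class TestWilson:
    def test_published_interval(self):
        lo, hi = wilson_ci(86, 96)
        assert round_half_up(100 * lo, 1) == 81.9
        assert round_half_up(100 * hi, 1) == 94.2

    def test_matches_statsmodels(self):
        for k, n in [(86, 96), (0, 10), (10, 10), (117, 130), (1, 200)]:
            lo, hi = wilson_ci(k, n)
            ref_lo, ref_hi = proportion_confint(k, n, method="wilson")
            assert lo == pytest.approx(ref_lo, abs=1e-10)
            assert hi == pytest.approx(ref_hi, abs=1e-10)

    def test_zero_successes_has_zero_lower_bound(self):
        lo, hi = wilson_ci(0, 10)
        assert lo == 0.0 and hi > 0.0

    @settings(max_examples=150, derandomize=True)
    @given(st.integers(0, 200), st.integers(1, 200))
    def test_contains_point_estimate_and_mirrors(self, k, n):
        k = min(k, n)
        lo, hi = wilson_ci(k, n)
        assert 0.0 <= lo <= k / n <= hi <= 1.0
        mlo, mhi = wilson_ci(n - k, n)
        assert mlo == pytest.approx(1 - hi, abs=1e-12)
        assert mhi == pytest.approx(1 - lo, abs=1e-12)

    def test_width_shrinks_with_n(self):
        widths = [np.diff(wilson_ci(int(0.7 * n), n))[0] for n in (10, 40, 160, 640)]
        assert all(a > b for a, b in zip(widths, widths[1:]))


class TestDiagnostics:
    def test_published_te_row(self):
        d = diagnostic_summary(ConfusionTable(tp=86, fp=32, fn=10, tn=128))
        assert d.sensitivity.pct == 89.6 and d.sensitivity.ci_pct == (81.9, 94.2)
        assert d.specificity.pct == 80.0 and d.specificity.ci_pct == (73.1, 85.5)
        assert d.npv.pct == 92.8 and d.npv.ci_pct == (87.2, 96.0)
        assert d.ppv.pct == 72.9 and d.ppv.ci_pct == (64.2, 80.1)

    def test_nics_npv(self):
        d = diagnostic_summary(ConfusionTable(tp=83, fp=43, fn=13, tn=117))
        assert d.npv.pct == 90.0

    def test_zero_denominator_reported_as_undefined(self):
        d = diagnostic_summary(ConfusionTable(tp=0, fp=0, fn=0, tn=5))
        assert d.sensitivity is None and d.ppv is None
        assert d.specificity.value == 1.0


class TestConfusion:
    def test_identical_vectors(self):
        calls = {f"E{i}": i % 2 == 0 for i in range(10)}
        ct = confusion(calls, calls)
        assert ct.fp == ct.fn == 0 and ct.tp == 5 and ct.tn == 5

    def test_swapping_gold_labels_swaps_cells(self):
        a = {"a": True, "b": True, "c": False, "d": False}
        g = {"a": True, "b": False, "c": True, "d": False}
        ct = confusion(a, g)
        flipped = confusion(a, {k: not v for k, v in g.items()})
        assert (flipped.tp, flipped.fp, flipped.fn, flipped.tn) == (ct.fp, ct.tp, ct.tn, ct.fn)

    def test_reference_cohort_reproduces_pairwise_tables(self, cohort):
        gold = cohort["whole_call"].eq("abnormal")
        te = cohort["te_call"].eq("abnormal")
        nics = cohort["nics_call"].eq("abnormal")
        ct = confusion(te, gold)
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == (86, 32, 10, 128)
        ct = confusion(nics, gold)
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == (83, 43, 13, 117)
        ct = confusion(nics, te)
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == (89, 37, 29, 101)

    def test_disjoint_embryos_rejected(self):
        with pytest.raises(ValueError):
            confusion({"a": True}, {"b": True})


class TestExactPaired:
    @pytest.mark.parametrize(
        "b,c,expected",
        [(0, 0, 1.0), (3, 1, 0.625), (10, 0, 2.0 / 1024.0), (5, 5, 1.0)],
    )
    def test_closed_form_cases(self, b, c, expected):
        assert exact_mcnemar(b, c) == pytest.approx(expected)

    def test_equals_enumeration_for_all_small_tables(self):
        for m in range(0, 13):
            for b in range(m + 1):
                assert exact_mcnemar(b, m - b) == pytest.approx(
                    mcnemar_enumeration(b, m - b), abs=1e-12
                )

    def test_matches_statsmodels_exact(self):
        for b, c in [(3, 1), (7, 2), (10, 0), (4, 4)]:
            table = [[5, b], [c, 5]]
            ref = sm_mcnemar(table, exact=True).pvalue
            assert exact_mcnemar(b, c) == pytest.approx(ref, abs=1e-12)

    def test_vector_interface(self):
        a = [True, True, True, False, False]
        b = [True, False, False, False, True]
        # b (a+,b-)=2, c (a-,b+)=1 -> 2*P(X<=1 | n=3)
        assert exact_paired_test(a, b) == pytest.approx(1.0)


class TestKappa:
    def test_published_kappas(self, cohort):
        gold = cohort["whole_call"].eq("abnormal")
        te = cohort["te_call"].eq("abnormal")
        nics = cohort["nics_call"].eq("abnormal")
        r = cohen_kappa(confusion(te, gold))
        assert r.kappa_3dp == 0.665 and r.po_pct == 83.6
        r = cohen_kappa(confusion(nics, gold))
        assert r.kappa_3dp == 0.561 and r.po_pct == 78.1
        r = cohen_kappa(confusion(nics, te))
        assert r.kappa_3dp == 0.484 and r.po_pct == 74.2

    def test_perfect_agreement(self):
        r = cohen_kappa(ConfusionTable(tp=40, fp=0, fn=0, tn=60))
        assert r.kappa == pytest.approx(1.0)

    def test_chance_agreement_gives_zero(self):
        # independent marginals: po == pe
        r = cohen_kappa(np.array([[30, 20], [30, 20]]))
        assert r.kappa == pytest.approx(0.0, abs=1e-12)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 300)
        b = np.where(rng.random(300) < 0.7, a, rng.integers(0, 2, 300))
        table = pd.crosstab(a, b).to_numpy()
        assert cohen_kappa(table).kappa == pytest.approx(cohen_kappa_score(a, b))

    def test_ci_contains_kappa(self, cohort):
        gold = cohort["whole_call"].eq("abnormal")
        te = cohort["te_call"].eq("abnormal")
        r = cohen_kappa(confusion(te, gold))
        assert r.kappa_ci[0] < r.kappa < r.kappa_ci[1]

    def test_degenerate_marginals_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            cohen_kappa(np.array([[10, 0], [0, 0]]))


class TestChromSets:
    def test_reference_reconstruction_matches_published_regions(self):
        v = chrom_set_venn(reference_chromosome_sets())
        assert v.n_sets == 5267  # 23 x 229
        assert v.all_three == CHROM_SET_REGIONS["all_three"]
        assert v.nics_te_only == CHROM_SET_REGIONS["nics_te_only"]
        assert v.nics_whole_only == CHROM_SET_REGIONS["nics_whole_only"]
        assert v.te_whole_only == CHROM_SET_REGIONS["nics_differs_from_both"]

    def test_regions_partition_on_random_calls(self):
        rng = np.random.default_rng(4)
        rows = []
        for e in range(40):
            for chrom in ["1", "2", "3", "4", "5", "6"]:
                te, ni, wh = rng.choice(["euploid", "gain", "loss"], 3, replace=True)
                rows.append(
                    {"embryo_id": f"E{e}", "chrom": chrom, "te": te, "nics": ni, "whole": wh}
                )
        df = pd.DataFrame(rows)
        v = chrom_set_venn(df, mac_min=7)  # random statuses: allow heavy embryos
        total = v.all_three + v.nics_te_only + v.nics_whole_only + v.te_whole_only + v.all_different
        assert total == v.n_sets == len(df)

    def test_all_identical_is_all_three(self):
        df = pd.DataFrame(
            {
                "embryo_id": ["E1"] * 3,
                "chrom": ["1", "2", "3"],
                "te": ["gain", "euploid", "loss"],
                "nics": ["gain", "euploid", "loss"],
                "whole": ["gain", "euploid", "loss"],
            }
        )
        v = chrom_set_venn(df)
        assert v.all_three == 3 and v.all_different == 0

    def test_mosaic_counts_as_consistent_with_full_by_default(self):
        df = pd.DataFrame(
            {
                "embryo_id": ["E1"],
                "chrom": ["1"],
                "te": ["mosaic_gain"],
                "nics": ["gain"],
                "whole": ["segmental_gain"],
            }
        )
        assert chrom_set_venn(df).all_three == 1
        assert chrom_set_venn(df, collapse_mosaic=False).all_three == 0

    def test_mac_embryo_rejected(self):
        rows = [
            {"embryo_id": "M", "chrom": c, "te": "gain", "nics": "euploid", "whole": "euploid"}
            for c in ["1", "2", "3", "4", "5"]
        ]
        with pytest.raises(ValueError, match="MAC"):
            chrom_set_venn(pd.DataFrame(rows))


class TestKaryotypeConcordance:
    def test_both_euploid_full(self):
        assert karyotype_concordance(set(), set()) == "full"

    def test_reciprocal_and_mosaic_still_full(self):
        assert karyotype_concordance({"6", "20"}, {"6", "20"}) == "full"

    def test_one_shared_is_partial(self):
        assert karyotype_concordance({"6", "20"}, {"20", "15"}) == "partial"

    def test_disjoint_is_discordant(self):
        assert karyotype_concordance({"6"}, set()) == "discordant"


class TestGroups:
    def test_published_group_fractions(self, cohort):
        gold = cohort["whole_call"].eq("abnormal")
        gt = group_table(cohort["nics_group"], gold).set_index("group")
        assert gt.loc["A", "n"] == 130 and gt.loc["A", "consistent_pct"] == 90.0
        assert gt.loc["B", "n"] == 108 and gt.loc["B", "consistent_pct"] == 72.2
        assert gt.loc["C", "n"] == 18 and gt.loc["C", "consistent_pct"] == 27.8
        assert gt["n"].sum() == 256

    def test_all_group_a_gold_normal(self):
        groups = {f"E{i}": "A" for i in range(10)}
        gold = {f"E{i}": False for i in range(10)}
        gt = group_table(groups, gold).set_index("group")
        assert gt.loc["A", "consistent_pct"] == 100.0

    def test_splits_partition_each_group(self, cohort):
        gold = cohort["whole_call"].eq("abnormal")
        gt = group_table(cohort["te_group"], gold)
        assert (gt["gold_normal"] + gt["gold_abnormal"]).tolist() == gt["n"].tolist()


class TestSecondaryValidation:
    def test_published_mac_group_reclassification(self, cohort):
        gold = cohort["whole_call"].eq("abnormal")
        te = cohort["te_call"].eq("abnormal")
        sv = secondary_validation(cohort["nics_group"], te, gold, "C")
        assert sv.n == 18
        assert sv.secondary_accuracy == (15, 18)
        assert sv.secondary_accuracy_pct == 83.3
        assert sv.primary_accuracy_pct == 27.8
        assert sv.recategorized_normal == 12

    def test_published_group_b_reclassification(self, cohort):
        gold = cohort["whole_call"].eq("abnormal")
        te = cohort["te_call"].eq("abnormal")
        sv = secondary_validation(cohort["nics_group"], te, gold, "B")
        assert sv.n == 108
        assert sv.secondary_accuracy == (91, 108)
        assert sv.secondary_accuracy_pct == 84.3
        assert sv.recategorized_normal == 25

    def test_secondary_equal_to_gold_is_perfect(self):
        groups = {f"E{i}": "B" for i in range(6)}
        gold = {f"E{i}": i % 2 == 0 for i in range(6)}
        sv = secondary_validation(groups, gold, gold, "B")
        assert sv.secondary_accuracy_pct == 100.0

    def test_empty_stratum(self):
        sv = secondary_validation({"E1": "B"}, {"E1": True}, {"E1": True}, "C")
        assert sv.n == 0
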