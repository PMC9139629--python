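import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smrisk import CohortSpec, build_comparison_table, evaluate_cohort, generate_cohort, wilcoxon_paired
from smrisk.compare import METRICS
from smrisk.dasu import dasu_risk, default_dasu_registry, lookup_organ
from smrisk.errors import PairingError, ValidationError
from smrisk.schneider import default_schneider_registry, schneider_risk


def brute_force_signed_rank_p(d):
    """Two-tailed signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0.0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count_le = count_ge = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        count_le += w <= w_obs + 1e-9
        count_ge += w >= w_obs - 1e-9
    total = 2**n
    return min(1.0, 2.0 * min(count_le, count_ge) / total)


class TestWilcoxonPaired:
    def test_identical_samples_give_p_one(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0
        assert res.all_zero

    def test_five_concordant_pairs_exact_p(self):
        # all five differences positive: W+ = 15, the extreme of 2^5
        # equally likely assignments, so two-tailed p = 2/32
        y = np.zeros(5)
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = wilcoxon_paired(x, y)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2.0 / 32.0, abs=0)

    def test_large_constant_shift_at_n17_is_highly_significant(self):
        rng = np.random.default_rng(12)
        y = rng.normal(0, 1, 17)
        x = y + 10.0
        res = wilcoxon_paired(x, y)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2.0 / 2.0**17)
        assert res.p_value < 0.001

    @pytest.mark.parametrize("n", range(3, 13))
    def test_exact_p_matches_brute_force_enumeration(self, n):
        rng = np.random.default_rng(n)
        for trial in range(8):
            x = rng.normal(0, 1, n)
            y = rng.normal(0, 1, n)
            if trial % 3 == 0:  # inject ties and zeros
                x = np.round(x, 0)
                y = np.round(y, 0)
            d = x - y
            if np.all(d == 0):
                continue
            res = wilcoxon_paired(x, y, method="exact")
            assert res.p_value == pytest.approx(brute_force_signed_rank_p(d), abs=0)

    def test_exact_agrees_with_scipy_without_ties(self):
        rng = np.random.default_rng(44)
        for n in (8, 12, 17):
            x = rng.normal(0, 1, n)
            y = rng.normal(0, 1, n)
            ours = wilcoxon_paired(x, y, method="exact").p_value
            ref = stats.wilcoxon(x, y, method="exact").pvalue
            assert ours == pytest.approx(ref, rel=1e-12)

    def test_approx_agrees_with_scipy_normal_approximation(self):
        rng = np.random.default_rng(45)
        x = rng.normal(0, 1, 60)
        y = rng.normal(0.3, 1, 60)
        ours = wilcoxon_paired(x, y, method="approx").p_value
        ref = stats.wilcoxon(x, y, method="approx", correction=False).pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_antisymmetry_of_two_tailed_p(self):
        rng = np.random.default_rng(46)
        for n in (6, 17, 40):
            x = rng.normal(0, 1, n)
            y = rng.normal(0.5, 1, n)
            assert wilcoxon_paired(x, y).p_value == pytest.approx(
                wilcoxon_paired(y, x).p_value, rel=1e-12
            )

    def test_exact_threshold_switch(self):
        rng = np.random.default_rng(47)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        assert wilcoxon_paired(x, y).method == "approx"
        assert wilcoxon_paired(x, y, exact_threshold=30).method == "exact"

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_paired([1.0, 2.0], [1.0, 2.0, 3.0])


@pytest.fixture(scope="module")
def small_cohort():
    return generate_cohort(CohortSpec(n_patients=5, seed=11, organs=("lung", "thyroid")))


class TestEvaluateCohort:
    def test_row_cardinality(self, small_cohort):
        df = evaluate_cohort(small_cohort)
        assert len(df) == 5 * 3 * 2

    def test_rows_match_direct_module_calls(self, small_cohort):
        df = evaluate_cohort(small_cohort)
        dreg, sreg = default_dasu_registry(), default_schneider_registry()
        row = df[(df.patient_id == "P01") & (df.modality == "PBS") & (df.organ == "lung")].iloc[0]
        dvh = small_cohort.plans["P01"]["PBS"]["lung"]
        assert row.dasu_total_pct == dasu_risk(dvh, lookup_organ(dreg, "lung"), "total")
        assert row.dasu_fatal_pct == dasu_risk(dvh, lookup_organ(dreg, "lung"), "fatal")
        sr = schneider_risk(dvh, lookup_organ(sreg, "lung"))
        assert row.oed_gy == sr.oed
        assert row.schneider_incidence == sr.incidence

    def test_zero_dose_cohort_gives_all_zero_metrics(self, small_cohort):
        import copy

        zero = copy.deepcopy(small_cohort)
        for pid in zero.patients:
            for mod in zero.plans[pid]:
                for organ, dvh in zero.plans[pid][mod].items():
                    dvh.bin_dose = np.zeros_like(dvh.bin_dose)
        df = evaluate_cohort(zero)
        assert (df[list(METRICS)] == 0).all().all()


class TestComparisonTable:
    def test_identical_modalities_give_p_one_and_equal_medians(self, small_cohort):
        import copy

        clone = copy.deepcopy(small_cohort)
        for pid in clone.patients:
            base = clone.plans[pid]["3DCRT"]
            clone.plans[pid]["IMRT"] = copy.deepcopy(base)
            clone.plans[pid]["PBS"] = copy.deepcopy(base)
        table = build_comparison_table(evaluate_cohort(clone)).data
        for _, row in table.iterrows():
            assert row["3DCRT_median"] == row["IMRT_median"] == row["PBS_median"]
            assert row["p_pbs_vs_3dcrt"] == 1.0
            assert row["p_imrt_vs_3dcrt"] == 1.0

    def test_medians_match_independent_sort_based_median(self, small_cohort):
        df = evaluate_cohort(small_cohort)
        table = build_comparison_table(df).data
        row = table[(table.organ == "lung") & (table.metric == "dasu_total_pct")].iloc[0]
        vals = np.sort(
            df[(df.organ == "lung") & (df.modality == "PBS")]
            .sort_values("patient_id")["dasu_total_pct"]
            .to_numpy()
        )
        k = vals.size
        med = vals[k // 2] if k % 2 else 0.5 * (vals[k // 2 - 1] + vals[k // 2])
        assert row["PBS_median"] == pytest.approx(med, rel=1e-15)
        assert row["PBS_min"] == vals[0] and row["PBS_max"] == vals[-1]

    def test_incomplete_pairing_rejected_with_cell_listing(self, small_cohort):
        df = evaluate_cohort(small_cohort)
        broken = df.drop(
            df[(df.patient_id == "P02") & (df.modality == "IMRT") & (df.organ == "lung")].index
        )
        with pytest.raises(PairingError, match="P02/IMRT/lung"):
            build_comparison_table(broken)

    def test_missing_metric_column_rejected(self, small_cohort):
        df = evaluate_cohort(small_cohort).drop(columns=["dasu_fatal_pct"])
        with pytest.raises(ValidationError):
            build_comparison_table(df)

    def test_markdown_report_contains_all_cells(self, small_cohort):
        table = build_comparison_table(evaluate_cohort(small_cohort))
        md = table.to_markdown()
        assert "lung" in md and "thyroid" in md
        assert md.count("|") > 20
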