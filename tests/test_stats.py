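"""Normality gate, group comparisons, Spearman correlations, full report."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from neuromorph.io import CohortRecord
from neuromorph.morphometry import TissueComposition
from neuromorph.stats import (
    StatsConfig,
    compare_groups,
    run_full_analysis,
    significance_stars,
    spearman_correlation,
)
from neuromorph.stats import test_normality as normality_test


class TestNormality:
    def test_normal_draws_pass_at_nominal_level(self):
        """Lilliefors at alpha 0.05 flags normal data normal ~95% of seeds."""
        flagged = 0
        n_rep = 200
        for seed in range(n_rep):
            x = np.random.default_rng(seed).standard_normal(500)
            flagged += normality_test(x).p_value > 0.05
        assert flagged >= 0.94 * n_rep

    def test_two_point_mass_rejected(self):
        x = np.random.default_rng(0).choice([0.0, 1.0], size=500)
        res = normality_test(x)
        assert res.p_value <= 0.05
        assert res.note == "non-normal"

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            normality_test([2.0, 2.0, 2.0, 2.0])

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="n >= 4"):
            normality_test([1.0, 2.0, 3.0])


class TestCompareGroups:
    def test_exact_mann_whitney_separated_triples(self):
        res = compare_groups([1, 2, 3], [4, 5, 6], force_nonparametric=True)
        assert res.test_name == "mann_whitney_u"
        assert res.statistic == 0.0
        # brute force over all C(6,3)=20 assignments: 2/20
        assert res.p_value == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        res = compare_groups([1, 2, 3], [1, 2, 3], force_nonparametric=True)
        assert res.p_value >= 0.99

    def test_degenerate_group_auto_routes_to_mann_whitney(self):
        # constant "unorganized area in controls" cannot be normal
        res = compare_groups([0.0, 0.0, 0.0, 0.0], [0.2, 0.3, 0.25, 0.4])
        assert res.test_name == "mann_whitney_u"
        assert "Mann-Whitney" in res.note

    def test_normal_groups_use_t_test(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 30)
        b = rng.normal(2, 1, 30)
        res = compare_groups(a, b)
        assert res.test_name == "t_independent"
        assert res.p_value < 0.001
        assert res.effect_direction == "a<b"

    def test_student_matches_scipy(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 25), rng.normal(0.3, 1, 20)
        res = compare_groups(a, b)
        if res.test_name == "t_independent":
            ref = sps.ttest_ind(a, b)
            assert res.statistic == pytest.approx(ref.statistic)
            assert res.p_value == pytest.approx(ref.pvalue)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            compare_groups([1.0], [2.0, 3.0])

    def test_exact_enumeration_agrees_with_own_brute_force(self):
        """Independent oracle: re-enumerate assignments by hand."""
        a, b = [3.1, 0.2, 1.5], [2.2, 0.9]
        res = compare_groups(a, b, force_nonparametric=True)
        pooled = np.array(a + b)
        ranks = sps.rankdata(pooled)
        u_obs = ranks[:3].sum() - 6
        mu = 3 * 2 / 2.0
        hits = total = 0
        for comb in itertools.combinations(range(5), 3):
            u = ranks[list(comb)].sum() - 6
            total += 1
            hits += abs(u - mu) >= abs(u_obs - mu) - 1e-9
        assert res.p_value == pytest.approx(hits / total)

    def test_exact_close_to_normal_approximation(self):
        """Tie-free pooled n=12: exact vs asymptotic p within 0.05."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            pooled = rng.permutation(np.arange(12, dtype=float) + 1)
            a, b = pooled[:6], pooled[6:]
            exact = compare_groups(a, b, force_nonparametric=True).p_value
            approx = sps.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert abs(exact - min(1.0, approx)) <= 0.05


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_correlation([1, 2, 3, 4], [4, 3, 2, 1]).statistic == pytest.approx(-1)
        assert spearman_correlation([1, 2, 3, 4], [1, 2, 3, 4]).statistic == pytest.approx(1)

    def test_tied_data_matches_midrank_pearson_oracle(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        res = spearman_correlation(x, y)
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        rho_oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.statistic == pytest.approx(rho_oracle)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])

    def test_permutation_p_agrees_with_t_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        y = x + rng.normal(scale=1.0, size=20)
        t_res = spearman_correlation(x, y)
        p_res = spearman_correlation(x, y, n_permutations=20000, seed=0)
        assert p_res.statistic == pytest.approx(t_res.statistic)
        assert abs(p_res.p_value - t_res.p_value) < 0.02

    def test_permutation_p_is_seeded(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=10), rng.normal(size=10)
        p1 = spearman_correlation(x, y, n_permutations=500, seed=9).p_value
        p2 = spearman_correlation(x, y, n_permutations=500, seed=9).p_value
        assert p1 == p2


class TestSignificanceStars:
    @pytest.mark.parametrize(
        "p, stars", [(0.006, "**"), (0.03, "*"), (0.2, ""), (0.0499, "*")]
    )
    def test_annotation_convention(self, p, stars):
        assert significance_stars(p) == stars


def _cohort_fixture(nrs_values=(0, 0, 0, 0, 0, 0, 0, 5, 6, 7, 8, 8)):
    """Hand-built compositions with a clean negative organized-vs-NRS trend."""
    groups = ["control"] * 4 + ["nonpainful_neuroma"] * 3 + ["painful_neuroma"] * 5
    records, comps = [], []
    rng = np.random.default_rng(0)
    for i, (g, nrs) in enumerate(zip(groups, nrs_values)):
        sid = f"S{i:02d}"
        records.append(
            CohortRecord(sid, g, int(nrs), 40 + i, "male" if i % 3 else "female", 0.5)
        )
        org = {"control": 0.40, "nonpainful_neuroma": 0.25}.get(g, 0.25 - 0.02 * nrs)
        org += rng.normal(0, 0.002)
        unorg = {"control": 0.005, "nonpainful_neuroma": 0.15}.get(g, 0.04 * nrs)
        rel = dict(
            organized_nervous=org,
            unorganized_nervous=unorg,
            connective=0.9 - org - unorg,
            adipose=0.08,
            erythrocyte=0.02,
        )
        absolute = {k: v * 0.1 for k, v in rel.items()}
        dev = (unorg - org) / max(unorg, org)
        comps.append(TissueComposition(sid, absolute, rel, dev))
    return comps, records


class TestFullAnalysis:
    def test_report_contains_every_paper_comparison(self):
        comps, records = _cohort_fixture()
        report = run_full_analysis(comps, records)
        assert len(report.group_comparisons) == 16  # 2 contrasts x 2 kinds x 4 classes
        variables = {
            (r.variable, r.comparison) for r in report.group_comparisons
        }
        assert ("relative_unorganized_nervous", "control_vs_neuroma") in variables
        assert ("absolute_adipose", "painful_vs_nonpainful") in variables
        corr = {r.variable for r in report.pain_correlations}
        assert corr == {
            "relative_unorganized_nervous",
            "relative_organized_nervous",
            "deviation_index",
        }
        assert any(r.variable == "age" for r in report.exploratory)

    def test_encoded_effect_directions_recovered(self):
        comps, records = _cohort_fixture()
        report = run_full_analysis(comps, records)
        org = report.find("relative_organized_nervous", "vs_nrs")
        dev = report.find("deviation_index", "vs_nrs")
        assert org.statistic < 0
        assert dev.statistic > 0
        unorg_cn = report.find("relative_unorganized_nervous", "control_vs_neuroma")
        assert unorg_cn.effect_direction == "a<b"  # more unorganized in neuromas

    def test_constant_nrs_flagged_not_computable(self):
        comps, records = _cohort_fixture()
        # painful records with NRS 0 are legal; only control/non-painful
        # groups force NRS 0, so an all-zero cohort keeps its group sizes
        records = [
            CohortRecord(r.sample_id, r.group, 0, r.age, r.sex, r.mpp)
            for r in records
        ]
        report = run_full_analysis(comps, records)
        for r in report.pain_correlations:
            assert "not computable" in r.note
            assert np.isnan(r.p_value)

    def test_missing_composition_lists_sample_ids(self):
        comps, records = _cohort_fixture()
        with pytest.raises(ValueError, match="S11"):
            run_full_analysis(comps[:-1], records)

    def test_bh_adjustment_column_optional(self):
        comps, records = _cohort_fixture()
        plain = run_full_analysis(comps, records)
        adjusted = run_full_analysis(comps, records, StatsConfig(bh_adjust=True))
        assert plain.bh_adjusted is None
        assert adjusted.bh_adjusted
        for key, p_adj in adjusted.bh_adjusted.items():
            variable, comparison = key.split("|")
            raw = adjusted.find(variable, comparison).p_value
            assert p_adj >= raw - 1e-12

    def test_report_round_trips_to_json(self, tmp_path):
        import json

        comps, records = _cohort_fixture()
        report = run_full_analysis(comps, records)
        path = tmp_path / "report.json"
        path.write_text(json.dumps(report.to_dict()))
        blob = json.loads(path.read_text())
        assert len(blob["group_comparisons"]) == 16
        assert blob["config"]["welch"] is False
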