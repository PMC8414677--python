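"""Statistical battery against exact enumerations and reference routines."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcshape import (
    CohortSpec,
    ShapeFeatures,
    SubjectRecord,
    binomial_laterality_test,
    demographics_table,
    group_comparison,
    kendall_correlation_screen,
    make_cohort,
    nvc_crosstab,
    no_nvc_subgroup_comparison,
    paired_side_comparison,
    records_from_tables,
    run_full_analysis,
)
from mcshape.features import FEATURE_NAMES
from mcshape.io import MANIFEST_COLUMNS
from mcshape.stats import holm_adjust, select_masks

from conftest import brute_force_tau_b


def features_from(**overrides) -> ShapeFeatures:
    base = {name: 1.0 for name in FEATURE_NAMES}
    base.update(overrides)
    return ShapeFeatures(**base)


def record(sid, group="PTN", affected="right", nvc=("no", "no"), left=None, right=None, **kw):
    return SubjectRecord(
        subject_id=sid,
        group=group,
        affected_side=affected if group == "PTN" else "none",
        nvc_left=nvc[0],
        nvc_right=nvc[1],
        features_left=left or features_from(),
        features_right=right or features_from(),
        **kw,
    )


class TestBinomialLaterality:
    def test_study_counts_38_77(self):
        res = binomial_laterality_test(38, 77)
        assert res.extra["proportion_right_pct"] == pytest.approx(66.96, abs=0.005)
        assert res.extra["proportion_left_pct"] == pytest.approx(33.04, abs=0.005)
        assert res.p_value < 0.01

    def test_symmetric_counts_p_one(self):
        assert binomial_laterality_test(10, 10).p_value == pytest.approx(1.0)

    def test_exact_enumeration_zero_eight(self):
        # two-sided exact: P(X=0) + P(X=8) at p=0.5
        assert binomial_laterality_test(0, 8).p_value == pytest.approx(2 * 0.5**8)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            binomial_laterality_test(0, 0)


class TestPairedComparison:
    def test_matches_manual_paired_t(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0.41, 0.05, 20), rng.normal(0.39, 0.05, 20)
        recs = [
            record(f"S{i}", left=features_from(flatness=ai), right=features_from(flatness=bi))
            for i, (ai, bi) in enumerate(zip(a, b))
        ]
        res = paired_side_comparison(recs, "flatness", "left_right")
        d = a - b
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res.statistic == pytest.approx(t_manual, rel=1e-9)
        assert res.paired

    def test_affected_pairing_orientation(self):
        # affected side carries the lower flatness; difference must be negative
        recs = [
            record(f"S{i}", affected="right",
                   left=features_from(flatness=0.42), right=features_from(flatness=0.38 + 1e-3 * i))
            for i in range(5)
        ]
        res = paired_side_comparison(recs, "flatness", "affected")
        assert res.mean_a < res.mean_b
        assert res.extra["mean_difference"] < 0

    def test_identical_sides_flagged_no_p(self):
        recs = [record(f"S{i}") for i in range(5)]
        res = paired_side_comparison(recs, "flatness", "left_right")
        assert np.isnan(res.p_value)
        assert "zero-variance" in res.note

    def test_small_stratum_flagged(self):
        res = paired_side_comparison([record("S1"), record("S2")], "flatness", "affected")
        assert np.isnan(res.p_value)
        assert "too small" in res.note


class TestGroupComparison:
    @staticmethod
    def _arms(seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(10.0, 1.0, 40)
        b = rng.normal(10.8, 1.0, 40)
        return a, b

    def test_ols_equals_pooled_t(self):
        from scipy import stats as sps

        a, b = self._arms()
        res = group_comparison([], "flatness", lambda f: a, lambda f: b)
        t, p = sps.ttest_ind(a, b, equal_var=True)
        assert abs(res.statistic) == pytest.approx(abs(t), rel=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_welch_flag_switches_test(self):
        from scipy import stats as sps

        a, b = self._arms(1)
        res = group_comparison([], "flatness", lambda f: a, lambda f: b, welch=True)
        t, p = sps.ttest_ind(a, b, equal_var=False)
        assert abs(res.statistic) == pytest.approx(abs(t), rel=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_identical_arms_zero_difference(self):
        a = np.full(10, 3.0) + np.arange(10) * 0.01
        res = group_comparison([], "flatness", lambda f: a, lambda f: a.copy())
        assert res.extra["mean_difference"] == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_selector_picks_group_and_side(self):
        recs = [
            record("P1", group="PTN", affected="left",
                   left=features_from(flatness=0.3), right=features_from(flatness=0.5)),
            record("H1", group="HC",
                   left=features_from(flatness=0.7), right=features_from(flatness=0.9)),
        ]
        assert list(select_masks(recs, group="PTN", side="affected")("flatness")) == [0.3]
        assert list(select_masks(recs, group="HC", side="both")("flatness")) == [0.7, 0.9]
        assert list(select_masks(recs, group="PTN", side="unaffected")("flatness")) == [0.5]

    def test_empty_arm_flagged(self):
        res = group_comparison([], "flatness", lambda f: np.array([]), lambda f: np.ones(5))
        assert np.isnan(res.p_value)


class TestKendallScreen:
    def test_perfect_monotone_tau_one(self):
        from scipy import stats as sps

        tau, _ = sps.kendalltau([1, 2, 3, 4, 5], [2, 4, 6, 8, 10], variant="b")
        assert tau == pytest.approx(1.0)

    def test_toy_list_matches_brute_force(self):
        x, y = [1, 2, 3, 4, 5], [3, 1, 2, 5, 4]
        assert brute_force_tau_b(x, y) == pytest.approx(0.4)
        from scipy import stats as sps

        tau, _ = sps.kendalltau(x, y, variant="b")
        assert tau == pytest.approx(0.4)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(-5, 5), st.integers(-5, 5)), min_size=5, max_size=30
        ).filter(
            lambda ps: len({a for a, _ in ps}) > 1 and len({b for _, b in ps}) > 1
        )
    )
    def test_tau_b_matches_brute_force_with_ties(self, pairs):
        from scipy import stats as sps

        x, y = zip(*pairs)
        tau, _ = sps.kendalltau(x, y, variant="b")
        assert tau == pytest.approx(brute_force_tau_b(x, y), rel=1e-9, abs=1e-9)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.permutations(list(range(8))))
    def test_tau_invariant_to_monotone_transform(self, ranks):
        from scipy import stats as sps

        x = np.arange(8.0)
        y = np.asarray(ranks, dtype=float)
        raw, _ = sps.kendalltau(x, y, variant="b")
        transformed, _ = sps.kendalltau(np.exp(x), y**3 + 2 * y, variant="b")
        assert transformed == pytest.approx(raw, abs=1e-12)

    def test_screen_signs_match_generator_mechanics(self):
        """Flatness varies via c/a: positively tied to the least axis,
        negatively to the major axis, in both study groups."""
        cohort = make_cohort(CohortSpec(n_ptn=40, n_hc=20, seed=31, spacing=(1.0,) * 3))
        feats = _extract_table(cohort, ["flatness", "least_axis_length", "major_axis_length"])
        recs = records_from_tables(cohort.manifest, feats)
        for group in ("PTN", "HC"):
            results = {r.contrast.split(" vs ")[-1]: r for r in kendall_correlation_screen(recs, group)}
            assert results["least_axis_length"].statistic > 0
            assert results["major_axis_length"].statistic < 0

    def test_constant_feature_flagged(self):
        recs = [
            record(f"S{i}", left=features_from(flatness=0.3 + 0.01 * i, voxel_volume=5.0),
                   right=features_from(flatness=0.35 + 0.01 * i, voxel_volume=5.0))
            for i in range(5)
        ]
        results = kendall_correlation_screen(recs, "PTN")
        const = [r for r in results if "voxel_volume" in r.contrast][0]
        assert "constant" in const.note


def _extract_table(cohort, names=None):
    from mcshape import extract_features

    rows = []
    for (sid, side), mask in cohort.masks.items():
        f = extract_features(mask, names)
        rows.append({"subject_id": sid, "side": side, **f.as_dict()})
    return pd.DataFrame(rows)


class TestTables:
    def test_demographics_sex_percentages_and_chi(self):
        rows = []
        sexes = ["male"] * 45 + ["female"] * 70 + ["male"] * 15 + ["female"] * 31
        groups = ["PTN"] * 115 + ["HC"] * 46
        for i, (g, s) in enumerate(zip(groups, sexes)):
            rows.append([f"S{i}", g, "right" if g == "PTN" else "none", "no", "no", "", "", 60.0, s])
        man = pd.DataFrame(rows, columns=MANIFEST_COLUMNS + ["age", "sex"])
        table = demographics_table(man)
        male = table[table.variable == "Male (n, %)"].iloc[0]
        assert "45 (39.13)" in male["PTN"]
        assert "15 (32.61)" in male["HC"]
        female = table[table.variable == "Female (n, %)"].iloc[0]
        assert "70 (60.87)" in female["PTN"]
        assert "31 (67.39)" in female["HC"]

    def test_chi_square_zero_on_balanced_table(self):
        from scipy import stats as sps

        chi2, p, _, _ = sps.chi2_contingency([[10, 10], [10, 10]], correction=False)
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_nvc_crosstab_percentages(self):
        recs = []
        i = 0
        for pattern, count in zip([("yes", "no"), ("no", "yes"), ("yes", "yes"), ("no", "no")], [12, 4, 13, 9]):
            for _ in range(count):
                # affected = left, so nvc order (left, right) = (affected, unaffected)
                recs.append(record(f"S{i}", affected="left", nvc=pattern))
                i += 1
        tab = nvc_crosstab(recs)
        left = tab[tab.affected_side_group.str.startswith("left")]
        assert left["count"].tolist() == [12, 4, 13, 9]
        assert left["percent"].tolist() == pytest.approx([31.58, 10.53, 34.21, 23.68], abs=0.005)
        assert left["percent"].sum() == pytest.approx(100.0, abs=0.1)

    def test_nvc_crosstab_single_record(self):
        tab = nvc_crosstab([record("S1", affected="right", nvc=("no", "yes"))])
        right = tab[tab.affected_side_group.str.startswith("right")]
        assert right["percent"].max() == pytest.approx(100.0)

    def test_no_nvc_subgroup_null_shows_no_systematic_difference(self):
        from mcshape.simulate import null_cohort_spec

        cohort = make_cohort(null_cohort_spec(n_ptn=60, n_hc=0, seed=8, spacing=(1.0,) * 3))
        feats = _extract_table(cohort, ["flatness"])
        # fill remaining feature columns so record assembly succeeds
        recs = records_from_tables(cohort.manifest, feats)
        tab = no_nvc_subgroup_comparison(recs)
        flat = tab[(tab.feature == "Flatness") & tab.p_value.notna()]
        assert (flat.p_value > 0.0009).all()  # no spuriously extreme null p


class TestHolm:
    def test_holm_monotone_and_bounded(self):
        p = np.array([0.001, 0.02, 0.04, 0.2, np.nan])
        adj = holm_adjust(p)
        assert np.isnan(adj[-1])
        finite = adj[:-1]
        assert (finite >= p[:-1]).all()
        assert (finite <= 1.0).all()


class TestRunFullAnalysis:
    @pytest.fixture(scope="class")
    def analysis(self, tmp_path_factory):
        out = tmp_path_factory.mktemp("analysis")
        cohort = make_cohort(CohortSpec(n_ptn=30, n_hc=12, seed=5, spacing=(1.0,) * 3))
        feats = _extract_table(cohort)
        result = run_full_analysis(cohort.manifest, feats, out, {"seed": 5})
        return cohort, feats, result, out

    def test_emits_all_tables_and_log(self, analysis):
        *_, out = analysis
        for name in ("table1.csv", "table2.csv", "table3.csv", "table4.csv", "run.log"):
            assert (out / name).exists()

    def test_table2_structure(self, analysis):
        _, _, result, _ = analysis
        t2 = result["table2"]
        assert len(t2) == 10 * 4  # ten features x four comparisons
        assert set(t2.comparison) == {
            "HC both sides vs PTN affected",
            "PTN affected vs unaffected",
            "PTN left vs right",
            "HC left vs right",
        }
        finite = t2.p_value.dropna()
        assert ((finite >= 0) & (finite <= 1)).all()

    def test_percentages_sum_to_100_per_denominator(self, analysis):
        _, _, result, _ = analysis
        t3 = result["table3"]
        for _, grp in t3.groupby("affected_side_group"):
            if grp["count"].sum():
                assert grp["percent"].sum() == pytest.approx(100.0, abs=0.1)

    def test_rerun_byte_identical_tables(self, analysis, tmp_path):
        cohort, feats, _, out = analysis
        run_full_analysis(cohort.manifest, feats, tmp_path, {"seed": 5})
        for name in ("table1.csv", "table2.csv", "table3.csv", "table4.csv"):
            assert (tmp_path / name).read_bytes() == (out / name).read_bytes()

    def test_injected_flatness_deficit_detected_only_in_flatness(self, tmp_path):
        """A generator-injected affected-side flatness deficit shows up in the
        flatness row of the side comparison, not in the size features."""
        spec = CohortSpec(
            n_ptn=60,
            n_hc=0,
            affected_flatness_delta=0.04,
            between_subject_sd=0.01,
            flatness_mean_left=0.40,
            flatness_mean_right=0.40,
            seed=77,
        )
        cohort = make_cohort(spec)
        feats = _extract_table(cohort)
        result = run_full_analysis(cohort.manifest, feats, tmp_path, {"seed": 77})
        t2 = result["table2"]
        aff = t2[t2.comparison == "PTN affected vs unaffected"].set_index("feature")
        assert aff.loc["Flatness", "p_value"] < 0.05
        assert aff.loc["Voxel Volume (mm3)", "p_value"] > 0.05
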