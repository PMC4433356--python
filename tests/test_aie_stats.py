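import numpy as np
import pandas as pd
import pytest

from spectex import (
    AccuracyReport,
    AIETable,
    ErrorMatrix,
    aie,
    build_aie_table,
    duncan_groups,
    two_way_anova,
)
from spectex.aie_stats import duncan_from_anova

DATASETS = ["HMS", "HMS5VI", "SpecTex", "HMS13B"]
CLASSIFIERS = ["mlc", "md", "sam", "sid", "svm", "nn"]


def _report(okc, classifier, dataset, role):
    m = ErrorMatrix([1], np.array([[10]]))
    return AccuracyReport(okc=okc, overall_accuracy=okc, sckc={1: okc},
                          matrix=m, classifier_name=classifier,
                          dataset_name=dataset, role=role)


def sim_table(rng, dataset_effect=0.0, classifier_effect=0.0,
              interaction=0.0, noise=0.3):
    """AIE tables with known factorial structure, okc_type as replicate."""
    d_eff = dataset_effect * np.linspace(-1, 1, len(DATASETS))
    c_eff = classifier_effect * np.linspace(-1, 1, len(CLASSIFIERS))
    rows = []
    for i, d in enumerate(DATASETS):
        for j, c in enumerate(CLASSIFIERS):
            inter = interaction * rng.normal() if interaction else 0.0
            for t in ("performance", "accuracy"):
                rows.append(dict(
                    classifier=c, dataset=d, okc_type=t, okc=np.nan,
                    aie=1.0 + d_eff[i] + c_eff[j] + inter
                    + rng.normal(0, noise),
                ))
    return AIETable(pd.DataFrame(rows), {"performance": 0.12, "accuracy": 0.03})


class TestAie:
    @pytest.mark.parametrize(
        "okc, okc_min, expected",
        [(0.98, 0.48, 0.50 / 0.48), (0.98, 0.58, 0.40 / 0.58), (0.5, 0.5, 0.0)],
    )
    def test_ratio_of_increment(self, okc, okc_min, expected):
        assert aie(okc, okc_min) == pytest.approx(expected)

    def test_published_percentages(self):
        assert 100 * aie(0.98, 0.48) == pytest.approx(104, abs=0.5)
        assert 100 * aie(0.98, 0.58) == pytest.approx(69, abs=0.5)

    def test_invalid_baseline(self):
        with pytest.raises(ValueError):
            aie(0.5, 0.0)

    def test_strictly_increasing_in_okc(self):
        vals = [aie(o, 0.4) for o in np.linspace(0.4, 1.0, 10)]
        assert np.all(np.diff(vals) > 0)


class TestBuildAieTable:
    def _reports(self):
        reps = []
        okcs = {"mlc": 0.8, "md": 0.5, "sid": 0.12}
        for c, okc in okcs.items():
            reps.append(_report(okc, c, "HMS", "training"))
            reps.append(_report(okc + 0.1, c, "SpecTex", "training"))
            reps.append(_report(okc / 4, c, "HMS", "test"))
        return reps

    def test_baseline_is_min_okc_on_baseline_dataset(self):
        table = build_aie_table(self._reports())
        assert table.okc_min["performance"] == pytest.approx(0.12)
        assert table.okc_min["accuracy"] == pytest.approx(0.03)

    def test_baseline_rows_include_zero_aie(self):
        table = build_aie_table(self._reports())
        t = table.table
        base = t[(t.dataset == "HMS") & (t.okc_type == "performance")]
        assert base["aie"].min() == pytest.approx(0.0)

    def test_scale_coupling(self):
        """Rescaling every OKC leaves AIE unchanged only because the
        baseline rescales with them."""
        reps = self._reports()
        doubled = [
            _report(0.5 * r.okc, r.classifier_name, r.dataset_name, r.role)
            for r in reps
        ]
        a = build_aie_table(reps).table.sort_values(
            ["classifier", "dataset", "okc_type"])["aie"].to_numpy()
        b = build_aie_table(doubled).table.sort_values(
            ["classifier", "dataset", "okc_type"])["aie"].to_numpy()
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_missing_baseline_dataset_errors(self):
        reps = [_report(0.5, "mlc", "SpecTex", "training")]
        with pytest.raises(ValueError, match="HMS"):
            build_aie_table(reps)


def anova_ss_oracle(df):
    """Balanced two-way ANOVA sums of squares from first principles."""
    y = df["aie"].to_numpy()
    grand = y.mean()
    a_means = df.groupby("dataset")["aie"].mean()
    b_means = df.groupby("classifier")["aie"].mean()
    cell = df.groupby(["dataset", "classifier"])["aie"].mean()
    n_a = df["dataset"].nunique()
    n_b = df["classifier"].nunique()
    r = len(df) / (n_a * n_b)
    ss_a = r * n_b * ((a_means - grand) ** 2).sum()
    ss_b = r * n_a * ((b_means - grand) ** 2).sum()
    ss_cells = r * ((cell - grand) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    ss_tot = ((y - grand) ** 2).sum()
    return ss_a, ss_b, ss_ab, ss_tot - ss_cells


class TestTwoWayAnova:
    def test_effect_sums_of_squares_vanish_on_constant_data(self):
        rows = [
            dict(classifier=c, dataset=d, okc_type=t, okc=np.nan, aie=1.0)
            for d in DATASETS for c in CLASSIFIERS
            for t in ("performance", "accuracy")
        ]
        table = AIETable(pd.DataFrame(rows), {"performance": 0.1,
                                              "accuracy": 0.1})
        res = two_way_anova(table)
        for term in ("C(dataset)", "C(classifier)", "C(dataset):C(classifier)"):
            assert res.anova_table.loc[term, "sum_sq"] == pytest.approx(
                0.0, abs=1e-12
            )
        assert res.significant_terms() == []

    def test_matches_sum_of_squares_oracle(self, rng):
        table = sim_table(rng, dataset_effect=0.4, classifier_effect=0.2)
        res = two_way_anova(table)
        ss_a, ss_b, ss_ab, ss_err = anova_ss_oracle(table.table)
        at = res.anova_table
        assert at.loc["C(dataset)", "sum_sq"] == pytest.approx(ss_a)
        assert at.loc["C(classifier)", "sum_sq"] == pytest.approx(ss_b)
        assert at.loc["C(dataset):C(classifier)", "sum_sq"] == pytest.approx(
            ss_ab)
        assert at.loc["Residual", "sum_sq"] == pytest.approx(ss_err)

    def test_decomposition_identity(self, rng):
        table = sim_table(rng, dataset_effect=0.3)
        res = two_way_anova(table)
        total = ((table.table["aie"] - table.table["aie"].mean()) ** 2).sum()
        assert res.anova_table["sum_sq"].sum() == pytest.approx(total)

    def test_unreplicated_interaction_rejected(self, rng):
        table = sim_table(rng)
        thinned = AIETable(
            table.table[table.table.okc_type == "performance"], table.okc_min
        )
        with pytest.raises(ValueError, match="additive"):
            two_way_anova(thinned)
        res = two_way_anova(thinned, interaction=False)
        assert "C(dataset)" in res.anova_table.index

    def test_detects_injected_dataset_effect(self, rng):
        """With a real dataset main effect the dataset term should be
        significant; the null interaction should rarely be."""
        res = two_way_anova(sim_table(rng, dataset_effect=0.6, noise=0.2))
        assert res.p_value("C(dataset)") <= 0.05
        assert res.residual_df == 24  # 48 obs - 24 cell means


class TestDuncan:
    def test_identical_means_single_group(self):
        g = duncan_groups({"a": 1.0, "b": 1.0, "c": 1.0}, ms_error=0.1,
                          df_error=20, n_per_mean=8)
        assert set(g.letters) == {"a"}

    def test_huge_separation_distinct_groups(self):
        g = duncan_groups({"x": 0.0, "y": 100.0, "z": 200.0}, ms_error=0.01,
                          df_error=20, n_per_mean=8)
        assert len(set(g.letters)) == 3
        assert g.levels == ["z", "y", "x"]  # sorted descending

    def test_letters_match_protected_stretch_oracle(self, rng):
        """Two levels share a letter iff some contiguous stretch of the
        ordered means containing both passes its least-significant-range
        test (Duncan's protection rule), checked exhaustively."""
        for trial in range(5):
            means = {f"l{i}": v for i, v in
                     enumerate(rng.normal(0, 1.0, size=5))}
            ms_error, df_error, n = 0.8, 24, 4
            g = duncan_groups(means, ms_error, df_error, n, alpha=0.05)
            sorted_means = np.array(g.means)
            ranges = g.critical_ranges
            k = len(sorted_means)
            for i in range(k):
                for j in range(i + 1, k):
                    # pair (i, j) nonsignificant iff some stretch [a, b]
                    # containing it has range <= its critical range
                    nonsig = any(
                        sorted_means[a] - sorted_means[b] <= ranges[b - a + 1]
                        for a in range(0, i + 1)
                        for b in range(j, k)
                    )
                    share = bool(set(g.letters[i]) & set(g.letters[j]))
                    assert share == nonsig

    def test_order_consistency(self, rng):
        """If the outer pair of an ordered triple shares a letter, the
        middle mean shares it too."""
        for trial in range(10):
            means = {f"l{i}": v for i, v in
                     enumerate(rng.normal(0, 0.5, size=6))}
            g = duncan_groups(means, 0.5, 30, 4)
            for i in range(len(g.levels)):
                for j in range(i + 2, len(g.levels)):
                    common = set(g.letters[i]) & set(g.letters[j])
                    for mid in range(i + 1, j):
                        assert common <= set(g.letters[mid])

    def test_every_level_lettered(self, rng):
        g = duncan_groups({f"l{i}": rng.normal() for i in range(7)},
                          1.0, 12, 3)
        assert all(g.letters)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            duncan_groups({"a": 1.0}, ms_error=0.0, df_error=5, n_per_mean=2)
        with pytest.raises(ValueError):
            duncan_groups({"a": 1.0}, ms_error=1.0, df_error=0, n_per_mean=2)

    def test_from_anova_grouping(self, rng):
        table = sim_table(rng, dataset_effect=1.5, noise=0.1)
        res = two_way_anova(table)
        g = duncan_from_anova(table, res, "dataset")
        df = g.to_dataframe()
        assert set(df["level"]) == set(DATASETS)
        # strong injected spread: extremes must not share a letter
        assert not (set(df["group"].iloc[0]) & set(df["group"].iloc[-1]))
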