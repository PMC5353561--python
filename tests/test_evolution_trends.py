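import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from regustress.data_model import (
    GeneSet,
    GeneSetCollection,
    ValidationError,
)
from regustress.evolution_trends import (
    build_trend_table,
    classify_monotone,
    concordance_with_annotation,
    is_stepwise,
    region_shift_test,
    stepwise_pathway_profile,
    trend_tallies,
)
from conftest import make_study


def monotone_oracle(series, tol=0.0):
    d = np.diff(series)
    if all(x >= -tol for x in d) and any(x > tol for x in d):
        return "monotone_up"
    if all(x <= tol for x in d) and any(x < -tol for x in d):
        return "monotone_down"
    return "non_monotone"


class TestClassifyMonotone:
    @pytest.mark.parametrize(
        "series,expected",
        [
            ((0.1, 0.4, 0.5, 0.9, 1.2), "monotone_up"),
            ((1.2, 0.9, 0.5, 0.4, 0.1), "monotone_down"),
            ((0.0, 0.0, 0.0, 0.0, 0.0), "non_monotone"),  # no strict step
            ((0.1, 0.5, 0.3, 0.9, 1.2), "non_monotone"),
            ((0.0, 0.0, 0.0, 0.0, 0.1), "monotone_up"),  # one strict step suffices
        ],
    )
    def test_cases(self, series, expected):
        assert classify_monotone(series) == expected

    def test_tie_tolerance_absorbs_small_dips(self):
        series = (0.0, 0.5, 0.45, 1.0)
        assert classify_monotone(series) == "non_monotone"
        assert classify_monotone(series, tie_tolerance=0.1) == "monotone_up"

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError):
            classify_monotone([1.0])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(300):
            series = rng.normal(0, 1, 5).round(1)  # rounding forces ties sometimes
            assert classify_monotone(series) == monotone_oracle(series)

    def test_reversal_swaps_up_and_down(self, rng):
        for _ in range(100):
            s = rng.normal(0, 1, 5)
            fwd, rev = classify_monotone(s), classify_monotone(s[::-1])
            flip = {"monotone_up": "monotone_down", "monotone_down": "monotone_up",
                    "non_monotone": "non_monotone"}
            assert rev == flip[fwd]


@settings(derandomize=True, max_examples=80, deadline=None)
@given(
    series=st.lists(
        st.integers(min_value=-500, max_value=500), min_size=2, max_size=8, unique=True
    ).map(lambda xs: [x / 10.0 for x in xs])
)
def test_monotone_invariant_under_increasing_transforms(series):
    """Any strictly increasing transform of the whole series preserves the class."""
    base = classify_monotone(series)
    for f in (lambda x: 3.0 * x + 7.0, np.exp, lambda x: np.arctan(x / 10.0)):
        transformed = [float(f(np.array(v))) for v in series]
        assert classify_monotone(transformed) == base


class TestStepwise:
    def test_all_strict_steps(self):
        assert is_stepwise((1, 2, 3, 4, 5))

    def test_one_tie_still_stepwise_two_ties_not(self):
        assert is_stepwise((1, 2, 2, 4, 5))
        assert not is_stepwise((1, 2, 2, 2, 5))

    def test_non_monotone_never_stepwise(self):
        assert not is_stepwise((1, 3, 2, 4, 5))


def _ea_study(series_by_gene, n_strains=2, noise=None, rng=None):
    """Study with a parent plus per-strain samples realizing given log2-FC series."""
    genes = list(series_by_gene)
    timepoints = [0, 384, 744, 1224, 1824, 2496]
    baseline = 8.0
    samples, conditions, strains, times, cols = ["parent"], ["parent"], ["parent"], [0], {}
    cols["parent"] = np.full(len(genes), baseline)
    for s in range(n_strains):
        strain = f"strain{s}"
        for k, t in enumerate(timepoints):
            name = f"{strain}_h{t}"
            shift = np.array(
                [0.0 if k == 0 else series_by_gene[g][k - 1] for g in genes]
            )
            col = baseline + shift
            if noise is not None:
                col = col + rng.normal(0, noise, len(genes))
            cols[name] = col
            samples.append(name)
            conditions.append("evolved")
            strains.append(strain)
            times.append(t)
    vals = np.column_stack([cols[s] for s in samples])
    return make_study(
        vals, genes=genes, samples=samples, conditions=conditions,
        strains=strains, time_h=times,
    )


class TestTrendTable:
    def test_planted_classes_recovered_noise_free(self):
        series = {
            "up1": [0.2, 0.4, 0.6, 0.8, 1.0],
            "down1": [-0.2, -0.4, -0.6, -0.8, -1.0],
            "zig": [0.5, -0.5, 0.5, -0.5, 0.5],
        }
        trends = build_trend_table(_ea_study(series), "parent")
        by_gene = trends.groupby("gene")["trend"].unique()
        assert list(by_gene["up1"]) == ["monotone_up"]
        assert list(by_gene["down1"]) == ["monotone_down"]
        assert list(by_gene["zig"]) == ["non_monotone"]
        assert trends["stepwise"][trends["gene"] == "up1"].all()

    def test_below_detection_is_not_expressed(self):
        series = {"g": [0.1, 0.2, 0.3, 0.4, 0.5]}
        trends = build_trend_table(
            _ea_study(series), "parent", detection_threshold=20.0
        )
        assert (trends["trend"] == "not_expressed").all()

    def test_missing_parent_rejected(self):
        study = _ea_study({"g": [0.1, 0.2, 0.3, 0.4, 0.5]})
        with pytest.raises(ValidationError, match="ghost"):
            build_trend_table(study, "ghost")


class TestConcordance:
    def _trends(self, matches):
        rows = []
        for i, match in enumerate(matches):
            trend = "monotone_up" if match else "monotone_down"
            rows.append({"gene": f"g{i}", "strain": "s", "trend": trend})
        return pd.DataFrame(rows)

    def _sets(self, n):
        return GeneSetCollection(
            [GeneSet("tol", tuple(f"g{i}" for i in range(n)), category="tolerance",
                     directions={f"g{i}": "overexpression_tolerant" for i in range(n)})]
        )

    def test_nine_of_ten_is_ninety_percent(self):
        res = concordance_with_annotation(self._trends([True] * 9 + [False]), self._sets(10))
        assert res.percent == pytest.approx(90.0)
        assert res.n == 10

    def test_noise_free_planted_all_concordant(self):
        series = {f"g{i}": [0.3, 0.6, 0.9, 1.2, 1.5] for i in range(6)}
        study = _ea_study(series)
        trends = build_trend_table(study, "parent")
        sets = self._sets(6)
        res = concordance_with_annotation(trends, sets)
        assert res.percent == pytest.approx(100.0)
        assert set(res.per_strain.values()) == {100.0}

    def test_no_annotated_genes_is_undefined(self):
        res = concordance_with_annotation(self._trends([True]), GeneSetCollection([]))
        assert not res.defined and np.isnan(res.percent)


class TestRegionShift:
    def test_forced_upward_shift_significant(self):
        series = {f"g{i}": [0.0, 0.0, 1.0, 1.0, 1.0] for i in range(20)}
        study = _ea_study(series, n_strains=1)
        p, n = region_shift_test(study, list(series), 744, 1224, "strain0")
        assert n == 20 and p < 0.01

    def test_zero_differences_p_one(self):
        series = {f"g{i}": [0.0, 0.1, 0.1, 0.5, 0.5] for i in range(5)}
        study = _ea_study(series, n_strains=1)
        p, _ = region_shift_test(study, list(series), 744, 1224, "strain0")
        assert p == 1.0

    def test_matches_sign_flip_permutation_oracle(self, rng):
        """Exhaustive sign-flip enumeration reproduces the one-sided signed-rank p."""
        series = {f"g{i}": list(rng.normal(0, 0.5, 5)) for i in range(10)}
        study = _ea_study(series, n_strains=1)
        p, _ = region_shift_test(study, list(series), 384, 2496, "strain0")
        d = np.array([series[g][4] - series[g][0] for g in series])
        ranks = pd.Series(np.abs(d)).rank().to_numpy()
        observed = ranks[d > 0].sum()
        count = total = 0
        for signs in itertools.product([0, 1], repeat=len(d)):
            total += 1
            count += ranks[np.array(signs, dtype=bool)].sum() >= observed
        assert p == pytest.approx(count / total, abs=1e-9)

    def test_too_few_genes_rejected(self):
        series = {"g1": [0.1] * 5, "g2": [0.1] * 5}
        study = _ea_study(series, n_strains=1)
        with pytest.raises(ValidationError):
            region_shift_test(study, list(series), 384, 744, "strain0")

    def test_null_pvalues_near_uniform(self, rng):
        """Kolmogorov-Smirnov check of null p-values (scaled-down: 300 nulls,
        20 genes; the discrete signed-rank support keeps D small but nonzero)."""
        from scipy import stats

        n_genes, n_sims = 20, 300
        ps = []
        for _ in range(n_sims):
            d = rng.normal(0, 1, n_genes)
            ps.append(float(stats.wilcoxon(d, alternative="greater").pvalue))
        d_stat = stats.kstest(ps, "uniform").statistic
        assert d_stat < 0.08


class TestPathwayProfile:
    def test_shared_series_returned(self):
        series = {f"g{i}": [1, 2, 3, 4, 5] for i in range(4)}
        trends = build_trend_table(_ea_study(series, n_strains=1), "parent")
        prof = stepwise_pathway_profile(trends, list(series))
        np.testing.assert_allclose(prof.to_numpy(), [1, 2, 3, 4, 5])
        assert list(prof.index) == [384, 744, 1224, 1824, 2496]

    def test_union_is_size_weighted_mean(self, rng):
        series = {f"a{i}": list(rng.normal(0, 1, 5)) for i in range(3)}
        series.update({f"b{i}": list(rng.normal(0, 1, 5)) for i in range(5)})
        trends = build_trend_table(_ea_study(series, n_strains=1), "parent")
        a = stepwise_pathway_profile(trends, [g for g in series if g.startswith("a")])
        b = stepwise_pathway_profile(trends, [g for g in series if g.startswith("b")])
        u = stepwise_pathway_profile(trends, list(series))
        np.testing.assert_allclose(u, (3 * a + 5 * b) / 8, atol=1e-12)

    def test_empty_overlap_rejected(self):
        series = {"g1": [1, 2, 3, 4, 5], "g2": [1, 2, 3, 4, 5], "g3": [1, 2, 3, 4, 5]}
        trends = build_trend_table(_ea_study(series, n_strains=1), "parent")
        with pytest.raises(ValidationError):
            stepwise_pathway_profile(trends, ["nope"])


def test_trend_tallies_pooled_and_per_strain():
    series = {
        "up1": [0.2, 0.4, 0.6, 0.8, 1.0],
        "zig": [0.5, -0.5, 0.5, -0.5, 0.5],
    }
    trends = build_trend_table(_ea_study(series, n_strains=3), "parent")
    tallies = trend_tallies(trends).set_index("scope")
    assert tallies.loc["pooled", "n_expressed"] == 6
    assert tallies.loc["pooled", "pct_monotone"] == pytest.approx(50.0)
    for strain in ("strain0", "strain1", "strain2"):
        assert tallies.loc[strain, "n_monotone"] == 1
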