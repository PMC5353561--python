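import itertools
import math

import numpy as np
import pytest

from regustress._utils import pct_display
from regustress.data_model import (
    ContrastDesign,
    GeneSet,
    GeneSetCollection,
    ValidationError,
)
from regustress.set_response import (
    correlate_processes,
    correlate_with_covariate,
    enrich_gene_sets,
    percent_mean_expression_change,
    set_deg_proportions,
    set_response_level,
)
from conftest import make_deg_table, make_study


def hypergeom_enumeration_oracle(universe, deg_genes, set_genes):
    """P(overlap >= observed) by exhaustive enumeration of all draws."""
    observed = len(set(deg_genes) & set(set_genes))
    hits = total = 0
    for draw in itertools.combinations(universe, len(deg_genes)):
        total += 1
        hits += len(set(draw) & set(set_genes)) >= observed
    return hits / total


class TestProportions:
    def test_twenty_of_twentysix_displays_77(self):
        calls = {f"m{i}": ("up" if i < 20 else "ns") for i in range(26)}
        deg = make_deg_table(calls)
        sets = GeneSetCollection([GeneSet("motility", tuple(calls), category="pathway")])
        prof = set_deg_proportions(deg, sets).iloc[0]
        assert prof["n_up"] == 20 and prof["n_in_set_expressed"] == 26
        assert prof["pct_up"] == 77

    def test_not_expressed_members_excluded_from_denominator(self):
        calls = {"a": "up", "b": "not_expressed", "c": "down", "d": "ns"}
        deg = make_deg_table(calls)
        sets = GeneSetCollection([GeneSet("s", ("a", "b", "c", "d"))])
        prof = set_deg_proportions(deg, sets).iloc[0]
        assert prof["n_in_set_expressed"] == 3
        assert prof["prop_up"] == pytest.approx(1 / 3)

    def test_disjoint_set_is_undefined(self):
        deg = make_deg_table({"a": "up"})
        sets = GeneSetCollection([GeneSet("other", ("zz",))])
        prof = set_deg_proportions(deg, sets).iloc[0]
        assert not prof["defined"]
        assert np.isnan(prof["prop_up"])

    def test_matches_direct_counting(self, rng):
        genes = [f"g{i}" for i in range(200)]
        calls = {
            g: rng.choice(["up", "down", "ns", "not_expressed"], p=[0.2, 0.2, 0.5, 0.1])
            for g in genes
        }
        deg = make_deg_table(calls)
        members = list(rng.choice(genes, 60, replace=False))
        sets = GeneSetCollection([GeneSet("s", tuple(members))])
        prof = set_deg_proportions(deg, sets).iloc[0]
        exp = [g for g in members if calls[g] != "not_expressed"]
        assert prof["n_up"] == sum(calls[g] == "up" for g in exp)
        assert prof["n_down"] == sum(calls[g] == "down" for g in exp)
        assert prof["prop_up"] + prof["prop_down"] <= 1
        assert prof["n_up"] + prof["n_down"] <= prof["n_in_set_expressed"]

    def test_permutation_invariance(self, rng):
        genes = [f"g{i}" for i in range(50)]
        calls = {g: rng.choice(["up", "down", "ns"]) for g in genes}
        sets = GeneSetCollection([GeneSet("s", tuple(genes))])
        a = set_deg_proportions(make_deg_table(calls), sets)
        shuffled = {g: calls[g] for g in rng.permutation(genes)}
        b = set_deg_proportions(make_deg_table(shuffled), sets)
        assert a["prop_up"].iloc[0] == b["prop_up"].iloc[0]

    @pytest.mark.parametrize(
        "num,den,expected",
        [(20, 26, 77), (12, 13, 92), (3, 4, 75), (16, 21, 76),
         (977, 1623, 60), (480, 977, 49), (96, 180, 53), (28, 43, 65),
         (20, 44, 45), (11, 20, 55), (78, 213, 37), (54, 213, 25), (21, 27, 78)],
    )
    def test_display_rounding_matches_printed_convention(self, num, den, expected):
        assert pct_display(num / den) == expected

    def test_half_rounds_away_from_zero(self):
        assert pct_display(0.775) == 78
        assert pct_display(-0.775) == -78


class TestResponseLevels:
    def test_mean_lfc_of_unit_shifts(self):
        deg = make_deg_table({"a": "up", "b": "up"}, fold_changes={"a": 2.0, "b": 2.0})
        level = set_response_level(None, deg, ["a", "b"], "mean_lfc")
        assert level["c1"] == pytest.approx(1.0)

    def test_prop_up_minus_down(self):
        calls = {f"g{i}": "up" for i in range(4)}
        calls.update({"g4": "down"})
        calls.update({f"g{i}": "ns" for i in range(5, 10)})
        deg = make_deg_table(calls)
        level = set_response_level(None, deg, list(calls), "prop_up_minus_down")
        assert level["c1"] == pytest.approx(0.4 - 0.1)

    def test_mean_expression_uses_treatment_group(self, rng):
        study = make_study(np.array([[5.0, 7.0, 1.0, 1.0]] * 2))
        c = ContrastDesign("c1", ("s1", "s2"), ("s3", "s4"))
        deg = make_deg_table({"g1": "ns", "g2": "ns"})
        level = set_response_level(study, deg, ["g1", "g2"], "mean_expression", [c])
        assert level["c1"] == pytest.approx(6.0)

    def test_unknown_method_rejected(self):
        deg = make_deg_table({"a": "up"})
        with pytest.raises(ValidationError, match="median"):
            set_response_level(None, deg, ["a"], "median")

    def test_percent_change_of_mean_expression(self):
        vals = np.log2(np.array([[100.0, 80.0, 80.0]]))
        study = make_study(vals, samples=["parent", "e1", "e2"],
                           conditions=["parent", "evolved", "evolved"])
        pct = percent_mean_expression_change(study, "parent", ["e1", "e2"], ["g1"])
        assert pct == pytest.approx(-20.0)


class TestCorrelations:
    def test_exact_linear_gives_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = correlate_with_covariate([2 * v + 1 for v in x], x)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_reversed_covariate_negates(self, rng):
        levels = rng.normal(size=7)
        cov = rng.normal(size=7)
        a = correlate_with_covariate(levels, cov)
        b = correlate_with_covariate(levels, -cov)
        assert a.r == pytest.approx(-b.r, abs=1e-12)

    def test_matches_closed_form(self, rng):
        x, y = rng.normal(size=7), rng.normal(size=7)
        res = correlate_with_covariate(x, y)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert res.r == pytest.approx(num / den, abs=1e-12)
        assert res.n == 7

    def test_constant_vector_flagged_not_zero(self):
        res = correlate_with_covariate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not res.defined and np.isnan(res.r)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            correlate_with_covariate([1.0, 2.0], [1.0, 2.0])

    def test_spearman_invariant_to_monotone_transform(self, rng):
        x, y = rng.normal(size=9), rng.normal(size=9)
        a = correlate_with_covariate(x, y, method="spearman")
        b = correlate_with_covariate(np.exp(x), y, method="spearman")
        assert a.r == pytest.approx(b.r, abs=1e-12)

    def test_process_correlation_identity_and_negation(self, rng):
        a = rng.normal(size=7)
        assert correlate_processes(a, a).r == pytest.approx(1.0, abs=1e-12)
        assert correlate_processes(a, -a).r == pytest.approx(-1.0, abs=1e-12)
        shared = correlate_with_covariate(a, a * 2 + 1)
        assert correlate_processes(a, a * 2 + 1).r == pytest.approx(shared.r, abs=1e-15)


class TestEnrichment:
    def test_full_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(20)]
        deg = universe[:5]
        sets = GeneSetCollection([GeneSet("s", tuple(deg))])
        res = enrich_gene_sets(deg, universe, sets)
        assert res["p"].iloc[0] == pytest.approx(1 / math.comb(20, 5), rel=1e-10)

    def test_disjoint_set_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        sets = GeneSetCollection([GeneSet("s", tuple(universe[5:]))])
        res = enrich_gene_sets(universe[:3], universe[:5], sets)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        universe = [f"g{i}" for i in range(12)]
        deg = list(rng.choice(universe, 4, replace=False))
        for size in (3, 6):
            members = tuple(rng.choice(universe, size, replace=False))
            sets = GeneSetCollection([GeneSet("s", members)])
            res = enrich_gene_sets(deg, universe, sets)
            oracle = hypergeom_enumeration_oracle(universe, deg, members)
            assert res["p"].iloc[0] == pytest.approx(oracle, rel=1e-9)

    def test_p_monotone_in_overlap(self):
        from scipy import stats
        ps = [float(stats.hypergeom.sf(k - 1, 30, 10, 8)) for k in range(0, 9)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_bh_adjustment_monotone_and_bounded(self, rng):
        universe = [f"g{i}" for i in range(40)]
        deg = list(rng.choice(universe, 10, replace=False))
        sets = GeneSetCollection(
            [GeneSet(f"s{j}", tuple(rng.choice(universe, 8, replace=False)))
             for j in range(6)]
        )
        res = enrich_gene_sets(deg, universe, sets, correction="BH").sort_values("p")
        assert (res["p_adj"] <= 1).all()
        assert res["p_adj"].is_monotonic_increasing

    def test_errors(self):
        sets = GeneSetCollection([GeneSet("s", ("a",))])
        with pytest.raises(ValidationError, match="universe"):
            enrich_gene_sets([], [], sets)
        with pytest.raises(ValidationError, match="ghost"):
            enrich_gene_sets(["ghost"], ["a"], sets)
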