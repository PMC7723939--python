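import itertools

import numpy as np
import pandas as pd
import pytest

from reaxpot.network import Reaction
from reaxpot.potential import (
    bootstrap_ranking_scores,
    call_significant_reactions,
    compute_reaction_potentials,
    reaction_enzyme_log2fc,
    reaction_log2fc,
    select_testable_reactions,
)

from .conftest import make_matrix


def fc(mapping):
    return pd.DataFrame({"log2FC": pd.Series(mapping, dtype=float)})


class TestSelectTestable:
    def test_requires_measured_substrate_product_and_enzyme(self, toy_network):
        metab = fc({"C00001": 0.1, "C00003": 0.2, "C00005": -0.1, "C00006": 0.0})
        enzyme = fc({"R1": 0.0, "R2": 0.1, "R3": 0.2})
        testable = select_testable_reactions(toy_network, metab, enzyme)
        # R1: substrate C00001, product C00003, enzyme measured -> in
        # R2: substrate C00003, product C00005, enzyme measured -> in
        # R3: substrate C00005, product C00006, enzyme measured -> in
        # R4: measured sides but no enzyme FC -> out; R5: product C00007 unmeasured -> out
        assert testable == ["R1", "R2", "R3"]

    def test_allow_missing_enzyme_waives_requirement(self, toy_network):
        metab = fc({"C00006": 0.5, "C00007": -0.5})
        assert select_testable_reactions(toy_network, metab, None) == []
        assert select_testable_reactions(
            toy_network, metab, None, allow_missing_enzyme=True
        ) == ["R3", "R4"] or select_testable_reactions(
            toy_network, metab, None, allow_missing_enzyme=True
        ) == ["R4"]


class TestReactionLog2FC:
    def test_direct_substitution(self):
        """enzyme 0.25 + substrate 1*1 - product 0.5*2 = 0.25."""
        rxn = Reaction("R", (("A", 1),), (("B", 2),), ("E",))
        result = reaction_log2fc(rxn, fc({"A": 1.0, "B": 0.5}), fc({"R": 0.25}))
        assert result.log2fc_r == pytest.approx(0.25)
        assert dict(result.breakdown) == pytest.approx(
            {"enzyme": 0.25, "substrate:A": 1.0, "product:B": -1.0}
        )

    def test_zero_inputs_give_zero(self):
        rxn = Reaction("R", (("A", 1),), (("B", 1),), ("E",))
        result = reaction_log2fc(rxn, fc({"A": 0.0, "B": 0.0}), fc({"R": 0.0}))
        assert result.log2fc_r == 0.0

    def test_swapping_sides_negates(self):
        metab = fc({"A": 0.7, "B": -0.3, "C": 1.1})
        enzyme = fc({"R": 0.0})
        fwd = Reaction("R", (("A", 1), ("B", 2)), (("C", 1),), ("E",))
        rev = Reaction("R", (("C", 1),), (("A", 1), ("B", 2)), ("E",))
        assert reaction_log2fc(fwd, metab, enzyme).log2fc_r == pytest.approx(
            -reaction_log2fc(rev, metab, enzyme).log2fc_r
        )

    def test_unmeasured_slots_contribute_zero(self):
        rxn = Reaction("R", (("A", 1), ("X", 2)), (("B", 1), ("Y", 1)), ("E",))
        result = reaction_log2fc(rxn, fc({"A": 0.5, "B": 0.2}), fc({"R": 0.1}))
        assert result.log2fc_r == pytest.approx(0.1 + 0.5 - 0.2)
        assert result.n_substrates_measured == 1
        assert result.n_products_measured == 1

    def test_missing_enzyme_raises_without_flag(self):
        rxn = Reaction("R", (("A", 1),), (("B", 1),), ())
        with pytest.raises(ValueError):
            reaction_log2fc(rxn, fc({"A": 0.5, "B": 0.2}), fc({}))
        res = reaction_log2fc(rxn, fc({"A": 0.5, "B": 0.2}), None, allow_missing_enzyme=True)
        assert res.log2fc_r == pytest.approx(0.3)

    def test_additivity_and_exponent_form_on_random_reactions(self):
        """log2FC_r equals the sum of its breakdown, and 2**log2FC_r equals the
        linear-scale ratio FC_p * prod FC_A^m / prod FC_B^m, to 1e-10."""
        rng = np.random.default_rng(11)
        for i in range(1000):
            n_sub, n_prod = rng.integers(1, 4), rng.integers(1, 4)
            ids = [f"C{j}" for j in range(n_sub + n_prod)]
            ms = rng.integers(1, 3, size=n_sub + n_prod)
            fcs = rng.normal(0, 1, size=n_sub + n_prod)
            enz_fc = float(rng.normal(0, 1))
            rxn = Reaction(
                f"R{i}",
                tuple((ids[j], int(ms[j])) for j in range(n_sub)),
                tuple((ids[j], int(ms[j])) for j in range(n_sub, n_sub + n_prod)),
                ("E",),
            )
            res = reaction_log2fc(rxn, fc(dict(zip(ids, fcs))), fc({rxn.id: enz_fc}))
            assert res.log2fc_r == pytest.approx(sum(v for _, v in res.breakdown), abs=1e-12)
            linear = 2.0**enz_fc
            for j in range(n_sub):
                linear *= (2.0 ** fcs[j]) ** ms[j]
            for j in range(n_sub, n_sub + n_prod):
                linear /= (2.0 ** fcs[j]) ** ms[j]
            assert 2.0**res.log2fc_r == pytest.approx(linear, rel=1e-10)


class TestEnzymeFoldChanges:
    def test_multiple_enzymes_summed_before_fold_change(self, toy_network):
        # R5 lists E1 and E2; activities must be summed per sample, then logged
        activity = make_matrix(
            [[3.0, 3.0, 7.0, 7.0], [1.0, 1.0, 1.0, 1.0], [2.0, 2.0, 2.0, 2.0]],
            ["E1", "E2", "E3"],
        )
        table = reaction_enzyme_log2fc(toy_network, activity)
        expected_r5 = np.log2(7 + 1 + 1) - np.log2(3 + 1 + 1)
        assert table.loc["R5", "log2FC"] == pytest.approx(expected_r5)
        assert table.loc["R5", "n_enzymes_measured"] == 2
        expected_r1 = np.log2(8.0) - np.log2(4.0)
        assert table.loc["R1", "log2FC"] == pytest.approx(expected_r1)
        assert "R4" not in table.index  # no enzyme annotation


class TestBootstrap:
    def make_result(self, metab, enzyme, sub=("A",), prod=("B",)):
        rxn = Reaction("R", tuple((s, 1) for s in sub), tuple((p, 1) for p in prod), ("E",))
        return reaction_log2fc(rxn, metab, enzyme)

    def test_zero_observed_gives_score_one(self):
        metab = fc({"A": 0.0, "B": 0.0, "X": 1.0})
        enzyme = fc({"R": 0.0})
        res = self.make_result(metab, enzyme)
        scored = bootstrap_ranking_scores([res], metab, enzyme, n_boot=100, seed=1)
        assert scored[0].ranking_score == pytest.approx(1.0)

    def test_unbeatable_observation_gets_minimal_score(self):
        metab = fc({"A": 10.0, "B": -10.0, "X": 0.1})
        enzyme = fc({"R": 0.0})
        res = self.make_result(metab, enzyme)
        # pool max gives |null| <= 20.5 < observed 20.0? observed = 10+10 = 20
        # shrink the pool so no draw can reach the observed value
        pool = fc({"A": 0.1, "B": -0.1, "X": 0.05})
        scored = bootstrap_ranking_scores([res], pool, enzyme, n_boot=200, seed=1)
        assert scored[0].ranking_score == pytest.approx(1.0 / 201.0)

    def test_matches_exhaustive_enumeration(self):
        """Sampled score at n_boot=10000 matches brute-force enumeration of all
        slot assignments within three binomial standard errors."""
        metab_pool = [0.4, -0.8]
        enz_pool = [0.3]
        metab = fc({"A": 0.4, "B": -0.8})
        enzyme = fc({"R": 0.3})
        res = self.make_result(metab, enzyme)
        observed = abs(res.log2fc_r)  # 0.3 + 0.4 + 0.8 = 1.5
        # enumerate all (substrate, product, enzyme) pool assignments
        hits = total = 0
        for a, b, e in itertools.product(metab_pool, metab_pool, enz_pool):
            total += 1
            if abs(e + a - b) >= observed - 1e-12:
                hits += 1
        exact = hits / total
        n_boot = 10_000
        scored = bootstrap_ranking_scores([res], metab, enzyme, n_boot=n_boot, seed=3)
        se = np.sqrt(exact * (1 - exact) / n_boot) if 0 < exact < 1 else 1e-4
        expected = (1 + exact * n_boot) / (n_boot + 1)
        assert scored[0].ranking_score == pytest.approx(expected, abs=max(3 * se, 3e-4))

    def test_reproducible_and_order_invariant(self, toy_network):
        metab = fc({"C00001": 0.4, "C00002": -0.2, "C00003": 0.9, "C00005": 0.3,
                    "C00006": -0.7})
        enzyme = fc({"R1": 0.2, "R2": -0.1, "R3": 0.5})
        results = compute_reaction_potentials(toy_network, metab, enzyme)
        fwd = bootstrap_ranking_scores(results, metab, enzyme, n_boot=300, seed=9)
        rev = bootstrap_ranking_scores(results[::-1], metab, enzyme, n_boot=300, seed=9)
        by_id_fwd = {r.reaction_id: r.ranking_score for r in fwd}
        by_id_rev = {r.reaction_id: r.ranking_score for r in rev}
        assert by_id_fwd == by_id_rev
        again = bootstrap_ranking_scores(results, metab, enzyme, n_boot=300, seed=9)
        assert [r.ranking_score for r in again] == [r.ranking_score for r in fwd]

    def test_scores_bounded_in_unit_interval(self, toy_network):
        rng = np.random.default_rng(4)
        metab = fc({c: rng.normal() for c in toy_network.compounds})
        enzyme = fc({r: rng.normal() for r in ["R1", "R2", "R3", "R5"]})
        results = compute_reaction_potentials(toy_network, metab, enzyme)
        scored = bootstrap_ranking_scores(results, metab, enzyme, n_boot=50, seed=5)
        for r in scored:
            assert 0.0 < r.ranking_score <= 1.0

    def test_invalid_n_boot(self):
        with pytest.raises(ValueError):
            bootstrap_ranking_scores([], fc({"A": 1.0}), None, n_boot=0, seed=1)


class TestCallSignificantReactions:
    @pytest.mark.parametrize(
        "score, log2fc_r, expected, direction",
        [
            (0.01, -0.8, True, "down"),
            (0.01, 0.4, False, "up"),
            (0.05, 2.0, False, "up"),  # strict score cutoff
            (0.049, 0.51, True, "up"),
        ],
    )
    def test_cutoffs(self, score, log2fc_r, expected, direction):
        rxn = Reaction("R", (("A", 1),), (("B", 1),), ("E",))
        res = reaction_log2fc(
            rxn, fc({"A": log2fc_r, "B": 0.0}), fc({"R": 0.0})
        )
        from dataclasses import replace

        res = replace(res, ranking_score=score)
        called = call_significant_reactions([res])[0]
        assert called.significant == expected
        assert called.direction == direction
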