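"""Causal-graph machinery: parsing, d-separation, adjustment sets,
implied independences and the residual-based data-consistency tests."""

import numpy as np
import pandas as pd
import pytest

from caniact import dag as dag_mod
from caniact.dag import (
    CausalDag,
    DagParseError,
    IndependenceClaim,
    d_separated,
    implied_independences,
    minimal_adjustment_sets,
    parse_dag,
    simulate_linear_gaussian,
    test_independences as run_ci_tests,
)
from caniact.pipeline import packaged_dag_path

from oracles import (
    brute_force_d_separated,
    brute_force_minimal_backdoor_sets,
    random_dag,
)


class TestParsing:
    def test_minimal_chain(self):
        d = parse_dag("A -> B\nB -> C")
        assert set(d.nodes) == {"A", "B", "C"}
        assert d.observed == {"A", "B", "C"}
        assert set(d.edges) == {("A", "B"), ("B", "C")}

    def test_latent_marker_and_comments(self):
        d = parse_dag("# comment\nU [latent]\nU -> X\nU -> Y\n")
        assert d.latent == {"U"}
        assert d.observed == {"X", "Y"}

    def test_smallest_cycle_rejected(self):
        with pytest.raises(DagParseError, match="cycle"):
            parse_dag("A -> B\nB -> A")

    def test_duplicate_declaration_rejected(self):
        with pytest.raises(DagParseError, match="duplicate"):
            parse_dag("A [latent]\nA [latent]")

    def test_fixture_round_trips_through_serialisation(self):
        d = dag_mod.load_dag(packaged_dag_path())
        assert parse_dag(d.to_text()) == d
        # canonical form is a fixed point
        assert parse_dag(d.to_text()).to_text() == d.to_text()

    def test_empty_graph_rejected(self):
        with pytest.raises(DagParseError):
            CausalDag(nodes={}, edges=())


class TestDSeparation:
    def test_chain_rules(self):
        d = parse_dag("A -> B\nB -> C")
        assert d_separated(d, "A", "C", {"B"})
        assert not d_separated(d, "A", "C", set())

    def test_collider_rules(self):
        d = parse_dag("A -> B\nC -> B")
        assert d_separated(d, "A", "C", set())
        assert not d_separated(d, "A", "C", {"B"})

    def test_unknown_token_raises(self):
        d = parse_dag("A -> B")
        with pytest.raises(KeyError):
            d_separated(d, "A", "Z", set())

    def test_agrees_with_path_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(120):
            d = random_dag(rng)
            names = sorted(d.nodes)
            x, y = rng.choice(names, size=2, replace=False)
            rest = [n for n in names if n not in (x, y)]
            k = rng.integers(0, len(rest) + 1)
            given = set(rng.choice(rest, size=k, replace=False)) if k else set()
            assert d_separated(d, x, y, given) == brute_force_d_separated(
                d, x, y, given
            )


class TestAdjustmentSets:
    def test_textbook_confounder(self):
        d = parse_dag("Z -> X\nZ -> Y\nX -> Y")
        sets = minimal_adjustment_sets(d, "X", "Y")
        assert [sorted(s.members) for s in sets] == [["Z"]]

    def test_unobservable_confounder(self):
        d = parse_dag("Z [latent]\nZ -> X\nZ -> Y\nX -> Y")
        assert minimal_adjustment_sets(d, "X", "Y") == []

    def test_no_confounding_needs_empty_set(self):
        d = parse_dag("X -> Y")
        sets = minimal_adjustment_sets(d, "X", "Y")
        assert len(sets) == 1 and sets[0].members == frozenset()

    def test_exposure_equals_outcome_rejected(self):
        d = parse_dag("X -> Y")
        with pytest.raises(ValueError):
            minimal_adjustment_sets(d, "X", "X")

    def test_matches_exhaustive_subset_search(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            d = random_dag(rng)
            obs = sorted(d.observed)
            if len(obs) < 2:
                continue
            x, y = rng.choice(obs, size=2, replace=False)
            got = [s.members for s in minimal_adjustment_sets(d, x, y)]
            assert got == brute_force_minimal_backdoor_sets(d, x, y)

    def test_no_descendant_of_exposure_in_any_set(self):
        d = dag_mod.load_dag(packaged_dag_path())
        for exposure in ("breed_size", "neuter_status", "weight_status"):
            desc = d.descendants(exposure)
            for s in minimal_adjustment_sets(d, exposure, "active_minutes"):
                assert not (s.members & desc)

    def test_node_count_guard(self):
        nodes = {f"n{i}": True for i in range(30)}
        d = CausalDag(nodes=nodes, edges=(("n0", "n1"),))
        with pytest.raises(ValueError, match="guard"):
            minimal_adjustment_sets(d, "n0", "n1")


class TestImpliedIndependences:
    def test_chain(self):
        d = parse_dag("A -> B\nB -> C")
        claims = implied_independences(d)
        assert [(c.x, c.y, set(c.given)) for c in claims] == [("A", "C", {"B"})]

    def test_complete_dag_yields_nothing(self):
        d = parse_dag("A -> B\nA -> C\nB -> C")
        assert implied_independences(d) == []

    def test_fixture_claims_are_self_consistent(self):
        d = dag_mod.load_dag(packaged_dag_path())
        claims = implied_independences(d, observed_only=True)
        assert claims  # the study graph is sparse enough to imply plenty
        for c in claims:
            assert d_separated(d, c.x, c.y, c.given)
            assert {c.x, c.y} | c.given <= d.observed
            # minimality: no smaller-or-equal-size strict subset separates
            for member in c.given:
                assert not d_separated(d, c.x, c.y, c.given - {member})

    def test_invariant_to_declaration_order(self):
        text = "A -> B\nB -> C\nD -> C\n"
        d1 = parse_dag("A\nB\nC\nD\n" + text)
        d2 = parse_dag("D\nC\nB\nA\n" + text)
        k1 = [c.key() for c in implied_independences(d1)]
        k2 = [c.key() for c in implied_independences(d2)]
        assert k1 == k2

    def test_latent_mediated_pairs_are_omitted_when_observed_only(self):
        d = parse_dag("M [latent]\nX -> M\nM -> Y")
        assert implied_independences(d, observed_only=True) == []
        full = implied_independences(d, observed_only=False)
        assert [(c.x, c.y) for c in full] == [("X", "Y")]


class TestIndependenceTests:
    def test_perfect_dependence_rejected(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(200)
        data = pd.DataFrame({"A": a, "C": a})
        (claim,) = run_ci_tests(
            [IndependenceClaim("A", "C", frozenset())], data
        )
        assert claim.rejected

    def test_conditioning_removes_chain_dependence(self):
        d = parse_dag("A -> B\nB -> C")
        data = simulate_linear_gaussian(d, 2000, seed=3)
        claims = run_ci_tests(
            [
                IndependenceClaim("A", "C", frozenset({"B"})),
                IndependenceClaim("A", "C", frozenset()),
            ],
            data,
        )
        assert not claims[0].rejected  # d-separated claim holds
        assert claims[1].rejected  # marginal dependence detected

    def test_constant_column_warns_instead_of_testing(self):
        data = pd.DataFrame({"A": [1.0] * 50, "C": np.arange(50.0)})
        (claim,) = run_ci_tests(
            [IndependenceClaim("A", "C", frozenset())], data
        )
        assert claim.warning is not None and claim.p_value is None

    def test_categorical_conditioning_set_is_encoded(self):
        rng = np.random.default_rng(5)
        g = rng.choice(["a", "b", "c"], size=1500)
        shift = pd.Series(g).map({"a": 0.0, "b": 2.0, "c": -2.0}).to_numpy()
        x = shift + rng.standard_normal(1500)
        y = shift + rng.standard_normal(1500)
        data = pd.DataFrame({"x": x, "y": y, "g": g})
        tested = run_ci_tests(
            [
                IndependenceClaim("x", "y", frozenset({"g"})),
                IndependenceClaim("x", "y", frozenset()),
            ],
            data,
        )
        assert not tested[0].rejected
        assert tested[1].rejected

    def test_false_rejection_rate_near_alpha(self):
        # 40 independent pairs at alpha=0.05: expected 2 rejections
        rng = np.random.default_rng(11)
        n, pairs, alpha = 2000, 40, 0.05
        rejections = 0
        for i in range(pairs):
            data = pd.DataFrame(rng.standard_normal((n, 2)), columns=["A", "C"])
            (c,) = run_ci_tests(
                [IndependenceClaim("A", "C", frozenset())], data, alpha=alpha
            )
            rejections += bool(c.rejected)
        se = np.sqrt(pairs * alpha * (1 - alpha))
        assert abs(rejections - pairs * alpha) <= 3 * se


class TestLinearGaussianSimulation:
    def test_deterministic_under_seed(self):
        d = parse_dag("A -> B\nB -> C")
        df1 = simulate_linear_gaussian(d, 100, seed=9)
        df2 = simulate_linear_gaussian(d, 100, seed=9)
        pd.testing.assert_frame_equal(df1, df2)

    def test_latent_columns_hidden_by_default(self):
        d = parse_dag("U [latent]\nU -> X\nU -> Y")
        df = simulate_linear_gaussian(d, 50, seed=1)
        assert list(df.columns) == ["X", "Y"]
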