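import itertools

import numpy as np
import pytest

from _oracles import naive_fixpoint, naive_learn
from bnstratify.learning import (
    BNFamily,
    BooleanFamilyLearner,
    BooleanNetwork,
    Experiment,
    classify_behaviors,
    clause_frequencies,
    family_from_json_obj,
    family_to_json_obj,
    fixpoint,
    learn,
    mse,
    predict,
    union_network,
)
from bnstratify.pkn import PKN, Clause, HyperGraph, SignedEdge, expand_hypergraph


def net(*clauses: Clause) -> BooleanNetwork:
    return BooleanNetwork(frozenset(clauses))


C = Clause


class TestFixpoint:
    def test_and_gate_with_inhibitor(self):
        n = net(C("R", (("S", 1), ("I", -1))))
        assert fixpoint(n, {"S": 1, "I": 0})["R"] == 1
        assert fixpoint(n, {"S": 1, "I": 1})["R"] == 0

    def test_chain_propagates(self):
        n = net(C("A", (("S", 1),)), C("R", (("A", 1),)))
        fp = fixpoint(n, {"S": 1})
        assert (fp["A"], fp["R"]) == (1, 1)
        assert fixpoint(n, {"S": 0})["R"] == 0

    def test_clamped_nodes_never_change(self):
        n = net(C("A", (("S", 1),)), C("R", (("A", 1),)))
        fp = fixpoint(n, {"S": 1, "A": 0})
        assert fp["A"] == 0 and fp["R"] == 0

    def test_unregulated_node_defaults_to_zero(self):
        n = net(C("R", (("S", 1), ("X", 1))))
        assert fixpoint(n, {"S": 1})["X"] == 0
        assert fixpoint(n, {"S": 1})["R"] == 0

    def test_oscillation_reports_zero_with_warning(self, caplog):
        n = net(C("A", (("B", -1),)), C("B", (("A", 1),)))
        with caplog.at_level("WARNING"):
            fp = fixpoint(n, {}, nodes=["A", "B"])
        assert fp == {"A": 0, "B": 0}
        assert any("oscillatory" in r.message for r in caplog.records)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_state_space_simulation(self, seed):
        """Bit-parallel sweeps equal naive dictionary simulation on random nets."""
        rng = np.random.default_rng(seed)
        n_nodes = int(rng.integers(3, 11))
        nodes = [f"n{i}" for i in range(n_nodes)]
        clauses = []
        for _ in range(int(rng.integers(1, 2 * n_nodes))):
            target = nodes[int(rng.integers(n_nodes))]
            k = int(rng.integers(1, 3))
            regs = rng.choice(n_nodes, size=k, replace=False)
            lits = tuple(
                (nodes[int(r)], int(rng.choice([1, -1])))
                for r in regs
                if nodes[int(r)] != target
            )
            if lits:
                clauses.append(C(target, lits))
        network = BooleanNetwork(frozenset(clauses))
        n_clamped = int(rng.integers(0, n_nodes + 1))
        clamped = {
            nodes[i]: int(rng.integers(2))
            for i in rng.choice(n_nodes, size=n_clamped, replace=False)
        }
        ours = fixpoint(network, clamped, nodes=nodes)
        ref_clauses = [(c.target, list(c.literals)) for c in network.clauses]
        ref, osc = naive_fixpoint(ref_clauses, clamped, nodes)
        assert ours == ref


class TestPredictAndMse:
    def test_single_network_family_equals_fixpoint(self):
        n = net(C("R", (("S", 1),)))
        fam = BNFamily([n], 0.0, 1, nodes=("R", "S"), readouts=("R",))
        assert predict(fam, {"S": 1}, ["R"]) == {"R": 1.0}

    def test_family_mean_is_fraction_of_networks(self):
        fam = BNFamily(
            [net(C("R", (("S", 1),))), net(C("R", (("S", -1),)))],
            0.0,
            1,
            nodes=("R", "S"),
            readouts=("R",),
        )
        assert predict(fam, {"S": 1}, ["R"]) == {"R": 0.5}

    def test_mse_examples(self):
        n = net(C("R", (("S", 1),)))
        exps = [Experiment({"S": 1}, {"R": 1.0}), Experiment({"S": 0}, {"R": 0.0})]
        assert mse(n, exps) == 0.0
        assert mse(n, [Experiment({"S": 1}, {"R": 0.5})]) == pytest.approx(0.25)

    def test_mse_bounded_by_one(self):
        n = net(C("R", (("S", 1),)))
        assert mse(n, [Experiment({"S": 1}, {"R": 0.0})]) <= 1.0


def toy_hypergraph() -> HyperGraph:
    pkn = PKN([SignedEdge("S", "R", 1), SignedEdge("S", "R", -1)])
    return expand_hypergraph(pkn)


class TestLearn:
    def test_unique_optimum_is_found(self):
        hg = toy_hypergraph()
        exps = [Experiment({"S": 1}, {"R": 1.0}), Experiment({"S": 0}, {"R": 0.0})]
        fam = learn(hg, exps)
        assert fam.fitness == 0.0 and fam.size == 1
        assert fam.networks == [net(C("R", (("S", 1),)))]

    def test_all_zero_readouts_select_the_empty_network(self):
        hg = toy_hypergraph()
        exps = [Experiment({"S": 1}, {"R": 0.0}), Experiment({"S": 0}, {"R": 0.0})]
        fam = learn(hg, exps)
        assert fam.networks == [BooleanNetwork(frozenset())]
        assert fam.fitness == 0.0 and fam.size == 0

    def test_symmetric_clauses_both_enter_the_family(self):
        """Two regulators indistinguishable on the data give a 2-network family."""
        pkn = PKN([SignedEdge("A", "R", 1), SignedEdge("B", "R", 1)])
        hg = expand_hypergraph(pkn, max_inputs=1)
        exps = [
            Experiment({"A": 1, "B": 1}, {"R": 1.0}),
            Experiment({"A": 0, "B": 0}, {"R": 0.0}),
        ]
        fam = learn(hg, exps)
        assert len(fam.networks) == 2
        assert {n.sorted_clauses()[0].literals[0][0] for n in fam.networks} == {"A", "B"}

    def test_cap_exceeded_advises_backend(self):
        hg = toy_hypergraph()
        with pytest.raises(ValueError, match="cap"):
            learn(hg, [Experiment({"S": 1}, {"R": 1.0})], max_clauses=1)

    def test_fit_tolerance_widens_the_family(self):
        hg = toy_hypergraph()
        exps = [Experiment({"S": 1}, {"R": 1.0}), Experiment({"S": 0}, {"R": 0.0})]
        strict = learn(hg, exps)
        loose = learn(hg, exps, fit_tolerance=1.0, size_tolerance=3)
        assert len(loose.networks) > len(strict.networks)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_enumeration_oracle(self, seed):
        """learn() equals scoring all clause subsets with the naive simulator."""
        rng = np.random.default_rng(500 + seed)
        pkn, hg, exps = random_learning_instance(rng)
        fam = learn(hg, exps)
        ref_clauses = [(c.target, list(c.literals)) for c in hg.clauses]
        ref_exps = [(e.clamped, e.observed) for e in exps]
        masks, ref_mse, ref_size = naive_learn(ref_clauses, ref_exps, list(pkn.nodes))
        assert fam.fitness == pytest.approx(ref_mse, abs=1e-9)
        assert fam.size == ref_size
        expected = {
            frozenset(hg.clauses[i] for i in range(len(hg.clauses)) if m >> i & 1)
            for m in masks
        }
        assert {n.clauses for n in fam.networks} == expected

    def test_estimator_wrapper_exposes_fitted_family(self):
        hg = toy_hypergraph()
        exps = [Experiment({"S": 1}, {"R": 1.0}), Experiment({"S": 0}, {"R": 0.0})]
        learner = BooleanFamilyLearner(hg).fit(exps)
        assert learner.mse_ == 0.0 and learner.size_ == 1
        assert learner.get_params()["fit_tolerance"] == 0.0


def random_learning_instance(rng: np.random.Generator, max_clauses: int = 12):
    """Random layered PKN plus random [0,1] observations on a few clampings."""
    while True:
        n_stim = int(rng.integers(1, 4))
        n_mid = int(rng.integers(0, 3))
        n_read = int(rng.integers(1, 3))
        stimuli = [f"S{i}" for i in range(n_stim)]
        mids = [f"M{i}" for i in range(n_mid)]
        reads = [f"R{i}" for i in range(n_read)]
        edges = []
        for i, m in enumerate(mids):
            pool = stimuli + mids[:i]
            for src in rng.choice(pool, size=min(len(pool), int(rng.integers(1, 3))), replace=False):
                edges.append(SignedEdge(str(src), m, int(rng.choice([1, -1]))))
        for r in reads:
            pool = stimuli + mids
            for src in rng.choice(pool, size=min(len(pool), int(rng.integers(1, 3))), replace=False):
                edges.append(SignedEdge(str(src), r, int(rng.choice([1, -1]))))
        used = {e.source for e in edges} | {e.target for e in edges}
        if not used.issuperset(reads):
            continue
        try:
            pkn = PKN(list(dict.fromkeys(edges)))
        except ValueError:
            continue
        hg = expand_hypergraph(pkn)
        if 1 <= len(hg.clauses) <= max_clauses and pkn.readouts:
            break
    inputs = sorted(set(pkn.stimuli) | set(pkn.inhibitors))
    n_exp = int(rng.integers(2, 9))
    exps = []
    for _ in range(n_exp):
        clamped = {v: int(rng.integers(2)) for v in inputs}
        observed = {r: float(np.round(rng.random(), 3)) for r in pkn.readouts}
        exps.append(Experiment(clamped, observed))
    return pkn, hg, exps


class TestBehaviors:
    def test_opposite_regulation_splits_groups(self):
        fam = BNFamily(
            [net(C("R", (("S", 1),))), net(C("R", (("S", -1),)))],
            0.0,
            1,
            nodes=("R", "S"),
            clamp_nodes=("S",),
            readouts=("R",),
        )
        assert classify_behaviors(fam) == [[0], [1]]

    def test_logically_equivalent_networks_share_a_group(self):
        """R <- A or (A and B) is the same input-output map as R <- A."""
        fam = BNFamily(
            [
                net(C("R", (("A", 1),)), C("R", (("A", 1), ("B", 1)))),
                net(C("R", (("A", 1),))),
            ],
            0.0,
            1,
            nodes=("A", "B", "R"),
            clamp_nodes=("A", "B"),
            readouts=("R",),
        )
        assert classify_behaviors(fam) == [[0, 1]]

    def test_groups_agree_with_exhaustive_prediction_comparison(self, tiny_bundle):
        hg = tiny_bundle.hypergraph
        rng = np.random.default_rng(0)
        # a family of random small networks over the synthetic PKN
        nets = []
        for _ in range(6):
            chosen = [c for c in hg.clauses if rng.random() < 0.3]
            nets.append(BooleanNetwork(frozenset(chosen)))
        inputs = sorted(set(tiny_bundle.pkn.stimuli) | set(tiny_bundle.pkn.inhibitors))
        fam = BNFamily(
            nets, 0.0, 0,
            nodes=tuple(tiny_bundle.pkn.nodes),
            clamp_nodes=tuple(inputs),
            readouts=tuple(tiny_bundle.pkn.readouts),
        )
        groups = classify_behaviors(fam)
        group_of = {i: g for g, members in enumerate(groups) for i in members}
        for pattern in itertools.product([0, 1], repeat=len(inputs)):
            clamped = dict(zip(inputs, pattern))
            preds = [
                tuple(
                    predict(n, clamped, fam.readouts, nodes=fam.nodes).items()
                )
                for n in nets
            ]
            for i, j in itertools.combinations(range(len(nets)), 2):
                if group_of[i] == group_of[j]:
                    assert preds[i] == preds[j]

    def test_too_many_inputs_is_an_error(self):
        fam = BNFamily([net(C("R", (("S", 1),)))], 0.0, 1, readouts=("R",))
        with pytest.raises(ValueError, match="clampings"):
            classify_behaviors(fam, input_nodes=[f"x{i}" for i in range(25)])


class TestFamilySummaries:
    def make_family(self):
        c1, c2, c3 = C("R", (("A", 1),)), C("R", (("B", 1),)), C("R", (("A", -1),))
        return BNFamily(
            [net(c1, c2), net(c1), net(c1, c3)], 0.1, 2, nodes=("A", "B", "R")
        )

    def test_clause_frequencies(self):
        fam = self.make_family()
        freqs = {str(f.clause): f.frequency for f in clause_frequencies(fam)}
        assert freqs["R <- A"] == 1.0
        assert freqs["R <- B"] == pytest.approx(1 / 3)
        assert all(0 < f.frequency <= 1 for f in clause_frequencies(fam))

    def test_union_contains_frequency_one_clauses(self):
        fam = self.make_family()
        union = union_network(fam)
        always = {f.clause for f in clause_frequencies(fam) if f.frequency == 1.0}
        assert always <= union.clauses
        assert len(union.clauses) == 3

    def test_singleton_family_union_is_itself(self):
        n = net(C("R", (("A", 1),)))
        fam = BNFamily([n], 0.0, 1)
        assert union_network(fam) == n

    def test_json_round_trip(self):
        fam = self.make_family()
        fam.clamp_nodes = ("A", "B")
        fam.readouts = ("R",)
        again = family_from_json_obj(family_to_json_obj(fam))
        assert [n.clauses for n in again.networks] == [n.clauses for n in fam.networks]
        assert (again.fitness, again.size) == (fam.fitness, fam.size)
        assert again.clamp_nodes == fam.clamp_nodes
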