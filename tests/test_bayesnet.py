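import itertools
import math

import numpy as np
import pandas as pd
import pytest

from nanohazard.bayesnet import (
    BayesNet,
    ConstraintSet,
    ZeroProbabilityEvidence,
    asina_constraints,
    evidence_probability,
    fit_cpts,
    learn_structure_exact,
    learn_structure_hillclimb,
    make_scorer,
    posterior,
    predict_class,
    sample,
    _encode,
)
from nanohazard.preprocessing import BinnedDataset


from _oracles import all_dags, joint_enumeration_posterior, random_bn, random_binned


class TestConstraints:
    def test_hazard_constraint_content(self):
        cons = asina_constraints()
        assert ("dose", "hazard") in cons.required_arcs
        assert ("assay", "hazard") in cons.required_arcs
        assert ("coating", "spherical_surface_area") in cons.required_arcs
        assert ("coating", "ag3d_at") in cons.required_arcs
        assert ("hydro_size_t24", "dose") in cons.forbidden_arcs
        assert ("pdi_t24", "pdi_t0") in cons.forbidden_arcs
        assert ("core_size", "coating") in cons.forbidden_arcs
        assert cons.roots == {"dose", "assay"}
        assert cons.sink == "hazard"
        assert not cons.arc_allowed("hazard", "dose")
        assert not cons.arc_allowed("dose", "core_size")
        assert cons.arc_allowed("hydro_size_t0", "hydro_size_t24")
        assert not cons.arc_allowed("hydro_size_t24", "hydro_size_t0")

    def test_required_and_forbidden_disjoint(self):
        with pytest.raises(ValueError):
            ConstraintSet(required_arcs={("a", "b")}, forbidden_arcs={("a", "b")})


class TestFitCpts:
    @staticmethod
    def _root_data(counts):
        vals = []
        for s, k in counts.items():
            vals += [s] * k
        frame = pd.DataFrame({"x": vals})
        return BinnedDataset(frame=frame, states={"x": sorted(counts)})

    def test_smoothed_root_counts(self):
        binned = self._root_data({"A": 3, "B": 1})
        struct = BayesNet(nodes=["x"], states={"x": ["A", "B"]}, parents={"x": ()})
        bn = fit_cpts(struct, binned, pseudocount=0.5)
        assert bn.cpts["x"][0].tolist() == pytest.approx([0.7, 0.3])

    def test_unobserved_configuration_uniform(self):
        frame = pd.DataFrame({"a": ["0", "0"], "b": ["1", "1"]})
        binned = BinnedDataset(frame=frame, states={"a": ["0", "1"], "b": ["0", "1"]})
        struct = BayesNet(
            nodes=["a", "b"], states=binned.states, parents={"a": (), "b": ("a",)}
        )
        bn = fit_cpts(struct, binned)
        # a = 1 never observed -> its row is the uniform smoothed row
        assert bn.cpts["b"][1].tolist() == pytest.approx([0.5, 0.5])

    def test_rows_sum_to_one(self, prepared_split):
        cons = asina_constraints()
        struct = learn_structure_hillclimb(
            prepared_split["binned_train"], constraints=cons, max_parents=3
        )
        bn = fit_cpts(struct, prepared_split["binned_train"])
        for v in bn.nodes:
            assert np.allclose(bn.cpts[v].sum(axis=1), 1.0, atol=1e-12)


class TestPosterior:
    def test_bayes_rule_by_hand(self):
        bn = BayesNet(
            nodes=["A", "B"],
            states={"A": ["0", "1"], "B": ["0", "1"]},
            parents={"A": (), "B": ("A",)},
            cpts={
                "A": np.array([[0.5, 0.5]]),
                "B": np.array([[0.9, 0.1], [0.1, 0.9]]),
            },
        )
        post = posterior(bn, {"B": "1"}, "A")
        assert post["1"] == pytest.approx(0.9)

    def test_no_evidence_gives_prior_marginal(self):
        bn = random_bn(4, seed=0)
        target = bn.nodes[-1]
        post = posterior(bn, {}, target)
        oracle = joint_enumeration_posterior(bn, {}, target)
        for s in bn.states[target]:
            assert post[s] == pytest.approx(oracle[s], abs=1e-10)

    def test_zero_probability_evidence_raises(self):
        bn = BayesNet(
            nodes=["A", "B"],
            states={"A": ["0", "1"], "B": ["0", "1"]},
            parents={"A": (), "B": ("A",)},
            cpts={
                "A": np.array([[1.0, 0.0]]),
                "B": np.array([[1.0, 0.0], [0.5, 0.5]]),
            },
        )
        with pytest.raises(ZeroProbabilityEvidence):
            posterior(bn, {"B": "1"}, "A")

    def test_elimination_order_invariance(self):
        bn = random_bn(6, seed=3)
        target = bn.nodes[0]
        ev = {bn.nodes[-1]: bn.states[bn.nodes[-1]][0]}
        hidden = [v for v in bn.nodes if v != target and v not in ev]
        a = posterior(bn, ev, target, order=hidden)
        b = posterior(bn, ev, target, order=hidden[::-1])
        for s in bn.states[target]:
            assert a[s] == pytest.approx(b[s], abs=1e-10)

    def test_joint_normalizes(self):
        bn = random_bn(5, seed=9)
        total = sum(
            math.prod(
                bn.cpts[v][bn.parent_config_index(v, dict(zip(bn.nodes, combo)))][
                    bn.states[v].index(dict(zip(bn.nodes, combo))[v])
                ]
                for v in bn.nodes
            )
            for combo in itertools.product(*(bn.states[v] for v in bn.nodes))
        )
        assert total == pytest.approx(1.0, abs=1e-10)


class TestPredictClass:
    @staticmethod
    def _outcome_net(probs):
        return BayesNet(
            nodes=["x", "hazard"],
            states={"x": ["0"], "hazard": ["very_toxic", "toxic", "safe"]},
            parents={"x": (), "hazard": ("x",)},
            cpts={"x": np.array([[1.0]]), "hazard": np.array([probs])},
        )

    def test_argmax(self):
        bn = self._outcome_net([0.2, 0.3, 0.5])
        assert predict_class(bn, {"x": "0"}) == "safe"

    def test_precautionary_tie_break(self):
        bn = self._outcome_net([0.1, 0.45, 0.45])
        assert predict_class(bn, {"x": "0"}) == "toxic"


class TestStructureLearning:
    def test_copy_pair_recovered_independent_ignored(self):
        rng = np.random.default_rng(0)
        x = rng.choice(["0", "1"], 500)
        frame = pd.DataFrame({"X": x, "Y": x.copy(), "Z": rng.choice(["0", "1"], 500)})
        binned = BinnedDataset(
            frame=frame, states={c: ["0", "1"] for c in frame.columns}
        )
        bn = learn_structure_exact(binned, max_parents=2)
        arcs = bn.arcs()
        assert ("X", "Y") in arcs or ("Y", "X") in arcs
        assert not any("Z" in arc for arc in arcs)
        hc = learn_structure_hillclimb(binned, max_parents=2)
        assert hc.score == pytest.approx(bn.score, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_543_dag_enumeration(self, seed):
        binned = random_binned(4, 200, seed=seed)
        data, nodes, card, _ = _encode(binned)
        local = make_scorer(data, card, score="bdeu", ess=1.0)
        dags = list(all_dags(4))
        assert len(dags) == 543
        best = max(sum(local(v, ps) for v, ps in enumerate(combo)) for combo in dags)
        bn = learn_structure_exact(binned, max_parents=3)
        assert bn.score == pytest.approx(best, abs=1e-9)

    def test_skeleton_recovery_from_known_dag(self):
        """Data sampled from a known 5-node network recovers its skeleton."""
        states = {v: ["0", "1"] for v in "ABCDE"}
        parents = {"A": (), "B": ("A",), "C": ("A",), "D": ("B", "C"), "E": ("D",)}
        cpts = {
            "A": np.array([[0.5, 0.5]]),
            "B": np.array([[0.9, 0.1], [0.1, 0.9]]),
            "C": np.array([[0.8, 0.2], [0.2, 0.8]]),
            # noisy XOR of (B, C): dependence on each parent survives
            # marginalization over the other
            "D": np.array([[0.9, 0.1], [0.1, 0.9], [0.1, 0.9], [0.9, 0.1]]),
            "E": np.array([[0.85, 0.15], [0.15, 0.85]]),
        }
        truth = BayesNet(nodes=list("ABCDE"), states=states, parents=parents, cpts=cpts)
        data = sample(truth, 5000, seed=1)
        learned = learn_structure_exact(data, max_parents=3)
        skel = {frozenset(a) for a in learned.arcs()}
        true_skel = {frozenset((p, v)) for v, ps in parents.items() for p in ps}
        assert skel == true_skel

    def test_constrained_score_not_above_unconstrained(self, prepared_split):
        binned = prepared_split["binned_train"]
        cons = asina_constraints()
        hc_con = learn_structure_hillclimb(binned, constraints=cons, max_parents=6)
        hc_unc = learn_structure_hillclimb(binned, constraints=None, max_parents=6)
        assert hc_con.score <= hc_unc.score + 1e-9

    def test_parent_limit_respected(self, prepared_split):
        bn = learn_structure_hillclimb(
            prepared_split["binned_train"], constraints=asina_constraints(), max_parents=6
        )
        assert max(len(ps) for ps in bn.parents.values()) <= 6

    def test_too_many_nodes_directs_to_hillclimb(self):
        binned = random_binned(13, 20, seed=0)
        with pytest.raises(ValueError, match="hillclimb"):
            learn_structure_exact(binned)

    def test_sample_deterministic(self):
        bn = random_bn(4, seed=2)
        a = sample(bn, 100, seed=5).frame
        b = sample(bn, 100, seed=5).frame
        pd.testing.assert_frame_equal(a, b)


class TestEvidenceProbability:
    def test_matches_enumeration(self):
        bn = random_bn(5, seed=11)
        v = bn.nodes[2]
        ev = {v: bn.states[v][0]}
        total = 0.0
        for combo in itertools.product(*(bn.states[n] for n in bn.nodes)):
            assign = dict(zip(bn.nodes, combo))
            if assign[v] != ev[v]:
                continue
            p = 1.0
            for n in bn.nodes:
                row = bn.cpts[n][bn.parent_config_index(n, assign)]
                p *= row[bn.states[n].index(assign[n])]
            total += p
        assert evidence_probability(bn, ev) == pytest.approx(total, abs=1e-12)
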