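"""Discrete Bayesian-network machinery: expert-constrained structure
learning (exact dynamic programming and greedy hill climbing), CPT
estimation with pseudocounts, and exact posterior inference by
variable elimination.

The expert constraint set encodes the causal reasoning of the hazard
model: exposure dose and assay are independent global parameters
feeding only the viability outcome, the coating determines surface
area and surface silver, t0 dispersion states precede t24 states, and
viability is the unique terminal node.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .preprocessing import BinnedDataset
from .schema import HAZARD_LABELS

__all__ = [
    "ConstraintSet",
    "BayesNet",
    "ZeroProbabilityEvidence",
    "asina_constraints",
    "learn_structure_exact",
    "learn_structure_hillclimb",
    "fit_cpts",
    "posterior",
    "predict_class",
    "sample",
]

#: Practical node-count limit of the exact subset dynamic program.
EXACT_NODE_LIMIT = 12


class ZeroProbabilityEvidence(ValueError):
    """The supplied evidence has zero joint probability under the model."""


# ---------------------------------------------------------------------------
# constraints


@dataclass
class ConstraintSet:
    """Expert constraints on the DAG.

    ``tiers`` is a partial order: an arc u -> v is forbidden when
    tier(u) > tier(v).  ``roots`` have no parents; the ``sink`` has no
    children and, when set, the learners guarantee it is the *unique*
    childless node (every other node is given at least one outgoing
    arc).
    """

    required_arcs: set[tuple[str, str]] = field(default_factory=set)
    forbidden_arcs: set[tuple[str, str]] = field(default_factory=set)
    roots: set[str] = field(default_factory=set)
    sink: str | None = None
    tiers: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.required_arcs = set(map(tuple, self.required_arcs))
        self.forbidden_arcs = set(map(tuple, self.forbidden_arcs))
        clash = self.required_arcs & self.forbidden_arcs
        if clash:
            raise ValueError(f"arcs both required and forbidden: {sorted(clash)}")
        for p, c in self.required_arcs:
            if not self._tier_ok(p, c):
                raise ValueError(f"required arc {p}->{c} violates tiers")
            if c in self.roots:
                raise ValueError(f"required arc into root node {c}")
            if p == self.sink:
                raise ValueError(f"required arc out of sink node {p}")

    def _tier_ok(self, parent: str, child: str) -> bool:
        tp, tc = self.tiers.get(parent), self.tiers.get(child)
        return tp is None or tc is None or tp <= tc

    def arc_allowed(self, parent: str, child: str) -> bool:
        if parent == child:
            return False
        if (parent, child) in self.required_arcs:
            return True
        if (parent, child) in self.forbidden_arcs:
            return False
        if child in self.roots:
            return False
        if parent == self.sink:
            return False
        return self._tier_ok(parent, child)

    def required_parents(self, child: str) -> set[str]:
        return {p for p, c in self.required_arcs if c == child}

    def check_dag(self, parents: Mapping[str, Sequence[str]]) -> None:
        for p, c in self.required_arcs:
            if p not in parents.get(c, ()):
                raise ValueError(f"required arc {p}->{c} absent")
        for c, ps in parents.items():
            for p in ps:
                if not self.arc_allowed(p, c):
                    raise ValueError(f"forbidden arc {p}->{c} present")


def asina_constraints(
    nodes: Sequence[str] | None = None, outcome: str = "hazard"
) -> ConstraintSet:
    """The hazard model's expert constraint set.

    Exposure dose and assay are roots whose only outgoing arc feeds
    the outcome; no dispersion state may determine the dose; the
    coating determines the spherical surface area and the Ag 3d
    surface concentration while the core size may not determine the
    coating; t24 dispersion states never precede t0 states; the
    outcome is the unique sink.
    """
    if nodes is None:
        from .preprocessing import FINAL_CATEGORICAL, FINAL_NUMERIC

        nodes = FINAL_NUMERIC + FINAL_CATEGORICAL + [outcome]
    nodes = list(nodes)
    required = {
        ("dose", outcome),
        ("assay", outcome),
        ("coating", "spherical_surface_area"),
        ("coating", "ag3d_at"),
    }
    forbidden: set[tuple[str, str]] = set()
    for n in nodes:
        # dose and assay feed only the outcome
        if n != outcome:
            forbidden.add(("dose", n))
            forbidden.add(("assay", n))
        # nothing determines the externally set dose or assay
        if n != "dose":
            forbidden.add((n, "dose"))
        if n != "assay":
            forbidden.add((n, "assay"))
        # the outcome is terminal
        if n != outcome:
            forbidden.add((outcome, n))
    forbidden.add(("core_size", "coating"))
    # t24 dispersion states may not determine t0 states
    tiers = {"hydro_size_t0": 0, "pdi_t0": 0, "hydro_size_t24": 1, "pdi_t24": 1}
    for late in ("hydro_size_t24", "pdi_t24"):
        for early in ("hydro_size_t0", "pdi_t0"):
            forbidden.add((late, early))
    forbidden -= required
    return ConstraintSet(
        required_arcs=required,
        forbidden_arcs={(p, c) for p, c in forbidden if p in nodes and c in nodes},
        roots={"dose", "assay"},
        sink=outcome,
        tiers=tiers,
    )


# ---------------------------------------------------------------------------
# data encoding and scoring


def _encode(binned: BinnedDataset) -> tuple[np.ndarray, list[str], np.ndarray, dict]:
    nodes = list(binned.frame.columns)
    states = {n: list(binned.states[n]) for n in nodes}
    card = np.array([len(states[n]) for n in nodes])
    data = np.empty((len(binned.frame), len(nodes)), dtype=np.int64)
    for j, n in enumerate(nodes):
        lut = {s: i for i, s in enumerate(states[n])}
        try:
            data[:, j] = [lut[v] for v in binned.frame[n]]
        except KeyError as e:
            raise ValueError(f"state {e} of node {n!r} missing from state set") from None
    return data, nodes, card, states


def _family_counts(data: np.ndarray, card: np.ndarray, child: int,
                   parents: tuple[int, ...]) -> np.ndarray:
    r = int(card[child])
    if not parents:
        return np.bincount(data[:, child], minlength=r)[None, :]
    q = int(np.prod(card[list(parents)]))
    code = np.zeros(len(data), dtype=np.int64)
    for p in parents:
        code = code * card[p] + data[:, p]
    idx = code * r + data[:, child]
    return np.bincount(idx, minlength=q * r).reshape(q, r)


def make_scorer(data: np.ndarray, card: np.ndarray, score: str = "bdeu",
                ess: float = 1.0):
    """Decomposable local-score function ``f(child, parents) -> float``.

    'bdeu' is the Bayesian Dirichlet equivalent uniform score with
    equivalent sample size ``ess``; 'bic' the penalized log-likelihood.
    """
    n = len(data)

    @lru_cache(maxsize=None)
    def local(child: int, parents: tuple[int, ...]) -> float:
        counts = _family_counts(data, card, child, parents)
        q, r = counts.shape
        if score == "bdeu":
            a_jk = ess / (q * r)
            a_j = ess / q
            nj = counts.sum(axis=1)
            val = float(
                np.sum(gammaln(a_j) - gammaln(a_j + nj))
                + np.sum(gammaln(a_jk + counts) - gammaln(a_jk))
            )
            return val
        if score == "bic":
            nj = counts.sum(axis=1, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = np.where(counts > 0, counts * np.log(counts / nj), 0.0)
            return float(ll.sum() - 0.5 * math.log(max(n, 1)) * q * (r - 1))
        raise ValueError(f"unknown score {score!r}")

    return local


# ---------------------------------------------------------------------------
# the network


@dataclass
class BayesNet:
    """DAG over discrete nodes with smoothed CPTs.

    ``cpts[v]`` has shape (q, r): one row per parent configuration
    (row-major over ``parents[v]`` in order), one column per state of
    v; every row sums to 1.
    """

    nodes: list[str]
    states: dict[str, list[str]]
    parents: dict[str, tuple[str, ...]]
    cpts: dict[str, np.ndarray] = field(default_factory=dict)
    pseudocount: float = 0.5
    score: float = float("nan")

    def __post_init__(self):
        g = self.digraph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("parent sets define a cyclic graph")
        for v, table in self.cpts.items():
            if not np.allclose(table.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError(f"CPT rows of {v!r} do not sum to 1")

    def digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for v, ps in self.parents.items():
            g.add_edges_from((p, v) for p in ps)
        return g

    def arcs(self) -> set[tuple[str, str]]:
        return {(p, v) for v, ps in self.parents.items() for p in ps}

    def topological_order(self) -> list[str]:
        return list(nx.topological_sort(self.digraph()))

    def markov_blanket(self, node: str) -> list[str]:
        g = self.digraph()
        mb = set(g.predecessors(node)) | set(g.successors(node))
        for ch in g.successors(node):
            mb |= set(g.predecessors(ch))
        mb.discard(node)
        return [n for n in self.nodes if n in mb]

    def parent_config_index(self, node: str, assignment: Mapping[str, str]) -> int:
        idx = 0
        for p in self.parents[node]:
            idx = idx * len(self.states[p]) + self.states[p].index(assignment[p])
        return idx

    def to_dot(self) -> str:
        lines = ["digraph bn {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for p, c in sorted(self.arcs()):
            lines.append(f'  "{p}" -> "{c}";')
        lines.append("}")
        return "\n".join(lines)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.digraph(), path)

    def cpts_json(self) -> str:
        return json.dumps(
            {
                v: {
                    "parents": list(self.parents[v]),
                    "states": self.states[v],
                    "table": self.cpts[v].tolist(),
                }
                for v in self.nodes
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# structure learning


def _candidate_sets(cand: list[int], required: set[int], cap: int):
    opt = [c for c in cand if c not in required]
    base = tuple(sorted(required))
    if len(base) > cap:
        return
    for k in range(0, cap - len(base) + 1):
        for extra in itertools.combinations(opt, k):
            yield tuple(sorted(base + extra))


def learn_structure_exact(
    binned: BinnedDataset,
    score: str = "bdeu",
    constraints: ConstraintSet | None = None,
    max_parents: int = 4,
    ess: float = 1.0,
    exempt: Sequence[str] = (),
) -> BayesNet:
    """Globally score-optimal DAG by dynamic programming over variable
    subsets, restricted to constraint-permitted parent sets.

    Nodes listed in ``exempt`` are free of the parent-set cap.  With
    an empty constraint set this is the unconstrained optimum.
    Feasible up to about a dozen nodes; use the hill climber beyond.
    """
    data, nodes, card, states = _encode(binned)
    d = len(nodes)
    if d > EXACT_NODE_LIMIT:
        raise ValueError(
            f"{d} nodes exceed the exact-search limit ({EXACT_NODE_LIMIT}); "
            "use learn_structure_hillclimb"
        )
    cons = constraints or ConstraintSet()
    local = make_scorer(data, card, score=score, ess=ess)
    name2idx = {n: i for i, n in enumerate(nodes)}

    full = (1 << d) - 1
    # best parent set of v among subsets of each candidate mask
    best_ps: list[dict[int, tuple[float, tuple[int, ...]]]] = []
    for v in range(d):
        cand = [u for u in range(d) if cons.arc_allowed(nodes[u], nodes[v])]
        req = {name2idx[p] for p in cons.required_parents(nodes[v]) if p in name2idx}
        cap = d - 1 if nodes[v] in exempt else max_parents
        scored: dict[int, tuple[float, tuple[int, ...]]] = {}
        for ps in _candidate_sets(cand, req, cap):
            mask = 0
            for p in ps:
                mask |= 1 << p
            scored[mask] = (local(v, ps), ps)
        if not scored:
            raise ValueError(
                f"unsatisfiable constraints: no permitted parent set for {nodes[v]!r}"
            )
        # propagate best over all submasks
        table: dict[int, tuple[float, tuple[int, ...]]] = {}

        def best_for(mask: int) -> tuple[float, tuple[int, ...]]:
            hit = table.get(mask)
            if hit is not None:
                return hit
            best = scored.get(mask, (-math.inf, ()))
            m = mask
            while m:
                bit = m & -m
                sub = best_for(mask & ~bit)
                if sub[0] > best[0]:
                    best = sub
                m &= m - 1
            table[mask] = best
            return best

        for mask in range(full + 1):
            if mask & (1 << v):
                continue
            best_for(mask)
        best_ps.append(table)

    # order DP: best score of a DAG over subset W
    best_sub = np.full(full + 1, -math.inf)
    best_sub[0] = 0.0
    choice: dict[int, tuple[int, tuple[int, ...]]] = {}
    for mask in range(1, full + 1):
        m = mask
        while m:
            bit = m & -m
            v = bit.bit_length() - 1
            rest = mask & ~bit
            if best_sub[rest] > -math.inf:
                sc, ps = best_ps[v].get(rest, (-math.inf, ()))
                total = best_sub[rest] + sc
                if total > best_sub[mask]:
                    best_sub[mask] = total
                    choice[mask] = (v, ps)
            m &= m - 1
    if best_sub[full] == -math.inf:
        raise ValueError("unsatisfiable constraints: no DAG admits all requirements")

    parents: dict[str, tuple[str, ...]] = {}
    mask = full
    while mask:
        v, ps = choice[mask]
        parents[nodes[v]] = tuple(nodes[p] for p in ps)
        mask &= ~(1 << v)

    bn = BayesNet(nodes=nodes, states=states, parents=parents, score=float(best_sub[full]))
    bn = _enforce_unique_sink(bn, cons, local, name2idx, max_parents, exempt)
    if constraints is not None:
        constraints.check_dag(bn.parents)
    return bn


def learn_structure_hillclimb(
    binned: BinnedDataset,
    score: str = "bdeu",
    constraints: ConstraintSet | None = None,
    max_parents: int = 6,
    ess: float = 1.0,
    seed: int = 0,
    max_moves: int = 10_000,
) -> BayesNet:
    """Greedy hill climbing with add/delete/reverse moves from the
    constraint-seeded graph; every accepted move strictly improves the
    decomposable score.  Deterministic: moves are enumerated in
    lexicographic (parent, child) order and the best-improving move is
    taken, first-found on ties.
    """
    del seed  # the search is deterministic; accepted for API symmetry
    data, nodes, card, states = _encode(binned)
    d = len(nodes)
    cons = constraints or ConstraintSet()
    local = make_scorer(data, card, score=score, ess=ess)
    name2idx = {n: i for i, n in enumerate(nodes)}

    parents: dict[str, set[str]] = {n: set(cons.required_parents(n)) for n in nodes}
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for c, ps in parents.items():
        g.add_edges_from((p, c) for p in ps)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("unsatisfiable constraints: required arcs are cyclic")

    def node_score(v: str, ps: Iterable[str]) -> float:
        return local(name2idx[v], tuple(sorted(name2idx[p] for p in ps)))

    current = {v: node_score(v, parents[v]) for v in nodes}

    def creates_cycle(p: str, c: str) -> bool:
        return p == c or nx.has_path(g, c, p)

    for _ in range(max_moves):
        best_delta, best_move = 1e-9, None
        for p in nodes:
            for c in nodes:
                if p == c:
                    continue
                if c in parents and p in parents[c]:
                    # delete p -> c
                    if (p, c) not in cons.required_arcs:
                        delta = node_score(c, parents[c] - {p}) - current[c]
                        if delta > best_delta:
                            best_delta, best_move = delta, ("del", p, c)
                    # reverse p -> c
                    if (
                        (p, c) not in cons.required_arcs
                        and cons.arc_allowed(c, p)
                        and len(parents[p]) < max_parents
                    ):
                        g.remove_edge(p, c)
                        cyc = creates_cycle(c, p)
                        g.add_edge(p, c)
                        if not cyc:
                            delta = (
                                node_score(c, parents[c] - {p})
                                - current[c]
                                + node_score(p, parents[p] | {c})
                                - current[p]
                            )
                            if delta > best_delta:
                                best_delta, best_move = delta, ("rev", p, c)
                elif (
                    cons.arc_allowed(p, c)
                    and len(parents[c]) < max_parents
                    and not creates_cycle(p, c)
                ):
                    delta = node_score(c, parents[c] | {p}) - current[c]
                    if delta > best_delta:
                        best_delta, best_move = delta, ("add", p, c)
        if best_move is None:
            break
        kind, p, c = best_move
        if kind == "add":
            parents[c].add(p)
            g.add_edge(p, c)
        elif kind == "del":
            parents[c].discard(p)
            g.remove_edge(p, c)
        else:
            parents[c].discard(p)
            g.remove_edge(p, c)
            parents[p].add(c)
            g.add_edge(c, p)
            current[p] = node_score(p, parents[p])
        current[c] = node_score(c, parents[c])

    bn = BayesNet(
        nodes=nodes,
        states=states,
        parents={v: tuple(sorted(parents[v])) for v in nodes},
        score=float(sum(current.values())),
    )
    bn = _enforce_unique_sink(bn, cons, local, name2idx, max_parents, ())
    if constraints is not None:
        constraints.check_dag(bn.parents)
    return bn


def _enforce_unique_sink(
    bn: BayesNet,
    cons: ConstraintSet,
    local,
    name2idx: Mapping[str, int],
    max_parents: int,
    exempt: Sequence[str],
) -> BayesNet:
    """Make the declared sink the unique childless node.

    Any other childless node receives its best-scoring permitted
    outgoing arc (respecting acyclicity and the child's parent cap).
    """
    if cons.sink is None:
        return bn
    parents = {v: set(ps) for v, ps in bn.parents.items()}
    g = bn.digraph()
    total = bn.score
    for u in bn.nodes:
        if u == cons.sink or g.out_degree(u) > 0:
            continue
        best = None
        for c in bn.nodes:
            cap = len(bn.nodes) - 1 if c in exempt else max_parents
            if (
                c == u
                or not cons.arc_allowed(u, c)
                or len(parents[c]) >= cap
                or nx.has_path(g, c, u)
            ):
                continue
            old = local(name2idx[c], tuple(sorted(name2idx[p] for p in parents[c])))
            new = local(
                name2idx[c], tuple(sorted(name2idx[p] for p in parents[c] | {u}))
            )
            delta = new - old
            if best is None or delta > best[0]:
                best = (delta, c)
        if best is None:
            raise ValueError(
                f"cannot enforce unique sink: no permitted outgoing arc for {u!r}"
            )
        _, c = best
        parents[c].add(u)
        g.add_edge(u, c)
        total += best[0]
    return BayesNet(
        nodes=bn.nodes,
        states=bn.states,
        parents={v: tuple(sorted(parents[v])) for v in bn.nodes},
        score=float(total),
    )


# ---------------------------------------------------------------------------
# parameters and inference


def fit_cpts(
    structure: BayesNet, binned: BinnedDataset, pseudocount: float = 0.5
) -> BayesNet:
    """Estimate every CPT as (count + a) / (sum + a*|states|) per
    parent configuration; unobserved configurations get the uniform
    smoothed row."""
    data, nodes, card, states = _encode(binned)
    if nodes != structure.nodes:
        order = [nodes.index(n) for n in structure.nodes]
        data = data[:, order]
        card = card[order]
        nodes = list(structure.nodes)
    name2idx = {n: i for i, n in enumerate(nodes)}
    cpts = {}
    for v in structure.nodes:
        pidx = tuple(name2idx[p] for p in structure.parents[v])
        counts = _family_counts(data, card, name2idx[v], pidx).astype(float)
        counts += pseudocount
        cpts[v] = counts / counts.sum(axis=1, keepdims=True)
    return BayesNet(
        nodes=structure.nodes,
        states=structure.states,
        parents=structure.parents,
        cpts=cpts,
        pseudocount=pseudocount,
        score=structure.score,
    )


@dataclass
class _Factor:
    vars: tuple[str, ...]
    table: np.ndarray  # one axis per var, in order


def _cpt_factor(bn: BayesNet, v: str) -> _Factor:
    ps = bn.parents[v]
    shape = [len(bn.states[p]) for p in ps] + [len(bn.states[v])]
    return _Factor(tuple(ps) + (v,), bn.cpts[v].reshape(shape))


def _reduce(f: _Factor, evidence: Mapping[str, int]) -> _Factor:
    idx = tuple(evidence.get(v, slice(None)) for v in f.vars)
    keep = tuple(v for v in f.vars if v not in evidence)
    return _Factor(keep, f.table[idx])


def _multiply(a: _Factor, b: _Factor) -> _Factor:
    vars_out = list(a.vars) + [v for v in b.vars if v not in a.vars]

    def expand(f: _Factor) -> np.ndarray:
        present = [v for v in vars_out if v in f.vars]
        t = np.transpose(f.table, [f.vars.index(v) for v in present])
        shape = [t.shape[present.index(v)] if v in f.vars else 1 for v in vars_out]
        return t.reshape(shape)

    return _Factor(tuple(vars_out), expand(a) * expand(b))


def _marginalize(f: _Factor, v: str) -> _Factor:
    ax = f.vars.index(v)
    return _Factor(tuple(x for x in f.vars if x != v), f.table.sum(axis=ax))


def posterior(
    bn: BayesNet,
    evidence: Mapping[str, str] | None = None,
    target: str = "hazard",
    order: Sequence[str] | None = None,
) -> dict[str, float]:
    """Exact P(target | evidence) by variable elimination.

    Hidden variables are eliminated in min-degree order unless an
    explicit ``order`` is given.  Evidence with zero joint probability
    raises :class:`ZeroProbabilityEvidence`.
    """
    evidence = dict(evidence or {})
    if target in evidence:
        raise ValueError("target must not be part of the evidence")
    ev_idx = {}
    for v, s in evidence.items():
        if v not in bn.states:
            raise ValueError(f"unknown evidence node {v!r}")
        if s not in bn.states[v]:
            raise ValueError(f"unknown state {s!r} of node {v!r}")
        ev_idx[v] = bn.states[v].index(s)

    factors = [_reduce(_cpt_factor(bn, v), ev_idx) for v in bn.nodes]
    hidden = [v for v in bn.nodes if v != target and v not in evidence]

    if order is not None:
        elim = [v for v in order if v in hidden]
        if set(elim) != set(hidden):
            raise ValueError("order must cover exactly the hidden variables")
    else:
        # min-degree heuristic on the interaction graph
        elim = []
        inter = {v: set() for v in hidden}
        for f in factors:
            hv = [v for v in f.vars if v in inter]
            for a in hv:
                inter[a].update(x for x in hv if x != a)
        remaining = set(hidden)
        while remaining:
            v = min(remaining, key=lambda x: (len(inter[x] & remaining), x))
            elim.append(v)
            nbrs = inter[v] & remaining
            for a in nbrs:
                inter[a].update(x for x in nbrs if x != a)
            remaining.discard(v)

    for v in elim:
        touching = [f for f in factors if v in f.vars]
        if not touching:
            continue
        factors = [f for f in factors if v not in f.vars]
        prod = touching[0]
        for f in touching[1:]:
            prod = _multiply(prod, f)
        factors.append(_marginalize(prod, v))

    result = _Factor((), np.array(1.0))
    for f in factors:
        result = _multiply(result, f)
    table = result.table
    if result.vars != (target,):
        ax = result.vars.index(target)
        table = np.moveaxis(table, ax, -1).reshape(-1, table.shape[ax]).sum(axis=0)
    z = table.sum()
    if z <= 0.0:
        raise ZeroProbabilityEvidence(f"evidence {evidence} has zero probability")
    probs = table / z
    return {s: float(p) for s, p in zip(bn.states[target], probs)}


def evidence_probability(bn: BayesNet, evidence: Mapping[str, str]) -> float:
    """Marginal probability P(evidence) by variable elimination."""
    ev_idx = {v: bn.states[v].index(s) for v, s in evidence.items()}
    factors = [_reduce(_cpt_factor(bn, v), ev_idx) for v in bn.nodes]
    hidden = [v for v in bn.nodes if v not in evidence]
    for v in hidden:
        touching = [f for f in factors if v in f.vars]
        if not touching:
            continue
        factors = [f for f in factors if v not in f.vars]
        prod = touching[0]
        for f in touching[1:]:
            prod = _multiply(prod, f)
        factors.append(_marginalize(prod, v))
    result = _Factor((), np.array(1.0))
    for f in factors:
        result = _multiply(result, f)
    return float(result.table.sum())


HAZARD_RANK = {label: i for i, label in enumerate(HAZARD_LABELS)}


def predict_class(
    bn: BayesNet,
    record: Mapping[str, str],
    target: str = "hazard",
    tol: float = 1e-12,
) -> str:
    """Argmax of the posterior over the outcome node; exact ties break
    toward the more hazardous class (precautionary)."""
    post = posterior(bn, {k: v for k, v in record.items() if k != target}, target)
    best = max(post.values())
    tied = [s for s, p in post.items() if best - p <= tol]
    return min(tied, key=lambda s: HAZARD_RANK.get(s, len(HAZARD_RANK)))


def sample(bn: BayesNet, n: int, seed: int = 0) -> BinnedDataset:
    """Forward (ancestral) sampling of n records from the network."""
    rng = np.random.default_rng(seed)
    order = bn.topological_order()
    cols: dict[str, np.ndarray] = {}
    for v in order:
        ps = bn.parents[v]
        r = len(bn.states[v])
        if not ps:
            probs = bn.cpts[v][0]
            draws = rng.choice(r, size=n, p=probs)
        else:
            idx = np.zeros(n, dtype=np.int64)
            for p in ps:
                idx = idx * len(bn.states[p]) + cols[p]
            draws = np.empty(n, dtype=np.int64)
            for cfg in np.unique(idx):
                m = idx == cfg
                draws[m] = rng.choice(r, size=m.sum(), p=bn.cpts[v][cfg])
        cols[v] = draws
    frame = pd.DataFrame(
        {v: [bn.states[v][i] for i in cols[v]] for v in bn.nodes}
    )
    return BinnedDataset(frame=frame, states={v: list(bn.states[v]) for v in bn.nodes})
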