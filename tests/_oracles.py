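"""Independent brute-force oracles used by the network tests:
joint-enumeration inference, exhaustive DAG enumeration, and random
network/dataset generators."""

import itertools

import numpy as np
import pandas as pd

from nanohazard.bayesnet import BayesNet
from nanohazard.preprocessing import BinnedDataset


def joint_enumeration_posterior(bn, evidence, target):
    """P(target | evidence) by summing the fully enumerated joint."""
    probs = {s: 0.0 for s in bn.states[target]}
    names = bn.nodes
    for combo in itertools.product(*(bn.states[v] for v in names)):
        assign = dict(zip(names, combo))
        if any(assign[k] != v for k, v in evidence.items()):
            continue
        p = 1.0
        for v in names:
            row = bn.cpts[v][bn.parent_config_index(v, assign)]
            p *= row[bn.states[v].index(assign[v])]
        probs[assign[target]] += p
    z = sum(probs.values())
    return {s: p / z for s, p in probs.items()}


def all_dags(n):
    """Every DAG over n labeled nodes as a tuple of parent sets."""
    nodes = list(range(n))
    options = []
    for v in nodes:
        others = [u for u in nodes if u != v]
        subsets = []
        for k in range(n):
            subsets += list(itertools.combinations(others, k))
        options.append(subsets)
    for combo in itertools.product(*options):
        indeg = {v: len(combo[v]) for v in nodes}
        children = {v: [] for v in nodes}
        for v in nodes:
            for p in combo[v]:
                children[p].append(v)
        queue = [v for v in nodes if indeg[v] == 0]
        seen = 0
        while queue:
            u = queue.pop()
            seen += 1
            for c in children[u]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if seen == n:
            yield combo


def random_bn(n_nodes, seed):
    """Random DAG with random 2-3-state nodes and Dirichlet CPT rows."""
    rng = np.random.default_rng(seed)
    names = [f"n{i}" for i in range(n_nodes)]
    states = {v: [f"s{k}" for k in range(rng.integers(2, 4))] for v in names}
    parents = {}
    for i, v in enumerate(names):
        pool = names[:i]
        parents[v] = tuple(p for p in pool if rng.random() < 0.4)
    cpts = {}
    for v in names:
        q = int(np.prod([len(states[p]) for p in parents[v]])) if parents[v] else 1
        cpts[v] = rng.dirichlet(np.ones(len(states[v])), size=q)
    return BayesNet(nodes=names, states=states, parents=parents, cpts=cpts)


def random_binned(n_nodes, n_rows, seed, n_states=2):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {f"n{i}": rng.choice([f"s{k}" for k in range(n_states)], n_rows)
         for i in range(n_nodes)}
    )
    states = {c: [f"s{k}" for k in range(n_states)] for c in frame.columns}
    return BinnedDataset(frame=frame, states=states)
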