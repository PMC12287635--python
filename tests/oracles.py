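"""Independent brute-force oracles for the causal-graph operations.

These deliberately avoid the implementation's reachability machinery: they
enumerate every undirected simple path and apply the textbook per-path
blocking rules (chain/fork blocked iff the middle node is conditioned;
collider blocked iff neither it nor any of its descendants is conditioned).
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from caniact.dag import CausalDag


def _descendants(edges: set[tuple[str, str]], node: str) -> set[str]:
    out, stack = set(), [node]
    children = {}
    for a, b in edges:
        children.setdefault(a, []).append(b)
    while stack:
        for ch in children.get(stack.pop(), []):
            if ch not in out:
                out.add(ch)
                stack.append(ch)
    return out


def path_blocked(
    path: list[str], edges: set[tuple[str, str]], given: set[str]
) -> bool:
    """Standard blocking rules applied triple by triple along one path."""
    for a, b, c in zip(path, path[1:], path[2:]):
        into_b_left = (a, b) in edges
        into_b_right = (c, b) in edges
        if into_b_left and into_b_right:  # collider
            if b not in given and not (_descendants(edges, b) & given):
                return True
        else:  # chain or fork
            if b in given:
                return True
    return False


def brute_force_d_separated(
    dag: CausalDag, x: str, y: str, given: set[str]
) -> bool:
    edges = set(dag.edges)
    ug = nx.Graph()
    ug.add_nodes_from(dag.nodes)
    ug.add_edges_from(edges)
    for path in nx.all_simple_paths(ug, x, y):
        if len(path) == 2:
            return False  # adjacent: the direct edge is never blocked
        if not path_blocked(path, edges, given):
            return False
    return True


def brute_force_backdoor_valid(
    dag: CausalDag, exposure: str, outcome: str, zs: set[str]
) -> bool:
    """Backdoor criterion by per-path enumeration: no member is a descendant
    of the exposure, and every path whose first edge points into the
    exposure is blocked."""
    edges = set(dag.edges)
    if zs & (_descendants(edges, exposure) | {exposure, outcome}):
        return False
    ug = nx.Graph()
    ug.add_nodes_from(dag.nodes)
    ug.add_edges_from(edges)
    for path in nx.all_simple_paths(ug, exposure, outcome):
        if (path[1], path[0]) not in edges:
            continue  # not a backdoor path
        if len(path) == 2:
            return False
        if not path_blocked(path, edges, zs):
            return False
    return True


def brute_force_minimal_backdoor_sets(
    dag: CausalDag, exposure: str, outcome: str
) -> list[frozenset[str]]:
    """Exhaustive search over ALL subsets of observed eligible nodes."""
    cands = sorted(
        dag.observed
        - {exposure, outcome}
        - _descendants(set(dag.edges), exposure)
    )
    valid: list[frozenset[str]] = []
    for size in range(len(cands) + 1):
        for combo in itertools.combinations(cands, size):
            zs = frozenset(combo)
            if any(v <= zs for v in valid):
                continue
            if brute_force_backdoor_valid(dag, exposure, outcome, set(zs)):
                valid.append(zs)
    return sorted(valid, key=lambda s: (len(s), tuple(sorted(s))))


def random_dag(
    rng: np.random.Generator,
    n_nodes: int = 6,
    edge_prob: float = 0.35,
    latent_prob: float = 0.25,
) -> CausalDag:
    names = [f"n{i}" for i in range(n_nodes)]
    order = rng.permutation(n_nodes)
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                edges.append((names[order[i]], names[order[j]]))
    observed = {nm: bool(rng.random() > latent_prob) for nm in names}
    return CausalDag(nodes=observed, edges=tuple(edges))
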