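"""Causal DAG representation, d-separation, backdoor adjustment sets and
data-consistency tests.

The analysis pipeline uses a directed acyclic graph to encode hypothesised
causal relations among dog, owner and environmental attributes and the daily
active-minutes outcome.  The graph drives two things: selection of minimal
backdoor adjustment sets for each exposure of interest, and a battery of
implied conditional-independence claims that can be tested against data as a
model-consistency check.

Nodes are either *observed* (available in the linked dataset) or *latent*
(hypothesised but unmeasured, e.g. daily weather).  Latent nodes participate
in path blocking but are never eligible for adjustment or conditioning.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CausalDag",
    "IndependenceClaim",
    "AdjustmentSet",
    "parse_dag",
    "load_dag",
    "d_separated",
    "minimal_adjustment_sets",
    "implied_independences",
    "test_independences",
    "simulate_linear_gaussian",
]

#: Enumeration refuses above this many observed nodes (subset search blows up).
MAX_ENUMERATION_NODES = 25


class DagParseError(ValueError):
    """Raised when DAG text cannot be parsed into a valid acyclic graph."""


@dataclass(frozen=True)
class CausalDag:
    """A directed acyclic graph with observed/latent node flags.

    Parameters
    ----------
    nodes
        Mapping node name -> observed flag (``True`` = observed).
    edges
        Iterable of ``(parent, child)`` pairs; endpoints must be declared
        nodes and the graph must be acyclic.
    """

    nodes: Mapping[str, bool]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.nodes:
            raise DagParseError("DAG must have at least one node")
        object.__setattr__(self, "nodes", dict(self.nodes))
        object.__setattr__(self, "edges", tuple(tuple(e) for e in self.edges))
        for a, b in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise DagParseError(f"edge {a} -> {b} references undeclared node")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = " -> ".join(u for u, _ in nx.find_cycle(g)) or "?"
            raise DagParseError(f"graph contains a cycle: {cycle}")

    def __eq__(self, other) -> bool:
        # structural equality: edge order is not meaningful
        if not isinstance(other, CausalDag):
            return NotImplemented
        return dict(self.nodes) == dict(other.nodes) and set(self.edges) == set(
            other.edges
        )

    def __hash__(self) -> int:
        return hash(
            (frozenset(self.nodes.items()), frozenset(self.edges))
        )

    def graph(self) -> nx.DiGraph:
        """Return the underlying :class:`networkx.DiGraph`."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @property
    def observed(self) -> set[str]:
        return {n for n, obs in self.nodes.items() if obs}

    @property
    def latent(self) -> set[str]:
        return {n for n, obs in self.nodes.items() if not obs}

    def require(self, *names: str) -> None:
        for n in names:
            if n not in self.nodes:
                raise KeyError(f"unknown node: {n!r}")

    def descendants(self, node: str) -> set[str]:
        self.require(node)
        return nx.descendants(self.graph(), node)

    def ancestors_of(self, nodes: Iterable[str]) -> set[str]:
        g = self.graph()
        out: set[str] = set()
        for n in nodes:
            out |= nx.ancestors(g, n)
            out.add(n)
        return out

    def to_text(self) -> str:
        """Serialise to the edge-list text format, canonically sorted.

        Latent markers come first, then isolated observed nodes, then edges;
        ``parse_dag(dag.to_text())`` reproduces the DAG exactly.
        """
        lines: list[str] = []
        for n in sorted(self.latent):
            lines.append(f"{n} [latent]")
        touched = {v for e in self.edges for v in e} | self.latent
        for n in sorted(set(self.nodes) - touched):
            lines.append(n)
        for a, b in sorted(self.edges):
            lines.append(f"{a} -> {b}")
        return "\n".join(lines) + "\n"


@dataclass
class IndependenceClaim:
    """A conditional-independence claim ``x ⟂ y | given`` implied by a DAG.

    ``p_value``/``rejected`` are filled in by :func:`test_independences`;
    ``warning`` is set when a claim could not be tested (e.g. a constant
    column).
    """

    x: str
    y: str
    given: frozenset[str] = field(default_factory=frozenset)
    p_value: float | None = None
    rejected: bool | None = None
    warning: str | None = None

    def key(self) -> tuple:
        return (self.x, self.y, tuple(sorted(self.given)))


@dataclass(frozen=True)
class AdjustmentSet:
    """An observed covariate set satisfying the backdoor criterion."""

    exposure: str
    outcome: str
    members: frozenset[str]


# ---------------------------------------------------------------------------
# parsing


def parse_dag(text: str) -> CausalDag:
    """Parse edge-list DAG text.

    Each non-comment line is either an edge ``A -> B`` or a node declaration
    ``A`` / ``A [latent]``.  Undeclared edge endpoints default to observed
    nodes.  Raises :class:`DagParseError` on cycles, duplicate declarations or
    malformed lines.
    """
    nodes: dict[str, bool] = {}
    declared: set[str] = set()
    edges: list[tuple[str, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "->" in line:
            parts = [p.strip() for p in line.split("->")]
            if len(parts) != 2 or not all(parts):
                raise DagParseError(f"line {lineno}: malformed edge {raw!r}")
            a, b = parts
            for n in (a, b):
                nodes.setdefault(n, True)
            edges.append((a, b))
        else:
            latent = False
            name = line
            if line.endswith("[latent]"):
                latent = True
                name = line[: -len("[latent]")].strip()
            if not name or " " in name:
                raise DagParseError(f"line {lineno}: malformed declaration {raw!r}")
            if name in declared:
                raise DagParseError(f"line {lineno}: duplicate node {name!r}")
            declared.add(name)
            nodes[name] = not latent
    return CausalDag(nodes=nodes, edges=tuple(edges))


def load_dag(path) -> CausalDag:
    """Read a DAG from a text file in the edge-list format."""
    with open(path) as fh:
        return parse_dag(fh.read())


# ---------------------------------------------------------------------------
# d-separation and adjustment sets


def d_separated(dag: CausalDag, x: str, y: str, given: Iterable[str] = ()) -> bool:
    """True iff ``x`` and ``y`` are d-separated given ``given`` in the DAG."""
    given = set(given)
    dag.require(x, y, *given)
    if x == y:
        raise ValueError("x and y must differ")
    if x in given or y in given:
        raise ValueError("x and y must not be in the conditioning set")
    return nx.is_d_separator(dag.graph(), {x}, {y}, given)


def _backdoor_valid(g_cut: nx.DiGraph, x: str, y: str, zs: set[str]) -> bool:
    return nx.is_d_separator(g_cut, {x}, {y}, zs)


def minimal_adjustment_sets(
    dag: CausalDag, exposure: str, outcome: str
) -> list[AdjustmentSet]:
    """All minimal observed sets satisfying the backdoor criterion.

    Returns ``[AdjustmentSet(members=frozenset())]`` when no adjustment is
    needed, and ``[]`` when no valid observed set exists (e.g. an
    unobservable confounder).  Minimality = no proper subset is itself valid.

    Candidate members are pruned to observed ancestors of exposure or outcome
    in the exposure-outedge-cut graph: every inclusion-minimal separator lies
    within the ancestor set of the pair, so the pruning loses nothing.
    """
    dag.require(exposure, outcome)
    if exposure == outcome:
        raise ValueError("exposure and outcome must differ")
    if len(dag.observed) > MAX_ENUMERATION_NODES:
        raise ValueError(
            f"refusing enumeration over {len(dag.observed)} observed nodes "
            f"(guard: {MAX_ENUMERATION_NODES})"
        )
    g = dag.graph()
    g_cut = g.copy()
    g_cut.remove_edges_from(list(g.out_edges(exposure)))
    forbidden = nx.descendants(g, exposure) | {exposure, outcome}
    anc = set()
    for n in (exposure, outcome):
        anc |= nx.ancestors(g_cut, n)
        anc.add(n)
    candidates = sorted((dag.observed & anc) - forbidden)
    found: list[frozenset[str]] = []
    for size in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            zs = frozenset(combo)
            if any(m <= zs for m in found):
                continue
            if _backdoor_valid(g_cut, exposure, outcome, set(zs)):
                found.append(zs)
    return [
        AdjustmentSet(exposure=exposure, outcome=outcome, members=m)
        for m in sorted(found, key=lambda s: (len(s), tuple(sorted(s))))
    ]


def _minimal_separator(
    dag: CausalDag, x: str, y: str, pool: Sequence[str]
) -> frozenset[str] | None:
    """Smallest-cardinality separating subset of ``pool`` (lexicographic
    tie-break), or None when no subset of ``pool`` separates x and y."""
    g = dag.graph()
    anc = dag.ancestors_of([x, y])
    cand = sorted(set(pool) & anc - {x, y})
    for size in range(len(cand) + 1):
        for combo in itertools.combinations(cand, size):
            if nx.is_d_separator(g, {x}, {y}, set(combo)):
                return frozenset(combo)
    return None


def implied_independences(
    dag: CausalDag, observed_only: bool = True
) -> list[IndependenceClaim]:
    """One conditional-independence claim per separable non-adjacent pair.

    Each claim carries a minimal separating set (smallest cardinality, ties
    broken lexicographically).  With ``observed_only`` both the pair and the
    conditioning pool are restricted to observed nodes; pairs that cannot be
    separated by any observed set (e.g. connected through a latent mediator)
    are omitted.  Output order is independent of node declaration order.
    """
    pool = sorted(dag.observed if observed_only else set(dag.nodes))
    adj = {frozenset(e) for e in dag.edges}
    claims: list[IndependenceClaim] = []
    for x, y in itertools.combinations(pool, 2):
        if frozenset((x, y)) in adj:
            continue
        sep = _minimal_separator(dag, x, y, pool)
        if sep is None:
            continue
        claims.append(IndependenceClaim(x=x, y=y, given=sep))
    return claims


# ---------------------------------------------------------------------------
# data-consistency testing


def _encode(df: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    """Numeric design block: numeric columns as-is, categoricals as
    drop-first indicator contrasts."""
    blocks: list[np.ndarray] = []
    for c in cols:
        s = df[c]
        if pd.api.types.is_numeric_dtype(s) and not isinstance(
            s.dtype, pd.CategoricalDtype
        ):
            blocks.append(np.asarray(s, dtype=float)[:, None])
        else:
            d = pd.get_dummies(s.astype("category"), drop_first=True, dtype=float)
            blocks.append(np.asarray(d))
    if not blocks:
        return np.empty((len(df), 0))
    return np.hstack(blocks)


def _residualize(block: np.ndarray, zmat: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(zmat, block, rcond=None)
    return block - zmat @ beta


def test_independences(
    claims: Sequence[IndependenceClaim],
    data: pd.DataFrame,
    alpha: float = 0.05,
) -> list[IndependenceClaim]:
    """Attach residual-partial-correlation p-values to independence claims.

    For each claim both variables are regressed (least squares, indicator
    contrasts for categoricals) on the conditioning set; the test is of zero
    correlation between the residuals.  Multi-column blocks (categoricals
    with >2 levels) are handled by a Bonferroni-corrected minimum over the
    column-pair correlation tests, which is conservative but reduces exactly
    to the plain partial-correlation t-test in the all-continuous case.

    Claims with a constant column are returned untested with ``warning`` set.
    """
    out: list[IndependenceClaim] = []
    n = len(data)
    for claim in claims:
        cols = [claim.x, claim.y, *sorted(claim.given)]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise KeyError(f"claim variables missing from data: {missing}")
        new = replace(claim)
        if any(data[c].nunique(dropna=True) < 2 for c in (claim.x, claim.y)):
            new.warning = "constant column; test skipped"
            out.append(new)
            continue
        zmat = np.hstack(
            [np.ones((n, 1)), _encode(data, sorted(claim.given))]
        )
        rx = _residualize(_encode(data, [claim.x]), zmat)
        ry = _residualize(_encode(data, [claim.y]), zmat)
        dof = n - zmat.shape[1] - 2
        if dof <= 0:
            new.warning = "insufficient degrees of freedom"
            out.append(new)
            continue
        pvals = []
        for i in range(rx.shape[1]):
            for j in range(ry.shape[1]):
                denom = np.sqrt((rx[:, i] ** 2).sum() * (ry[:, j] ** 2).sum())
                r = 0.0 if denom == 0 else float(rx[:, i] @ ry[:, j] / denom)
                r = np.clip(r, -0.9999999999, 0.9999999999)
                t = r * np.sqrt(dof / (1 - r * r))
                pvals.append(2 * stats.t.sf(abs(t), dof))
        k = len(pvals)
        new.p_value = float(min(1.0, k * min(pvals)))
        new.rejected = bool(new.p_value < alpha)
        out.append(new)
    return out


# ---------------------------------------------------------------------------
# generic simulation from a DAG (used for consistency-test calibration)


def simulate_linear_gaussian(
    dag: CausalDag,
    n: int,
    seed: int | np.random.Generator = 0,
    coef_range: tuple[float, float] = (0.5, 1.5),
    include_latent: bool = False,
) -> pd.DataFrame:
    """Sample a linear-Gaussian structural equation model over the DAG.

    Each node is a weighted sum of its parents plus unit-variance Gaussian
    noise; edge weights are drawn uniformly from ``coef_range`` with random
    sign.  By construction the data satisfy exactly the DAG's conditional
    independences, which makes this the calibration source for
    :func:`test_independences`.  Latent columns are dropped unless requested.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    g = dag.graph()
    order = list(nx.topological_sort(g))
    values: dict[str, np.ndarray] = {}
    for node in order:
        x = rng.standard_normal(n)
        for parent in g.predecessors(node):
            w = rng.uniform(*coef_range) * rng.choice([-1.0, 1.0])
            x = x + w * values[parent]
        values[node] = x
    cols = order if include_latent else [c for c in order if c in dag.observed]
    return pd.DataFrame({c: values[c] for c in sorted(cols)})
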