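"""Constraint-based causal discovery over deletions, immune expression and RFS.

Implements the PC algorithm: a stable (order-independent) skeleton search
using Fisher-z partial-correlation tests, v-structure orientation from
separation sets, and Meek rules 1–4 to closure.  The output is a CPDAG —
the Markov equivalence class compatible with the conditional-independence
facts at level alpha.  The intended use is to find deletion -> immune-gene
-> recurrence-free-survival mediation paths; binary carrier indicators are
tested with the same Gaussian test treating 0/1 as numeric, the pragmatic
convention of common PC implementations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CausalDataset:
    """Sample x variable matrix with variable roles."""

    data: pd.DataFrame
    roles: dict[str, str]  # name -> "dsv" | "expression" | "outcome"

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("dataset contains missing values; apply listwise deletion")
        if self.data.shape[1] < 3:
            raise ValueError("need at least 3 variables")


def build_causal_dataset(carriers, expr, surv, outcome: str = "RFS") -> CausalDataset:
    """Assemble {DSV carriers, expression, observed RFS time} on event samples.

    Censoring-aware independence testing is out of scope: only samples with
    an observed recurrence enter, and RFS is their event time (continuous).
    """
    ev = surv.event == 1
    samples = surv.X.index[ev]
    d = carriers.data.loc[samples].astype(float)
    e = expr.values[list(samples)].T
    df = pd.concat([d, e], axis=1)
    df[outcome] = surv.time[ev]
    roles = {c: "dsv" for c in carriers.data.columns}
    roles.update({g: "expression" for g in expr.values.index})
    roles[outcome] = "outcome"
    return CausalDataset(data=df, roles=roles)


def ci_test_fisher_z(data, i, j, S=(), corr: np.ndarray | None = None, n: int | None = None) -> float:
    """Fisher-z test of partial correlation of variables i, j given set S.

    The partial correlation is read off the inverse of the correlation
    submatrix over {i, j} | S; z = sqrt(n - |S| - 3) * atanh(rho) is
    referred to a standard normal (two-sided).
    """
    if corr is None:
        arr = np.asarray(data, dtype=float)
        corr = np.corrcoef(arr, rowvar=False)
        n = arr.shape[0]
    S = list(S)
    if len(S) > n - 3:
        raise ValueError(f"conditioning set of size {len(S)} too large for n = {n}")
    idx = [i, j] + S
    sub = corr[np.ix_(idx, idx)]
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular correlation submatrix for ({i},{j}|{S})") from exc
    rho = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
    rho = float(np.clip(rho, -1 + 1e-12, 1 - 1e-12))
    z = np.sqrt(n - len(S) - 3) * np.arctanh(rho)
    return float(2 * stats.norm.sf(abs(z)))


def pc_skeleton(
    data, alpha: float = 0.05
) -> tuple[nx.Graph, dict[frozenset, set]]:
    """Stable-PC skeleton: edges removed level-by-level with per-level
    adjacency snapshots, so the result is independent of variable order.

    Returns the undirected skeleton over column names and a separation-set
    map for every removed pair.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    df = data.data if isinstance(data, CausalDataset) else pd.DataFrame(data)
    names = list(df.columns)
    arr = df.to_numpy(dtype=float)
    n, p = arr.shape
    corr = np.corrcoef(arr, rowvar=False)
    g = nx.complete_graph(p)
    sepsets: dict[frozenset, set] = {}

    level = 0
    while True:
        snapshot = {v: set(g.neighbors(v)) for v in g.nodes}
        if all(len(snapshot[v]) - 1 < level for v in g.nodes):
            break
        for i, j in list(g.edges):
            removed = False
            for a, b in ((i, j), (j, i)):
                cands = snapshot[a] - {b}
                if len(cands) < level:
                    continue
                for S in combinations(sorted(cands), level):
                    if level > n - 3:
                        break
                    pval = ci_test_fisher_z(None, a, b, list(S), corr=corr, n=n)
                    if pval > alpha:
                        g.remove_edge(i, j)
                        sepsets[frozenset((i, j))] = set(S)
                        removed = True
                        break
                if removed:
                    break
        level += 1

    skel = nx.relabel_nodes(g, dict(enumerate(names)))
    sep_named = {
        frozenset(names[v] for v in key): {names[v] for v in S}
        for key, S in sepsets.items()
    }
    return skel, sep_named


@dataclass
class Cpdag:
    """Completed partially directed acyclic graph."""

    nodes: list[str]
    directed: set[tuple[str, str]] = field(default_factory=set)
    undirected: set[frozenset] = field(default_factory=set)
    sepsets: dict[frozenset, set] = field(default_factory=dict)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for u, v in self.directed:
            if (v, u) in self.directed:
                raise ValueError(f"directed 2-cycle {u} <-> {v}")
            if frozenset((u, v)) in self.undirected:
                raise ValueError(f"edge {u}-{v} both directed and undirected")
        dg = nx.DiGraph(self.directed)
        if not nx.is_directed_acyclic_graph(dg):
            raise ValueError("directed part contains a cycle")


def orient_edges(skeleton: nx.Graph, sepsets: dict[frozenset, set], alpha: float = 0.05) -> Cpdag:
    """Orient v-structures, then apply Meek rules 1–4 to closure.

    A collider X -> Z <- Y is declared for every nonadjacent pair (X, Y)
    with common neighbour Z outside sepset(X, Y).  Conflicting collider
    claims on one edge leave it undirected (logged).
    """
    nodes = list(skeleton.nodes)
    directed: set[tuple[str, str]] = set()
    conflicted: set[frozenset] = set()

    def adjacent(a, b):
        return skeleton.has_edge(a, b)

    # v-structures
    for z in nodes:
        nbrs = sorted(skeleton.neighbors(z))
        for x, y in combinations(nbrs, 2):
            if adjacent(x, y):
                continue
            S = sepsets.get(frozenset((x, y)), set())
            if z not in S:
                for a in (x, y):
                    if (z, a) in directed:
                        logger.info("orientation conflict on %s-%s; left undirected", a, z)
                        conflicted.add(frozenset((a, z)))
                        directed.discard((z, a))
                    elif frozenset((a, z)) not in conflicted:
                        directed.add((a, z))

    def is_undir(a, b):
        return (
            adjacent(a, b)
            and (a, b) not in directed
            and (b, a) not in directed
        )

    def try_orient(a, b) -> bool:
        """Direct a -> b unless it conflicts or closes a directed cycle."""
        if (b, a) in directed or frozenset((a, b)) in conflicted:
            return False
        dg = nx.DiGraph(directed)
        dg.add_nodes_from(nodes)
        if dg.has_edge(a, b):
            return False
        if nx.has_path(dg, b, a):
            logger.info("skipping %s->%s: would close a cycle", a, b)
            return False
        directed.add((a, b))
        return True

    # Meek rules to closure
    changed = True
    while changed:
        changed = False
        for a, b in [(u, v) for u in nodes for v in skeleton.neighbors(u) if is_undir(u, v)]:
            # R1: c -> a, a - b, c not adjacent b  =>  a -> b
            if any(
                (c, a) in directed and not adjacent(c, b)
                for c in skeleton.neighbors(a)
            ):
                changed |= try_orient(a, b)
                continue
            # R2: a -> c -> b with a - b  =>  a -> b
            if any(
                (a, c) in directed and (c, b) in directed
                for c in nodes
            ):
                changed |= try_orient(a, b)
                continue
            # R3: a - c -> b, a - d -> b, c,d nonadjacent  =>  a -> b
            cd = [
                c
                for c in skeleton.neighbors(a)
                if is_undir(a, c) and (c, b) in directed
            ]
            if any(
                not adjacent(c, d) for c, d in combinations(cd, 2)
            ):
                changed |= try_orient(a, b)
                continue
            # R4: a - d, d -> c, c -> b, a - c (or a adj c), b,d nonadjacent => a -> b
            if any(
                is_undir(a, d)
                and not adjacent(d, b)
                and any(
                    (d, c) in directed and (c, b) in directed and adjacent(a, c)
                    for c in nodes
                )
                for d in skeleton.neighbors(a)
            ):
                changed |= try_orient(a, b)

    undirected = {
        frozenset((u, v))
        for u, v in skeleton.edges
        if (u, v) not in directed and (v, u) not in directed
    }
    return Cpdag(
        nodes=nodes,
        directed=directed,
        undirected=undirected,
        sepsets=sepsets,
        alpha=alpha,
    )


def pc_algorithm(data, alpha: float = 0.05) -> Cpdag:
    """Skeleton + orientation in one call."""
    skel, seps = pc_skeleton(data, alpha=alpha)
    return orient_edges(skel, seps, alpha=alpha)


def find_mediation_paths(
    g: Cpdag, dsv_nodes, outcome: str
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """Length-2 paths dsv -> mediator -> outcome in the CPDAG.

    Returns (fully directed paths, "compatible" paths with exactly one
    undirected hop that some member of the equivalence class directs the
    right way).
    """
    if outcome not in g.nodes:
        raise ValueError(f"outcome node {outcome!r} absent from graph")
    dsv_nodes = [d for d in dsv_nodes if d in g.nodes]
    directed, compatible = [], []
    for d in dsv_nodes:
        for m in g.nodes:
            if m == d or m == outcome:
                continue
            hop1_dir = (d, m) in g.directed
            hop1_und = frozenset((d, m)) in g.undirected
            hop2_dir = (m, outcome) in g.directed
            hop2_und = frozenset((m, outcome)) in g.undirected
            if hop1_dir and hop2_dir:
                directed.append((d, m, outcome))
            elif (hop1_dir or hop1_und) and (hop2_dir or hop2_und):
                compatible.append((d, m, outcome))
    return directed, compatible


def cpdag_edge_table(g: Cpdag) -> pd.DataFrame:
    """Edge list: (from, to, type) with undirected edges listed once."""
    rows = [{"from": u, "to": v, "type": "directed"} for u, v in sorted(g.directed)]
    rows += [
        {"from": u, "to": v, "type": "undirected"}
        for u, v in sorted(tuple(sorted(e)) for e in g.undirected)
    ]
    return pd.DataFrame(rows, columns=["from", "to", "type"])
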