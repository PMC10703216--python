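"""PC-stable structure learning over proteins plus the class variable.

A Bayesian network factorizes the joint distribution of the variables as
prod_i P(X_i | parents(X_i)) over a directed acyclic graph.  PC-type
algorithms recover the Markov equivalence class of that graph — a CPDAG —
from conditional-independence (CI) tests: start from the complete
undirected graph, remove edges whose endpoints test independent given some
conditioning set, orient the unshielded colliders the separation sets
reveal, and propagate orientations with the Meek rules.  The *stable*
variant freezes every node's adjacency set at the start of each
conditioning-set level, which makes the learned skeleton independent of
the order in which variables are presented.

CI testing is pluggable: Fisher-z on partial correlations (the binary
class label entering as 0/1), a G² likelihood-ratio test on discretized
data, or an exact oracle driven by a population covariance matrix (used to
validate structural recovery analytically).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_preprocess import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "CITestResult",
    "CPDAG",
    "FisherZTester",
    "G2Tester",
    "OracleTester",
    "ci_test",
    "learn_skeleton_stable",
    "orient_v_structures",
    "apply_meek_rules",
    "learn_cpdag",
    "direct_markers",
    "cpdag_from_dag",
]


@dataclass
class CITestResult:
    """Outcome of one conditional-independence test (symmetric in a, b)."""

    a: str
    b: str
    S: tuple[str, ...]
    statistic: float
    p_value: float
    independent: bool


@dataclass
class CPDAG:
    """Completed partially directed acyclic graph.

    ``undirected`` holds unordered pairs (frozensets), ``directed`` ordered
    pairs; the two sets are disjoint.  ``sepsets`` maps each non-adjacent
    pair that was actively separated to the conditioning set that rendered
    it independent.
    """

    nodes: list[str]
    undirected: set[frozenset] = field(default_factory=set)
    directed: set[tuple[str, str]] = field(default_factory=set)
    sepsets: dict[frozenset, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = {frozenset(e) for e in self.directed} & self.undirected
        if overlap:
            raise ValueError(f"edges both directed and undirected: {overlap}")
        if not self.directed_is_acyclic():
            raise ValueError("directed subgraph contains a cycle")

    def adjacent(self, a: str, b: str) -> bool:
        return (
            frozenset((a, b)) in self.undirected
            or (a, b) in self.directed
            or (b, a) in self.directed
        )

    def neighbors(self, node: str) -> list[str]:
        out = {next(iter(e - {node})) for e in self.undirected if node in e}
        out |= {b for a, b in self.directed if a == node}
        out |= {a for a, b in self.directed if b == node}
        return sorted(out)

    def n_edges(self) -> int:
        return len(self.undirected) + len(self.directed)

    def directed_is_acyclic(self) -> bool:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed)
        return nx.is_directed_acyclic_graph(g)

    def to_networkx(self) -> nx.DiGraph:
        """Export as a DiGraph; undirected edges become reciprocal arcs
        flagged ``directed=False``."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for a, b in sorted(self.directed):
            g.add_edge(a, b, directed=True)
        for e in self.undirected:
            a, b = sorted(e)
            g.add_edge(a, b, directed=False)
            g.add_edge(b, a, directed=False)
        return g

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def edge_table(self) -> pd.DataFrame:
        rows = [(a, b, True) for a, b in sorted(self.directed)]
        rows += [(*sorted(e), False) for e in self.undirected]
        rows.sort()
        return pd.DataFrame(rows, columns=["source", "target", "directed"])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CPDAG):
            return NotImplemented
        return (
            set(self.nodes) == set(other.nodes)
            and self.undirected == other.undirected
            and self.directed == other.directed
        )


# ---------------------------------------------------------------------------
# conditional-independence testers


def _partial_corr(corr: np.ndarray) -> float:
    """Partial correlation of variables 0 and 1 given the rest, from their
    joint correlation submatrix, via precision-matrix inversion."""
    prec = np.linalg.inv(corr)
    return float(-prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1]))


class FisherZTester:
    """Fisher-z CI test on partial correlations of continuous data.

    A binary class column is treated as 0/1 numeric.  The test statistic is
    sqrt(n - |S| - 3) * atanh(r_ab.S) with a two-sided normal p-value.  A
    singular conditioning correlation matrix makes the test undecidable;
    the pair is then conservatively reported dependent.
    """

    def __init__(self, data: pd.DataFrame, alpha: float = 0.05):
        self.alpha = alpha
        num = data.apply(_as_numeric)
        self.n = len(num)
        self.columns = list(num.columns)
        self.corr = num.corr().to_numpy()
        self._idx = {c: i for i, c in enumerate(self.columns)}

    def __call__(self, a: str, b: str, S: tuple[str, ...]) -> CITestResult:
        S = tuple(S)
        if self.n <= len(S) + 3:
            raise InputError(f"n={self.n} too small for |S|={len(S)}")
        ix = [self._idx[a], self._idx[b]] + [self._idx[s] for s in S]
        sub = self.corr[np.ix_(ix, ix)]
        try:
            r = _partial_corr(sub)
        except np.linalg.LinAlgError:
            logger.warning("singular correlation matrix for (%s,%s | %s); "
                           "treating as dependent", a, b, S)
            return CITestResult(a, b, S, np.inf, 0.0, False)
        r = float(np.clip(r, -0.9999999, 0.9999999))
        z = np.sqrt(self.n - len(S) - 3) * np.arctanh(r)
        p = 2 * stats.norm.sf(abs(z))
        return CITestResult(a, b, S, float(z), float(p), p > self.alpha)


class G2Tester:
    """G² likelihood-ratio CI test after quantile discretization.

    Continuous variables are cut into ``n_bins`` quantile bins (default 3);
    variables with at most ``n_bins`` distinct values are kept as-is.  The
    statistic sums 2·O·ln(O/E) over the a×b contingency table within every
    configuration of the conditioning variables, with degrees of freedom
    (r_a - 1)(r_b - 1)·prod(r_s).
    """

    def __init__(self, data: pd.DataFrame, alpha: float = 0.05, n_bins: int = 3):
        self.alpha = alpha
        self.columns = list(data.columns)
        disc = {}
        for c in data.columns:
            col = data[c]
            codes = pd.factorize(col)[0] if col.nunique() <= n_bins else (
                pd.qcut(col.rank(method="first"), n_bins, labels=False)
            )
            disc[c] = np.asarray(codes, dtype=int)
        self.disc = pd.DataFrame(disc, index=data.index)
        self.levels = {c: int(self.disc[c].max()) + 1 for c in data.columns}

    def __call__(self, a: str, b: str, S: tuple[str, ...]) -> CITestResult:
        S = tuple(S)
        df_total = (self.levels[a] - 1) * (self.levels[b] - 1)
        for s in S:
            df_total *= self.levels[s]
        g2 = 0.0
        groups = (
            self.disc.groupby([self.disc[s] for s in S]) if S else [(None, self.disc)]
        )
        for _, chunk in groups:
            tab = pd.crosstab(chunk[a], chunk[b]).to_numpy(dtype=float)
            if tab.sum() == 0 or min(tab.shape) < 2:
                continue
            rows = tab.sum(1, keepdims=True)
            cols = tab.sum(0, keepdims=True)
            expected = rows @ cols / tab.sum()
            nz = tab > 0
            g2 += 2 * float((tab[nz] * np.log(tab[nz] / expected[nz])).sum())
        p = float(stats.chi2.sf(g2, df_total)) if df_total > 0 else 1.0
        return CITestResult(a, b, S, g2, p, p > self.alpha)


class OracleTester:
    """Exact CI oracle from a population covariance of a linear-Gaussian DAG.

    Declares (a ⟂ b | S) iff the analytic partial correlation vanishes
    (|r| < tol).  Used to validate structural recovery independently of
    sampling noise.
    """

    def __init__(self, cov: pd.DataFrame, tol: float = 1e-8):
        self.columns = list(cov.columns)
        self.cov = cov.to_numpy(dtype=float)
        self._idx = {c: i for i, c in enumerate(self.columns)}
        self.tol = tol
        self.alpha = 0.5  # nominal; decisions come from tol

    def __call__(self, a: str, b: str, S: tuple[str, ...]) -> CITestResult:
        S = tuple(S)
        ix = [self._idx[a], self._idx[b]] + [self._idx[s] for s in S]
        r = _partial_corr(self.cov[np.ix_(ix, ix)])
        indep = abs(r) < self.tol
        return CITestResult(a, b, S, r, 1.0 if indep else 0.0, indep)


def _as_numeric(col: pd.Series) -> pd.Series:
    if col.dtype == object or str(col.dtype) == "category":
        return pd.Series(pd.factorize(col, sort=True)[0], index=col.index, dtype=float)
    return col.astype(float)


def _make_tester(data: pd.DataFrame, alpha: float, method: str):
    if method == "fisher_z":
        return FisherZTester(data, alpha)
    if method == "g2_disc":
        return G2Tester(data, alpha)
    raise InputError(f"unknown CI method {method!r}")


def ci_test(
    data: pd.DataFrame,
    a: str,
    b: str,
    S: tuple[str, ...] = (),
    alpha: float = 0.05,
    method: str = "fisher_z",
) -> CITestResult:
    """Test conditional independence of ``a`` and ``b`` given ``S``."""
    return _make_tester(data, alpha, method)(a, b, tuple(S))


# ---------------------------------------------------------------------------
# PC-stable


def learn_skeleton_stable(
    data_or_tester,
    alpha: float = 0.05,
    max_cond: int | None = None,
    method: str = "fisher_z",
) -> tuple[nx.Graph, dict[frozenset, tuple[str, ...]]]:
    """Level-wise edge removal with adjacency sets frozen per level.

    At level ℓ every still-present edge a−b is tested against all size-ℓ
    subsets of adj(a)\\{b} and adj(b)\\{a}, where the adjacency sets are the
    ones recorded at the *start* of the level — the stable rule that makes
    the outcome invariant to variable ordering.  The conditioning set that
    first renders a pair independent is stored as its sepset.
    """
    tester = (
        _make_tester(data_or_tester, alpha, method)
        if isinstance(data_or_tester, pd.DataFrame)
        else data_or_tester
    )
    nodes = sorted(tester.columns)
    if max_cond is None:
        max_cond = len(nodes) - 2
    if hasattr(tester, "n"):  # Fisher-z needs n > |S| + 3
        max_cond = min(max_cond, tester.n - 4)
    adj: dict[str, set[str]] = {v: set(nodes) - {v} for v in nodes}
    sepsets: dict[frozenset, tuple[str, ...]] = {}

    level = 0
    while level <= max_cond:
        frozen = {v: sorted(adj[v]) for v in nodes}
        if all(len(frozen[v]) - 1 < level for v in nodes):
            break
        for a, b in combinations(nodes, 2):
            if b not in adj[a]:
                continue
            removed = False
            for x, y in ((a, b), (b, a)):
                candidates = [c for c in frozen[x] if c != y]
                if len(candidates) < level:
                    continue
                for S in combinations(candidates, level):
                    if tester(x, y, S).independent:
                        adj[a].discard(b)
                        adj[b].discard(a)
                        sepsets[frozenset((a, b))] = S
                        removed = True
                        break
                if removed:
                    break
        level += 1

    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from((a, b) for a in nodes for b in adj[a] if a < b)
    return g, sepsets


def orient_v_structures(
    skeleton: nx.Graph, sepsets: dict[frozenset, tuple[str, ...]]
) -> CPDAG:
    """Orient unshielded triples a−c−b as colliders a→c←b when c is absent
    from sepset(a, b); conflicting orientations revert to undirected."""
    nodes = sorted(skeleton.nodes)
    proposals: set[tuple[str, str]] = set()
    for c in nodes:
        for a, b in combinations(sorted(skeleton.neighbors(c)), 2):
            if skeleton.has_edge(a, b):
                continue
            if c not in sepsets.get(frozenset((a, b)), ()):
                proposals.add((a, c))
                proposals.add((b, c))
    directed = set()
    conflicted = set()
    for u, v in proposals:
        if (v, u) in proposals:
            conflicted.add(frozenset((u, v)))
        else:
            directed.add((u, v))
    for e in conflicted:
        logger.warning("conflicting collider orientations on %s; left undirected",
                       tuple(sorted(e)))
    undirected = {
        frozenset(e) for e in skeleton.edges
        if not ({(e[0], e[1]), (e[1], e[0])} & directed)
    }
    return CPDAG(nodes=nodes, undirected=undirected, directed=directed, sepsets=dict(sepsets))


def apply_meek_rules(pdag: CPDAG) -> CPDAG:
    """Propagate orientations to the maximally oriented CPDAG.

    Rules applied to closure: (R1) a→b, b−c, a≁c ⇒ b→c; (R2) a→b→c with
    a−c ⇒ a→c; (R3) a−b with two nonadjacent c, d satisfying a−c, a−d,
    c→b, d→b ⇒ a→b.  These three rules are complete for patterns produced
    by CI-based skeleton + collider discovery without background knowledge.
    """
    undirected = set(pdag.undirected)
    directed = set(pdag.directed)

    def adjacent(a, b):
        return frozenset((a, b)) in undirected or (a, b) in directed or (b, a) in directed

    def orient(u, v):
        undirected.discard(frozenset((u, v)))
        directed.add((u, v))

    changed = True
    while changed:
        changed = False
        for edge in sorted(undirected, key=lambda e: tuple(sorted(e))):
            x, y = sorted(edge)
            for a, b in ((x, y), (y, x)):
                # R1: some c→a with c not adjacent to b
                if any(v == a and not adjacent(u, b) and u != b for u, v in directed):
                    orient(a, b)
                    changed = True
                    break
                # R2: directed path a→k→b
                if any(
                    (a, k) in directed and (k, b) in directed
                    for k in pdag.nodes
                    if k not in (a, b)
                ):
                    orient(a, b)
                    changed = True
                    break
                # R3: c, d nonadjacent, a−c, a−d, c→b, d→b
                cands = [
                    c for c in pdag.nodes
                    if frozenset((a, c)) in undirected and (c, b) in directed
                ]
                if any(
                    not adjacent(c, d)
                    for c, d in combinations(sorted(cands), 2)
                ):
                    orient(a, b)
                    changed = True
                    break
            if changed:
                break
    return CPDAG(nodes=list(pdag.nodes), undirected=undirected, directed=directed,
                 sepsets=dict(pdag.sepsets))


def learn_cpdag(
    data_or_tester,
    alpha: float = 0.05,
    max_cond: int | None = None,
    method: str = "fisher_z",
) -> CPDAG:
    """Full PC-stable run: skeleton, collider orientation, Meek closure."""
    skeleton, sepsets = learn_skeleton_stable(data_or_tester, alpha, max_cond, method)
    return apply_meek_rules(orient_v_structures(skeleton, sepsets))


def direct_markers(cpdag: CPDAG, class_node: str) -> list[tuple[str, str]]:
    """Variables adjacent to the class node, with their edge orientation.

    Returns (name, orientation) pairs sorted by name; orientation is
    ``"to_class"``, ``"from_class"`` or ``"undirected"``.
    """
    if class_node not in cpdag.nodes:
        raise InputError(f"class node {class_node!r} not in the graph")
    out = []
    for nb in cpdag.neighbors(class_node):
        if (nb, class_node) in cpdag.directed:
            kind = "to_class"
        elif (class_node, nb) in cpdag.directed:
            kind = "from_class"
        else:
            kind = "undirected"
        out.append((nb, kind))
    return out


def cpdag_from_dag(edges: list[tuple[str, str]], nodes: list[str] | None = None) -> CPDAG:
    """CPDAG (Markov equivalence class) of a known DAG.

    Keeps the skeleton, orients exactly the unshielded colliders of the
    DAG, and closes under the Meek rules.
    """
    dag = nx.DiGraph(edges)
    if nodes:
        dag.add_nodes_from(nodes)
    if not nx.is_directed_acyclic_graph(dag):
        raise InputError("edge list contains a directed cycle")
    skel = dag.to_undirected()
    directed: set[tuple[str, str]] = set()
    for c in dag.nodes:
        for a, b in combinations(sorted(dag.predecessors(c)), 2):
            if not skel.has_edge(a, b):
                directed.add((a, c))
                directed.add((b, c))
    undirected = {
        frozenset(e) for e in skel.edges
        if not ({(e[0], e[1]), (e[1], e[0])} & directed)
    }
    pdag = CPDAG(nodes=sorted(dag.nodes), undirected=undirected, directed=directed)
    return apply_meek_rules(pdag)
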