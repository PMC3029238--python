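"""Negative-control network ensembles and empirical randomization p-values.

Two null schemes, used throughout the analyses:

* **NLS (node label shuffling)** permutes node identities over a fixed
  topology. Each protein keeps its own annotations (phospho label,
  covariates) but lands on a uniformly random network position, so every
  degree/label association is destroyed while the unlabeled graph is
  untouched. The shuffle is drawn as a uniform permutation — the fixed point
  of the random-transposition walk run to its iteration cap.
* **RER (random edge rewiring)** repeatedly picks two edges (a,b), (c,d) and
  swaps endpoints to (a,d),(c,b) or (a,c),(b,d), rejecting any move that
  would create a self-loop or duplicate edge. Every node keeps its exact
  degree; only the pairing of endpoints varies. Self-edges present in the
  input are frozen out of the swap pool and preserved verbatim.

Empirical p-values follow the raw-proportion definition: the fraction of
null statistics at least as extreme as the observed one, reported together
with N so that a zero proportion can be rendered as "< 1/N".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import networkx as nx

from .network import PhosphoPPI

DEFAULT_MULTIPLIER = 1000  # swap budget = multiplier x |E|


@dataclass
class EmpiricalP:
    """Empirical tail probability with its resolution.

    ``proportion`` is the raw fraction r/N of null values at least as
    extreme as the observed one (the definition used for all significance
    calls); ``conservative`` is the add-one variant (r+1)/(N+1) carried as
    metadata.
    """

    proportion: float
    n: int
    side: str

    @property
    def conservative(self) -> float:
        return (self.proportion * self.n + 1) / (self.n + 1)

    @property
    def label(self) -> str:
        if self.proportion == 0.0:
            return f"< {1 / self.n:g}"
        return f"{self.proportion:g}"

    def __float__(self) -> float:
        return self.proportion

    def __lt__(self, other) -> bool:
        return self.proportion < float(other)

    def __le__(self, other) -> bool:
        return self.proportion <= float(other)


@dataclass
class NullEnsemble:
    """Summary statistics of N randomized replicas (replicas are streamed)."""

    scheme: str
    n_replicates: int
    seed: int
    statistics: list = field(default_factory=list)
    multiplier: int = DEFAULT_MULTIPLIER

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def metadata(self) -> dict:
        return {
            "scheme": self.scheme,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "multiplier": self.multiplier,
        }


def empirical_pvalue(observed: float, nulls: Sequence[float], side: str = "ge") -> EmpiricalP:
    """Proportion of null values >= (side="ge") or <= (side="le") observed."""
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size == 0:
        raise ValueError("empirical_pvalue requires a nonempty null sample")
    if side == "ge":
        r = int(np.count_nonzero(nulls >= observed))
    elif side == "le":
        r = int(np.count_nonzero(nulls <= observed))
    else:
        raise ValueError(f"side must be 'ge' or 'le', got {side!r}")
    return EmpiricalP(r / nulls.size, int(nulls.size), side)


def two_sided_empirical_pvalue(observed: float, nulls: Sequence[float]) -> float:
    """2 x min(tail proportions), capped at 1."""
    ge = empirical_pvalue(observed, nulls, "ge").proportion
    le = empirical_pvalue(observed, nulls, "le").proportion
    return min(1.0, 2.0 * min(ge, le))


# ---------------------------------------------------------------------------
# array-level core (node ids are 0..n-1 integers)
# ---------------------------------------------------------------------------


def _to_arrays(net: PhosphoPPI):
    """(node names, name->index, edge list of int 2-tuples, frozen self-loops,
    phospho bool array)."""
    nodes = list(net.graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges: list[tuple[int, int]] = []
    frozen: list[int] = []  # self-loop node indices, excluded from swaps
    for u, v in net.graph.edges:
        if u == v:
            frozen.append(index[u])
        else:
            iu, iv = index[u], index[v]
            edges.append((iu, iv) if iu < iv else (iv, iu))
    phospho = np.array([net.is_phospho(v) for v in nodes], dtype=bool)
    return nodes, index, edges, frozen, phospho


try:  # JIT fast path for the swap chain; the pure-Python chain is the fallback
    import numba as _numba
except ImportError:  # pragma: no cover
    _numba = None

_REWIRE_KERNEL = None


def _get_rewire_kernel():
    global _REWIRE_KERNEL
    if _REWIRE_KERNEL is None and _numba is not None:

        @_numba.njit(cache=True)
        def kernel(eu, ev, adj, orig, budget, seed):  # pragma: no cover - jitted
            np.random.seed(seed)
            m = eu.shape[0]
            shared = 0
            for i in range(m):
                if orig[eu[i], ev[i]]:
                    shared += 1
            spent = 0
            while spent < budget and shared > 0:
                spent += 1
                e1 = np.random.randint(0, m)
                e2 = np.random.randint(0, m)
                if e1 == e2:
                    continue
                a, b = eu[e1], ev[e1]
                c, d = eu[e2], ev[e2]
                if np.random.randint(0, 2) == 1:
                    p, q, r, s = a, d, c, b
                else:
                    p, q, r, s = a, c, b, d
                if p == q or r == s:
                    continue
                if adj[p, q] or adj[r, s]:
                    continue
                if (p == r and q == s) or (p == s and q == r):
                    continue
                if orig[a, b]:
                    shared -= 1
                if orig[c, d]:
                    shared -= 1
                adj[a, b] = adj[b, a] = False
                adj[c, d] = adj[d, c] = False
                adj[p, q] = adj[q, p] = True
                adj[r, s] = adj[s, r] = True
                eu[e1], ev[e1] = p, q
                eu[e2], ev[e2] = r, s
                if orig[p, q]:
                    shared += 1
                if orig[r, s]:
                    shared += 1

        _REWIRE_KERNEL = kernel
    return _REWIRE_KERNEL


def _rewire_arrays_fast(
    eu: np.ndarray,
    ev: np.ndarray,
    n_nodes: int,
    orig_adj: np.ndarray,
    rng: np.random.Generator,
    multiplier: int,
) -> tuple[np.ndarray, np.ndarray] | None:
    """JIT swap chain on endpoint arrays; None when the fast path is off."""
    kernel = _get_rewire_kernel()
    if kernel is None or n_nodes > 20000:
        return None
    eu = eu.copy()
    ev = ev.copy()
    adj = orig_adj.copy()
    kernel(eu, ev, adj, orig_adj, multiplier * eu.shape[0], int(rng.integers(2**31)))
    return eu, ev


def _orig_adjacency(eu: np.ndarray, ev: np.ndarray, n_nodes: int) -> np.ndarray:
    adj = np.zeros((n_nodes, n_nodes), dtype=bool)
    adj[eu, ev] = True
    adj[ev, eu] = True
    return adj


def rewire_edges(
    edges: list[tuple[int, int]],
    rng: np.random.Generator,
    multiplier: int = DEFAULT_MULTIPLIER,
    count_retries: bool = True,
) -> list[tuple[int, int]]:
    """Degree-preserving double-edge-swap chain on an int edge list.

    Terminates when the current edge set shares no pair with the original or
    when the iteration budget ``multiplier * |edges|`` is exhausted. Moves
    that would create a duplicate edge or self-loop are retried; retries
    count against the budget when ``count_retries`` (the default).
    """
    m = len(edges)
    if m < 2:
        return list(edges)
    edges = list(edges)
    edge_set = set(edges)
    original = frozenset(edges)
    shared = m  # |current edge set  ∩  original|
    budget = multiplier * m
    spent = 0
    proposals = 0
    # hard cap so graphs with no accepted move terminate even when retries
    # are not counted against the budget
    max_proposals = 50 * budget
    chunk = 8192
    while spent < budget and shared > 0 and proposals < max_proposals:
        todo = min(chunk, budget - spent) if count_retries else chunk
        proposals += todo
        picks = rng.integers(0, m, size=2 * todo)
        coins = rng.integers(0, 2, size=todo)
        for t in range(todo):
            if count_retries:
                spent += 1
            e1 = picks[2 * t]
            e2 = picks[2 * t + 1]
            if e1 == e2:
                continue
            a, b = edges[e1]
            c, d = edges[e2]
            if coins[t]:
                p, q, r, s = a, d, c, b
            else:
                p, q, r, s = a, c, b, d
            if p == q or r == s:
                continue
            new1 = (p, q) if p < q else (q, p)
            new2 = (r, s) if r < s else (s, r)
            if new1 == new2 or new1 in edge_set or new2 in edge_set:
                continue
            old1, old2 = edges[e1], edges[e2]
            edge_set.discard(old1)
            edge_set.discard(old2)
            edge_set.add(new1)
            edge_set.add(new2)
            edges[e1] = new1
            edges[e2] = new2
            shared += (new1 in original) + (new2 in original)
            shared -= (old1 in original) + (old2 in original)
            if not count_retries:
                spent += 1
            if shared == 0:
                break
    return edges


def _permute_edges(
    edges: list[tuple[int, int]], frozen: list[int], perm: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a node-position permutation to an edge list; returns (u, v) arrays
    including the (permuted) self-loops."""
    if edges:
        arr = np.asarray(edges, dtype=np.int64)
        u, v = perm[arr[:, 0]], perm[arr[:, 1]]
    else:
        u = v = np.empty(0, dtype=np.int64)
    if frozen:
        loops = perm[np.asarray(frozen, dtype=np.int64)]
        u = np.concatenate([u, loops])
        v = np.concatenate([v, loops])
    return u, v


def _edges_to_graph(
    nodes: list, u: np.ndarray, v: np.ndarray, net: PhosphoPPI
) -> PhosphoPPI:
    graph = nx.Graph()
    graph.add_nodes_from((name, dict(net.graph.nodes[name])) for name in nodes)
    graph.add_edges_from(zip((nodes[i] for i in u), (nodes[i] for i in v)))
    return PhosphoPPI(graph, category=net.category, filtered=net.filtered)


# ---------------------------------------------------------------------------
# graph-level operations
# ---------------------------------------------------------------------------


def node_label_shuffle(net: PhosphoPPI, rng: np.random.Generator) -> PhosphoPPI:
    """Uniformly permute node identities over the fixed topology.

    Each protein keeps its own attributes but occupies a random network
    position; the unlabeled topology (sorted degree sequence, edge count)
    is exactly preserved.
    """
    if net.n_nodes < 2:
        raise ValueError("node label shuffling needs at least 2 nodes")
    nodes, _, edges, frozen, _ = _to_arrays(net)
    perm = rng.permutation(len(nodes))
    u, v = _permute_edges(edges, frozen, perm)
    return _edges_to_graph(nodes, u, v, net)


def random_edge_rewire(
    net: PhosphoPPI,
    rng: np.random.Generator,
    multiplier: int = DEFAULT_MULTIPLIER,
    count_retries: bool = True,
) -> PhosphoPPI:
    """Degree-preserving rewiring of the whole network (self-loops frozen)."""
    nodes, _, edges, frozen, _ = _to_arrays(net)
    if len(edges) < 2:
        import warnings

        warnings.warn("fewer than 2 rewirable edges; returning an identical copy")
        return net.copy()
    arr = np.asarray(edges, dtype=np.int64)
    fast = None
    if count_retries:
        fast = _rewire_arrays_fast(
            arr[:, 0], arr[:, 1], len(nodes), _orig_adjacency(arr[:, 0], arr[:, 1], len(nodes)),
            rng, multiplier,
        )
    if fast is not None:
        new_edges = list(zip(fast[0].tolist(), fast[1].tolist()))
    else:
        new_edges = rewire_edges(edges, rng, multiplier, count_retries)
    u, v = _permute_edges(new_edges, frozen, np.arange(len(nodes)))
    return _edges_to_graph(nodes, u, v, net)


def child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic per-replicate generators spawned from one seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def array_ensemble(
    net: PhosphoPPI,
    scheme: str,
    statistic_fn: Callable[[np.ndarray, np.ndarray, np.ndarray], object],
    n: int,
    seed: int,
    multiplier: int = DEFAULT_MULTIPLIER,
) -> NullEnsemble:
    """Fast ensemble: the statistic sees (u, v, phospho) index arrays.

    ``u``/``v`` are endpoint index arrays over nodes 0..n-1 (in the node
    order of ``net.graph.nodes``) and ``phospho`` the per-node label array.
    Used internally by analyses whose statistics need only edges and labels.
    """
    if scheme not in ("NLS", "RER"):
        raise ValueError(f"scheme must be 'NLS' or 'RER', got {scheme!r}")
    nodes, _, edges, frozen, phospho = _to_arrays(net)
    identity = np.arange(len(nodes))
    ens = NullEnsemble(scheme, n, seed, multiplier=multiplier)
    orig_adj = None
    eu = ev = None
    if scheme == "RER" and len(edges) >= 2:
        arr = np.asarray(edges, dtype=np.int64)
        eu, ev = arr[:, 0], arr[:, 1]
        orig_adj = _orig_adjacency(eu, ev, len(nodes))
    for i, rng in enumerate(child_rngs(seed, n)):
        try:
            if scheme == "NLS":
                u, v = _permute_edges(edges, frozen, rng.permutation(len(nodes)))
            elif orig_adj is not None:
                fast = _rewire_arrays_fast(eu, ev, len(nodes), orig_adj, rng, multiplier)
                if fast is None:
                    u, v = _permute_edges(
                        rewire_edges(edges, rng, multiplier), frozen, identity
                    )
                else:
                    u, v = _permute_edges(
                        list(zip(fast[0].tolist(), fast[1].tolist())), frozen, identity
                    )
            else:
                u, v = _permute_edges(rewire_edges(edges, rng, multiplier), frozen, identity)
            ens.statistics.append(statistic_fn(u, v, phospho))
        except Exception as exc:
            raise RuntimeError(f"statistic failed on replicate {i}: {exc}") from exc
    return ens


def ensemble(
    net: PhosphoPPI,
    scheme: str,
    statistic_fn: Callable[[PhosphoPPI], object],
    n: int,
    seed: int,
    multiplier: int = DEFAULT_MULTIPLIER,
) -> NullEnsemble:
    """Generate N independent randomizations and record a statistic of each.

    Replicate i draws its generator from the i-th spawn of ``seed``'s seed
    sequence, so results are reproducible bit-for-bit given (scheme, n,
    seed) regardless of execution order.
    """
    if scheme not in ("NLS", "RER"):
        raise ValueError(f"scheme must be 'NLS' or 'RER', got {scheme!r}")
    ens = NullEnsemble(scheme, n, seed, multiplier=multiplier)
    for i, rng in enumerate(child_rngs(seed, n)):
        try:
            replica = (
                node_label_shuffle(net, rng)
                if scheme == "NLS"
                else random_edge_rewire(net, rng, multiplier)
            )
            ens.statistics.append(statistic_fn(replica))
        except Exception as exc:
            raise RuntimeError(f"statistic failed on replicate {i}: {exc}") from exc
    return ens


def stars(p: float, thresholds: tuple[float, float, float] = (0.05, 0.01, 0.001)) -> str:
    """Significance tier string for a p-value: ns / * / ** / ***."""
    if p < thresholds[2]:
        return "***"
    if p < thresholds[1]:
        return "**"
    if p < thresholds[0]:
        return "*"
    return "ns"
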