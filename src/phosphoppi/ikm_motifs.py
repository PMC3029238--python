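"""Interacting kinate modules (IKMs) and signaling/PPI edge overlap.

An IKM is a triangle motif of one kinase and two of its substrates that
physically interact with each other. The kinase's own edges come from the
kinase-substrate table, not the PPI, so only substrate-substrate edges are
queried and the kinase itself need not be a network node. A kinase's IKM
formability is significant when its observed count beats BOTH null schemes
(NLS, which randomizes which proteins occupy network positions, and RER,
which rewires edges with every degree fixed) at the 0.05 level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .network import PhosphoPPI
from .null_models import (
    DEFAULT_MULTIPLIER,
    EmpiricalP,
    array_ensemble,
    empirical_pvalue,
)


@dataclass
class KinaseSubstrateMap:
    """kinase accession -> substrate accession set, with a source tag.

    Autophosphorylation entries (kinase listed as its own substrate) are
    removed on construction; for IKM analysis only kinases with at least two
    substrates are informative.
    """

    mapping: dict[str, set[str]] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        for kinase, subs in self.mapping.items():
            subs.discard(kinase)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]], source: str = "") -> "KinaseSubstrateMap":
        mapping: dict[str, set[str]] = {}
        for kin, sub in pairs:
            mapping.setdefault(kin, set()).add(sub)
        return cls(mapping, source)

    def with_min_substrates(self, n: int = 2) -> "KinaseSubstrateMap":
        return KinaseSubstrateMap(
            {k: set(s) for k, s in self.mapping.items() if len(s) >= n}, self.source
        )

    def __len__(self) -> int:
        return len(self.mapping)

    def __iter__(self):
        return iter(self.mapping)


@dataclass
class IKMResult:
    kinase: str
    n_substrates_in_network: int
    ikm_count: int
    p_nls: EmpiricalP
    p_rer: EmpiricalP

    @property
    def significant(self) -> bool:
        """Beats both null schemes at the 0.05 level."""
        return self.p_nls.proportion < 0.05 and self.p_rer.proportion < 0.05


def count_ikms(net: PhosphoPPI, substrates: Iterable[str]) -> int:
    """Number of substrate pairs {S1, S2}, S1 != S2, wired in the network.

    Substrates are intersected with the network node set first; equivalent
    to counting the edges of the substrate-induced subgraph (self-edges
    never qualify since the pair must be distinct).
    """
    subs = [s for s in set(substrates) if s in net.graph]
    sub_set = set(subs)
    count = 0
    for s in subs:
        for nbr in net.graph.adj[s]:
            if nbr != s and nbr in sub_set:
                count += 1
    return count // 2


@dataclass
class IKMExclusion:
    kinase: str
    reason: str


def ikm_significance(
    net: PhosphoPPI,
    ksmap: KinaseSubstrateMap,
    n: int,
    seed: int,
    multiplier: int = DEFAULT_MULTIPLIER,
) -> tuple[list[IKMResult], list[IKMExclusion]]:
    """Per-kinase IKM counts with one-sided empirical p under NLS and RER.

    All kinases are evaluated against the same two replicate streams (one
    NLS, one RER), so a kinase's two p-values refer to N replicas each.
    Kinases with fewer than two substrates in the network are excluded with
    a reason.
    """
    if n < 100:
        raise ValueError("IKM significance requires n >= 100 replicates")
    node_index = {v: i for i, v in enumerate(net.graph.nodes)}
    n_nodes = len(node_index)
    usable: list[tuple[str, np.ndarray]] = []
    excluded: list[IKMExclusion] = []
    for kinase in sorted(ksmap.mapping):
        in_net = [node_index[s] for s in ksmap.mapping[kinase] if s in node_index]
        if len(in_net) < 2:
            excluded.append(
                IKMExclusion(kinase, f"only {len(in_net)} substrate(s) in the network")
            )
            continue
        mask = np.zeros(n_nodes, dtype=bool)
        mask[in_net] = True
        usable.append((kinase, mask))
    if not usable:
        return [], excluded

    masks = np.vstack([m for _, m in usable])  # (K, n_nodes)

    def per_kinase_counts(u: np.ndarray, v: np.ndarray, phospho: np.ndarray) -> np.ndarray:
        non_self = u != v
        return (masks[:, u[non_self]] & masks[:, v[non_self]]).sum(axis=1)

    nls = array_ensemble(net, "NLS", per_kinase_counts, n, seed, multiplier)
    rer = array_ensemble(net, "RER", per_kinase_counts, n, seed + 1, multiplier)
    nls_stats = np.vstack(nls.statistics)
    rer_stats = np.vstack(rer.statistics)

    results: list[IKMResult] = []
    for j, (kinase, mask) in enumerate(usable):
        observed = count_ikms(net, [s for s in ksmap.mapping[kinase] if s in node_index])
        results.append(
            IKMResult(
                kinase=kinase,
                n_substrates_in_network=int(mask.sum()),
                ikm_count=observed,
                p_nls=empirical_pvalue(observed, nls_stats[:, j], "ge"),
                p_rer=empirical_pvalue(observed, rer_stats[:, j], "ge"),
            )
        )
    return results, excluded


@dataclass
class OverlapResult:
    n_reactions: int
    n_overlap: int
    fraction: float
    p_rer: EmpiricalP | None


def signaling_overlap(
    net: PhosphoPPI,
    reactions: Sequence[tuple[str, str]],
    n: int = 0,
    seed: int = 0,
    multiplier: int = DEFAULT_MULTIPLIER,
) -> OverlapResult:
    """Fraction of signaling reaction pairs present as PPI edges.

    Reaction direction is ignored (the PPI is undirected). With ``n`` > 0, a
    one-sided (ge) empirical p against the RER ensemble is attached.
    """
    if not reactions:
        raise ValueError("signaling_overlap requires at least one reaction")
    pairs = {tuple(sorted(r)) for r in reactions}
    node_index = {v: i for i, v in enumerate(net.graph.nodes)}
    idx_pairs = {
        (node_index[a], node_index[b]) if node_index[a] < node_index[b] else (node_index[b], node_index[a])
        for a, b in pairs
        if a in node_index and b in node_index and a != b
    }
    observed = sum(1 for a, b in pairs if a != b and net.graph.has_edge(a, b))
    fraction = observed / len(pairs)
    p = None
    if n > 0:

        def overlap_stat(u: np.ndarray, v: np.ndarray, phospho: np.ndarray) -> int:
            lo = np.minimum(u, v)
            hi = np.maximum(u, v)
            return sum(1 for e in zip(lo.tolist(), hi.tolist()) if e in idx_pairs)

        ens = array_ensemble(net, "RER", overlap_stat, n, seed, multiplier)
        p = empirical_pvalue(observed, ens.statistics, "ge")
    return OverlapResult(len(pairs), observed, fraction, p)
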