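"""Interaction tendencies with phosphoprotein-binding-domain (PPBD) proteins.

For each protein the normalized interaction probability is the fraction of
its distinct interaction partners that carry at least one PPBD (optionally
restricted to a single domain family). Averaging this per-node fraction
within the phosphoprotein and nonphosphoprotein groups normalizes away the
groups' different degree levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .degree_statistics import rank_sum
from .identifiers_io import CovariateTable
from .network import PhosphoPPI

#: The ten recognised PPBD families.
PPBD_DOMAINS = (
    "14-3-3",
    "BRCT",
    "C2",
    "FHA",
    "MH2",
    "PBD",
    "PTB",
    "SH2",
    "WD-40",
    "WW",
)


@dataclass
class PPBDComparisonRow:
    domain: str  # a PPBD family or "ALL"
    mean_phospho: float
    mean_nonphospho: float
    ranksum_p: float
    n_bearers_in_network: int


def _annotation_dict(ann) -> dict[str, set[str]]:
    entries = ann.entries if isinstance(ann, CovariateTable) else dict(ann)
    out: dict[str, set[str]] = {}
    for acc, domains in entries.items():
        doms = set(domains)
        unknown = doms - set(PPBD_DOMAINS)
        if unknown:
            raise ValueError(f"unknown PPBD tag(s) {sorted(unknown)} for {acc}")
        out[acc] = doms
    return out


def normalized_interaction_probability(
    net: PhosphoPPI,
    ann: CovariateTable | Mapping[str, set[str]],
    node: str,
    domain_filter: str = "ALL",
) -> float:
    """Fraction of a node's distinct partners bearing a passing PPBD.

    A self-edge makes the protein its own partner, consistent with the
    degree convention. ``domain_filter`` is one PPBD family or "ALL".
    """
    if domain_filter != "ALL" and domain_filter not in PPBD_DOMAINS:
        raise ValueError(f"unknown PPBD domain {domain_filter!r}")
    annotation = _annotation_dict(ann)
    partners = list(net.graph.adj[node])
    if not partners:
        raise ValueError(f"node {node!r} has no partners")
    n_hit = 0
    for p in partners:
        doms = annotation.get(p, set())
        if domain_filter == "ALL":
            n_hit += bool(doms)
        else:
            n_hit += domain_filter in doms
    return n_hit / len(partners)


def group_comparison(
    net: PhosphoPPI, ann: CovariateTable | Mapping[str, set[str]]
) -> list[PPBDComparisonRow]:
    """Mean normalized interaction probability per group, for ALL PPBDs and
    for each domain family present among network members.

    Significance is the two-sided rank-sum on the per-node probabilities.
    """
    annotation = _annotation_dict(ann)
    phospho = net.phospho_nodes
    nonphospho = net.nonphospho_nodes
    if not phospho or not nonphospho:
        raise ValueError("both groups must be nonempty")
    present = sorted(
        {d for v in net.graph.nodes for d in annotation.get(v, set())},
        key=PPBD_DOMAINS.index,
    )
    rows: list[PPBDComparisonRow] = []
    for domain in ["ALL"] + present:
        prob_p = [
            normalized_interaction_probability(net, annotation, v, domain) for v in phospho
        ]
        prob_n = [
            normalized_interaction_probability(net, annotation, v, domain)
            for v in nonphospho
        ]
        if domain == "ALL":
            n_bearers = sum(1 for v in net.graph.nodes if annotation.get(v))
        else:
            n_bearers = sum(1 for v in net.graph.nodes if domain in annotation.get(v, set()))
        rows.append(
            PPBDComparisonRow(
                domain=domain,
                mean_phospho=float(sum(prob_p) / len(prob_p)),
                mean_nonphospho=float(sum(prob_n) / len(prob_n)),
                ranksum_p=rank_sum(prob_p, prob_n),
                n_bearers_in_network=n_bearers,
            )
        )
    return rows
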