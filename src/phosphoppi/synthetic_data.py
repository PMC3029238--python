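"""Synthetic input bundles with the statistical structure the analyses assume.

The generator emulates the study conditions end to end: a scale-free PPI
grown by preferential attachment; a binary phospho label whose probability
rises with log degree (or, alternatively, labels planted assortatively in
network neighborhoods); protein abundance log-linear in degree with noise;
disorder probability shifted upward for phosphoproteins; heavy-tailed
phosphosite counts so only a minority of phosphoproteins carries two or
more sites; PPBD annotations optionally biased toward partners of
phosphoproteins; homolog pairs made by duplicating node neighborhoods; and
kinases whose substrates are either clustered in one node's closed
neighborhood (planted modules) or drawn uniformly (background).

Every bundle round-trips through the package readers, and all randomness
flows from one scenario seed via named child streams.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.special import expit

from .identifiers_io import (
    CovariateTable,
    InteractionRecord,
    PhosphoRecord,
    write_covariates,
    write_interactions,
    write_phospho,
)
from .ikm_motifs import KinaseSubstrateMap
from .network import PhosphoPPI
from .ppbd_interaction import PPBD_DOMAINS

#: Phosphoacceptor residue proportions used for synthetic sites (pS/pT/pY).
RESIDUE_PROPORTIONS = {"S": 0.72, "T": 0.23, "Y": 0.05}


@dataclass
class ScenarioConfig:
    """Knobs of the synthetic study; defaults are the reference conditions."""

    seed: int
    n_nodes: int = 2000
    attachment_m: int = 3
    method_proportions: tuple[float, float, float] = (0.4, 0.35, 0.25)  # Y2H/IMM/TAP

    # phospho labels: P(phospho | k) = expit(b0 + b1 * log10 k)
    phospho_base_rate: float = 0.0  # b0, logit scale
    phospho_degree_coupling: float = 1.0  # b1
    label_scheme: str = "degree"  # or "assortative"
    phospho_target_rate: float = 0.55  # assortative scheme only
    site_zipf_exponent: float = 2.5  # heavy-tailed phosphosite counts

    # covariates
    abundance_intercept: float = 2.5  # log10 copies/cell at k = 1
    abundance_slope: float = 0.5  # per log10 k
    abundance_noise_sd: float = 0.5
    abundance_phospho_shift: float = 0.0  # direct label->abundance confounding
    disorder_mean: float = 0.35
    disorder_sd: float = 0.2
    disorder_phospho_shift: float = 0.15
    disorder_degree_slope: float = 0.0  # per log10 k
    length_base: int = 400
    length_per_site: int = 50
    length_noise_sd: float = 100.0
    ppbd_rate: float = 0.05
    ppbd_attachment_bias: float = 0.0
    homolog_pair_count: int = 0

    # kinases
    n_kinases: int = 10  # background (uniform substrates)
    substrates_per_kinase: int = 20  # in vitro kinase maps carry tens each
    planted_kinase_count: int = 0
    planted_neighborhood_size: int = 20

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a scenario seed is mandatory")
        if not (self.n_nodes > self.attachment_m >= 1):
            raise ValueError("require n_nodes > attachment_m >= 1")
        if self.planted_kinase_count and (
            self.planted_neighborhood_size < self.substrates_per_kinase
        ):
            raise ValueError(
                "planted_neighborhood_size must cover substrates_per_kinase"
            )


#: Named presets, one per planted structure the analyses must recover.
SCENARIOS: dict[str, dict] = {
    # labels independent of everything: nominal false-positive calibration
    "null": dict(
        phospho_base_rate=0.3766,  # logit of the ~59% phosphoprotein share
        phospho_degree_coupling=0.0,
        disorder_phospho_shift=0.0,
        abundance_phospho_shift=0.0,
    ),
    # positive phospho-degree coupling (hub enrichment recovery)
    "degree_coupling": dict(phospho_base_rate=0.0, phospho_degree_coupling=1.0),
    # abundance and disorder tied to BOTH label and degree (degree is the
    # common cause, as in real interactomes); the planted coupling is set to
    # the strong, several-fold degree contrast real phospho-PPI data show,
    # and the within-bin degree gap must survive stratification
    "confounded": dict(
        phospho_base_rate=-1.2,
        phospho_degree_coupling=2.5,
        disorder_phospho_shift=0.15,
        disorder_degree_slope=0.1,
    ),
    # phospho labels clustered in network neighborhoods (edge-pattern signature)
    "assortative": dict(label_scheme="assortative", phospho_target_rate=0.55),
    # background kinases plus planted neighborhood kinases (motif power)
    "planted_kinase": dict(
        phospho_base_rate=0.0,
        phospho_degree_coupling=1.0,
        planted_kinase_count=3,
        n_kinases=10,
    ),
}


def scenario_config(name: str, seed: int, **overrides) -> ScenarioConfig:
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    params = dict(SCENARIOS[name])
    params.update(overrides)
    return ScenarioConfig(seed=seed, **params)


def _streams(cfg: ScenarioConfig) -> dict[str, np.random.Generator]:
    names = ("network", "labels", "covariates", "kinases", "homologs")
    children = np.random.SeedSequence(cfg.seed).spawn(len(names))
    return {name: np.random.default_rng(s) for name, s in zip(names, children)}


def _accession(i: int) -> str:
    return f"SYN{i:05d}"


def generate_network(cfg: ScenarioConfig, rng: np.random.Generator | None = None) -> list[InteractionRecord]:
    """Preferential-attachment PPI with random assay-method tags.

    The growth rule attaches each new node to ``attachment_m`` existing
    nodes, yielding exactly m*(n - m) edges, a connected simple graph and a
    heavy-tailed degree distribution.
    """
    rng = rng if rng is not None else _streams(cfg)["network"]
    graph = nx.barabasi_albert_graph(
        cfg.n_nodes, cfg.attachment_m, seed=int(rng.integers(2**31))
    )
    tags = ("Y2H", "IMM", "TAP")
    probs = np.asarray(cfg.method_proportions, dtype=float)
    probs = probs / probs.sum()
    choices = rng.choice(len(tags), size=graph.number_of_edges(), p=probs)
    return [
        InteractionRecord(_accession(u), _accession(v), frozenset([tags[c]]))
        for (u, v), c in zip(graph.edges, choices)
    ]


def _graph_of(net) -> nx.Graph:
    return net.graph if isinstance(net, PhosphoPPI) else net


def assign_phospho(
    net, cfg: ScenarioConfig, rng: np.random.Generator
) -> tuple[dict[str, bool], dict[str, int]]:
    """Draw phospho labels and per-phosphoprotein site counts.

    Degree scheme: P(phospho | k) = expit(b0 + b1 * log10 k). Assortative
    scheme: labels grow by randomized breadth-first spreading from a few
    seeds until the target rate is hit, so phospho nodes clump in network
    neighborhoods. Site counts are Zipf-distributed (a minority of
    phosphoproteins carries >= 2 sites).
    """
    graph = _graph_of(net)
    nodes = list(graph.nodes)
    if cfg.label_scheme == "degree":
        k = np.array([max(1, len(graph.adj[v])) for v in nodes], dtype=float)
        p = expit(cfg.phospho_base_rate + cfg.phospho_degree_coupling * np.log10(k))
        draws = rng.random(len(nodes)) < p
        labels = {v: bool(d) for v, d in zip(nodes, draws)}
    elif cfg.label_scheme == "assortative":
        target = int(round(cfg.phospho_target_rate * len(nodes)))
        labelled: set = set()
        frontier: list = []
        while len(labelled) < target:
            if not frontier:
                seed_node = nodes[int(rng.integers(len(nodes)))]
                if seed_node in labelled:
                    continue
                frontier = [seed_node]
            nxt = frontier.pop(int(rng.integers(len(frontier))))
            if nxt in labelled:
                continue
            labelled.add(nxt)
            nbrs = [w for w in graph.adj[nxt] if w not in labelled]
            frontier.extend(nbrs)
        labels = {v: v in labelled for v in nodes}
    else:
        raise ValueError(f"unknown label scheme {cfg.label_scheme!r}")
    site_counts = {
        v: (int(min(rng.zipf(cfg.site_zipf_exponent), 30)) if labels[v] else 0)
        for v in nodes
    }
    return labels, site_counts


def generate_covariates(
    net,
    labels: dict[str, bool],
    site_counts: dict[str, int],
    cfg: ScenarioConfig,
    rng: np.random.Generator,
) -> dict[str, CovariateTable]:
    """Abundance, disorder, length and PPBD tables consistent with the labels."""
    graph = _graph_of(net)
    nodes = list(graph.nodes)
    k = np.array([max(1, len(graph.adj[v])) for v in nodes], dtype=float)
    is_ph = np.array([labels[v] for v in nodes], dtype=float)

    log_ab = (
        cfg.abundance_intercept
        + cfg.abundance_slope * np.log10(k)
        + cfg.abundance_phospho_shift * is_ph
        + rng.normal(0.0, cfg.abundance_noise_sd, len(nodes))
    )
    abundance = CovariateTable("abundance")
    abundance.entries = {v: float(10.0**x) for v, x in zip(nodes, log_ab)}

    dis = np.clip(
        rng.normal(
            cfg.disorder_mean
            + cfg.disorder_phospho_shift * is_ph
            + cfg.disorder_degree_slope * np.log10(k),
            cfg.disorder_sd,
            len(nodes),
        ),
        0.0,
        1.0,
    )
    disorder = CovariateTable("disorder")
    disorder.entries = {v: float(x) for v, x in zip(nodes, dis)}

    length = CovariateTable("length")
    noise = rng.normal(0.0, cfg.length_noise_sd, len(nodes))
    length.entries = {
        v: int(max(50, round(cfg.length_base + cfg.length_per_site * site_counts[v] + e)))
        for v, e in zip(nodes, noise)
    }

    ppbd = CovariateTable("ppbd")
    for i, v in enumerate(nodes):
        partners = list(graph.adj[v])
        frac_ph = (
            sum(labels[w] for w in partners) / len(partners) if partners else 0.0
        )
        prob = min(1.0, cfg.ppbd_rate * (1.0 + cfg.ppbd_attachment_bias * frac_ph))
        if rng.random() < prob:
            n_dom = 1 + int(rng.random() < 0.2)
            ppbd.entries[v] = set(
                rng.choice(PPBD_DOMAINS, size=n_dom, replace=False).tolist()
            )
    return {"abundance": abundance, "disorder": disorder, "length": length, "ppbd": ppbd}


def duplicate_neighborhoods(
    records: list[InteractionRecord],
    n_pairs: int,
    rng: np.random.Generator,
) -> tuple[list[InteractionRecord], CovariateTable]:
    """Create homolog pairs by duplicating nodes' neighborhoods.

    Each duplicate inherits all of its template's interactions plus an edge
    to the template, and the (template, duplicate) pair is recorded as
    homologous; downstream homolog filtering should remove exactly those
    template-duplicate edges.
    """
    adjacency: dict[str, set[str]] = {}
    for rec in records:
        a, b = rec.pair
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    candidates = sorted(adjacency)
    pairs = CovariateTable("homolog_pairs")
    out = list(records)
    chosen = rng.choice(len(candidates), size=min(n_pairs, len(candidates)), replace=False)
    for ci in np.sort(chosen):
        u = candidates[int(ci)]
        dup = u + "D"
        for nbr in sorted(adjacency[u]):
            out.append(InteractionRecord(dup, nbr, frozenset(["IMM"])))
        out.append(InteractionRecord(dup, u, frozenset(["IMM"])))
        pairs.pairs.add((u, dup) if u <= dup else (dup, u))
    return out, pairs


def generate_kinases(
    net, cfg: ScenarioConfig, rng: np.random.Generator
) -> tuple[KinaseSubstrateMap, dict[str, bool]]:
    """Background kinases (uniform substrates) plus planted ones.

    A planted kinase draws its substrates from a single node's closed
    neighborhood, with the center always included, so at least s-1 of its
    substrate pairs are guaranteed network edges.
    """
    graph = _graph_of(net)
    nodes = list(graph.nodes)
    s = cfg.substrates_per_kinase
    mapping: dict[str, set[str]] = {}
    planted: dict[str, bool] = {}
    for i in range(cfg.n_kinases):
        kin = f"KINB{i:02d}"
        subs = rng.choice(len(nodes), size=s, replace=False)
        mapping[kin] = {nodes[int(j)] for j in subs}
        planted[kin] = False
    eligible = [v for v in nodes if len(graph.adj[v]) >= cfg.planted_neighborhood_size]
    for i in range(cfg.planted_kinase_count):
        if not eligible:
            raise ValueError(
                "no node has a closed neighborhood of size "
                f"{cfg.planted_neighborhood_size}"
            )
        kin = f"KINP{i:02d}"
        center = eligible[int(rng.integers(len(eligible)))]
        nbrs = sorted(graph.adj[center])
        picked = rng.choice(len(nbrs), size=s - 1, replace=False)
        mapping[kin] = {center} | {nbrs[int(j)] for j in picked}
        planted[kin] = True
    return KinaseSubstrateMap(mapping, source="synthetic"), planted


@dataclass
class Bundle:
    """A complete in-memory input bundle plus its ground truth."""

    config: ScenarioConfig
    records: list[InteractionRecord]
    phospho_records: list[PhosphoRecord]
    labels: dict[str, bool]
    site_counts: dict[str, int]
    covariates: dict[str, CovariateTable]
    homolog_pairs: CovariateTable
    kinases: KinaseSubstrateMap
    planted_kinases: dict[str, bool]
    sequences: dict[str, str] = field(default_factory=dict)

    def truth(self) -> dict:
        return {
            "config": dataclasses.asdict(self.config),
            "planted_kinases": self.planted_kinases,
            "n_phospho": sum(self.labels.values()),
            "n_nodes": len(self.labels),
        }


def _phospho_sites(
    labels: dict[str, bool],
    site_counts: dict[str, int],
    lengths: CovariateTable,
    rng: np.random.Generator,
) -> list[PhosphoRecord]:
    residues = np.array(list(RESIDUE_PROPORTIONS))
    probs = np.array(list(RESIDUE_PROPORTIONS.values()))
    out: list[PhosphoRecord] = []
    for v in sorted(labels):
        n_sites = site_counts[v]
        if not n_sites:
            continue
        length = int(lengths.entries.get(v, 400))
        n_sites = min(n_sites, length)
        positions = rng.choice(length, size=n_sites, replace=False) + 1
        res = rng.choice(residues, size=n_sites, p=probs)
        source_flags = rng.random(n_sites)
        for pos, r, f in zip(positions, res, source_flags):
            # split sites across two pseudo-sources; ~20% seen by both
            srcs = ["srcA"] if f < 0.45 else (["srcB"] if f < 0.8 else ["srcA", "srcB"])
            for src in srcs:
                out.append(PhosphoRecord(v, int(pos), str(r), src))
    return out


def generate_bundle(cfg: ScenarioConfig) -> Bundle:
    """Run every generator stage under named child streams of the seed."""
    streams = _streams(cfg)
    records = generate_network(cfg, streams["network"])
    if cfg.homolog_pair_count:
        records, homolog = duplicate_neighborhoods(
            records, cfg.homolog_pair_count, streams["homologs"]
        )
    else:
        homolog = CovariateTable("homolog_pairs")
    graph = nx.Graph()
    for rec in records:
        graph.add_edge(*rec.pair)
    labels, site_counts = assign_phospho(graph, cfg, streams["labels"])
    covariates = generate_covariates(
        graph, labels, site_counts, cfg, streams["covariates"]
    )
    phospho_records = _phospho_sites(
        labels, site_counts, covariates["length"], streams["labels"]
    )
    kinases, planted = generate_kinases(graph, cfg, streams["kinases"])
    return Bundle(
        config=cfg,
        records=records,
        phospho_records=phospho_records,
        labels=labels,
        site_counts=site_counts,
        covariates=covariates,
        homolog_pairs=homolog,
        kinases=kinases,
        planted_kinases=planted,
    )


def write_bundle(bundle: Bundle, out_dir: str | Path) -> dict[str, Path]:
    """Emit the bundle in the package's TSV dialects plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactions": out / "interactions.tsv",
        "phospho": out / "phospho.tsv",
        "homolog_pairs": out / "homolog_pairs.tsv",
        "kinases": out / "kinases.tsv",
        "truth": out / "truth.json",
    }
    write_interactions(bundle.records, paths["interactions"])
    write_phospho(bundle.phospho_records, paths["phospho"])
    write_covariates(bundle.homolog_pairs, paths["homolog_pairs"])
    for kind, table in bundle.covariates.items():
        paths[kind] = out / f"{kind}.tsv"
        write_covariates(table, paths[kind])
    with open(paths["kinases"], "w", encoding="utf-8") as fh:
        fh.write("kinase\tsubstrate\n")
        for kin in sorted(bundle.kinases.mapping):
            for sub in sorted(bundle.kinases.mapping[kin]):
                fh.write(f"{kin}\t{sub}\n")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(bundle.truth(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
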