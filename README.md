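# phosphoppi

Integrative analysis of a phosphoproteome overlaid on a protein–protein
interaction (PPI) network.

High-throughput mass spectrometry has shown that more than half of a yeast
proteome can be phosphorylated, far more proteins than classical signaling
accounts for. `phosphoppi` is for systems biologists who want to ask what
that large-scale phosphorylation does to the *interactome*: it annotates an
undirected PPI network with phosphorylation status ("phospho-PPI"), then
quantifies how phosphoproteins and nonphosphoproteins differ — in partner
counts, in binding to phosphoprotein-binding-domain (PPBD) proteins, in the
phosphorylation patterns of interacting pairs, and in kinase–substrate
triangle motifs — with all significance judged against two bespoke network
null models.

## The statistics at the core

For a node group *G* (phosphoproteins P or nonphosphoproteins N), the
reverse cumulative degree curve is

  *P*≥(*k*) = |{v ∈ G : deg(v) ≥ k}| / |G|,

compared directly as the **P/N ratio** and against expectation as the
**O/E ratio**, where E is the mean phosphoprotein curve over an ensemble of
null networks. Two null schemes are used:

* **NLS (node label shuffling)** — node identities are permuted uniformly
  over a fixed topology, destroying every association between a protein's
  annotations and its network position;
* **RER (random edge rewiring)** — degree-preserving double-edge swaps
  ((a,b),(c,d) → (a,d),(c,b)), rejecting self-loops and duplicate edges, so
  any result that survives RER cannot be an artifact of degree.

Significance is the empirical tail probability *p* = #{null ≥ observed}/N
(reported as "< 1/N" when zero). Confounding by protein abundance, disorder
or length is addressed by stratified bins with two-sided
Wilcoxon–Mann–Whitney rank-sum tests on within-bin degrees, and an
**IKM** (interacting kinate module — a kinase plus two of its substrates
that interact physically) is called significant only when its count beats
*both* nulls at the 0.05 level.

A fully parameterised synthetic-data generator produces input bundles with
the statistical structure the analyses assume (scale-free network, degree-
coupled phospho labels, degree-driven abundance, label-shifted disorder,
planted kinase neighborhoods), so every stage runs and is validated without
external downloads.

## Worked example

```python
import phosphoppi as ppi
from phosphoppi import synthetic_data as syn

cfg = syn.scenario_config("degree_coupling", seed=7, n_nodes=1000)
bundle = syn.generate_bundle(cfg)
phospho = {v for v, is_p in bundle.labels.items() if is_p}
net = ppi.build(bundle.records, phospho, "ALL")
print("network:", net.summary())

p = ppi.degree_curve(net, "phospho"); n = ppi.degree_curve(net, "nonphospho")
print(f"P>=(10): phospho {p.at(10):.3f}  nonphospho {n.at(10):.3f}  P/N {ppi.pn_ratio(p, n)[10]:.2f}")

row = next(r for r in ppi.oe_analysis(net, 1000, seed=1) if r.k == 10)
print(f"O/E at k=10: {row.oe:.2f}  (expected {row.expected_mean:.3f}, p {row.p_two_sided:g}, {row.stars})")
```

prints

```
network: {'category': 'ALL', 'filtered': False, 'n_nodes': 1000, 'n_edges': 2991,
          'n_phospho': 673, 'phospho_percent': 67.3}
P>=(10): phospho 0.125  nonphospho 0.061  P/N 2.04
O/E at k=10: 1.20  (expected 0.104, p 0.002, **)
```

The scenario plants a positive phospho–degree coupling: twice the share of
phosphoproteins reaches 10 partners (P/N 2.04), and the phosphoprotein tail
exceeds its label-shuffled expectation (O/E 1.20) with empirical p = 0.002
over 1,000 NLS replicas. On the same network, `ppi.pattern_significance`
reports the Both/Either/Neither edge counts against 1,000 RER replicas —
here none deviates, as degree coupling alone does not make labels
assortative along edges.

The same pipeline runs from the shell:

```sh
phosphoppi simulate --scenario degree_coupling --seed 7 --out bundle/
phosphoppi all --bundle bundle/ --out report/ --null-n 1000 --seed 1
```

writing per-analysis TSVs, `summary.json` and a log with the resolved
configuration. Scenario presets: `null` (calibration), `degree_coupling`,
`confounded`, `assortative`, `planted_kinase`.

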