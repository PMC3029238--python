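# Methods

## The phospho-PPI model

The package treats a proteome as an undirected simple graph whose nodes are
proteins (canonical UniProt-style accessions) and whose edges are physical
interactions, optionally restricted to one assay category (yeast two-hybrid
Y2H, co-immunoprecipitation IMM, tandem affinity purification TAP, or ALL).
Each node carries a binary phosphoprotein label: present in the unified
phosphosite catalog or not. "Nonphosphoprotein" therefore means *no site
identified to date*, not non-phosphorylatable — the label is a detection
outcome, and several analyses exist precisely to ask whether detection
covariates (abundance, disorder, length) explain away the label's network
correlates.

Conventions that the data sources leave open and that we fix as contracts:

* **Binary interactions only.** Records listing three or more interactors
  (one bait, several preys) are rejected at parse time and counted; the
  pair (a, b) is unordered.
* **Degree** is the number of distinct interaction partners; a self-edge
  contributes one partner (the protein itself), not two stubs. Nodes exist
  only through edges, so degree 0 cannot occur and log10(degree) is always
  defined.
* **Homolog filtering** removes every edge whose endpoints form a
  precomputed homologous pair (sequence-similar at a stringent E-value
  threshold, supplied as input) plus all self-edges; nodes isolated by the
  removal are dropped.
* **Identifier standardization** maps every accession through a
  synonym→canonical table before integration; unmapped accessions pass
  through with a warning count rather than an error, and standardization is
  idempotent.
* **Site unification** unions phosphosites over sources on (accession,
  position). Residue conflicts at a position are resolved by majority, ties
  by a declared source-priority order (first source listed wins by
  default). Per-source provenance is retained so novelty counts stay
  answerable.

## Null models

**Node label shuffling (NLS).** Node identities are permuted uniformly at
random over the fixed topology: each protein keeps its own annotations but
occupies a random network position. We draw the permutation directly
(Fisher–Yates) rather than by an explicit chain of random transpositions:
the transposition walk mixes in O(n log n) steps, orders of magnitude below
the customary cap of 1,000·|E| swaps, so the uniform permutation *is* the
distribution that capped chain samples. This choice also makes small-graph
behaviour exact (e.g. on a star K1,3 with one phosphoprotein, the label
occupies the hub position with probability exactly 1/4).

**Random edge rewiring (RER).** A Markov chain of double-edge swaps:
pick two edges (a,b), (c,d), rewire to (a,d),(c,b) or (a,c),(b,d) with
equal probability, and reject any move that would create a self-loop or a
duplicate edge. Every node's degree is exactly invariant. Self-edges in the
input are frozen out of the swap pool and preserved. The chain stops when
the current edge set shares no pair with the original or when the budget
`multiplier × |E|` is exhausted; proposals count against the budget whether
accepted or retried (configurable). The default multiplier is 1,000 (the
conventional cap); the analyses and tests run at multiplier 10, which on
the graphs used here already leaves < 5% of original pairs in place (the
practical decorrelation criterion) at a fraction of the cost. The swap loop
runs in a numba-compiled kernel with adjacency-matrix membership tests when
numba is importable and the graph has ≤ 20,000 nodes; a pure-Python chain
with identical semantics is the reference implementation and fallback.

**Empirical p-values** follow the raw-proportion definition
p = #{null ≥ observed}/N (or ≤ for the low side), reported with N so a zero
proportion renders as "< 1/N"; the add-one variant (r+1)/(N+1) is carried
as metadata but plays no role in significance calls. Replicate r of an
ensemble draws its generator from the r-th spawn of the seed's
SeedSequence, making ensembles reproducible bit-for-bit given (scheme, N,
seed) and independent of execution order.

## Degree statistics

The reverse cumulative curve P≥(k) is computed for k = 1..max degree; the
P/N ratio divides group curves pointwise (absent where the denominator is
zero). The O/E analysis compares the observed phosphoprotein curve with its
NLS expectation; because NLS makes the phospho group a uniformly random
position set of fixed size, replicate curves are drawn directly as random
degree subsets. Per degree level we report the replicate mean (E), 2.5th
and 97.5th percentile bounds of the replicate curves (these bracket E; the
corresponding O/E-scale interval is observed/ci_high .. observed/ci_low),
one-sided tail proportions, and a two-sided p (twice the smaller tail,
capped at 1) mapped to tiers at 0.05/0.01/0.001.

Stratified comparisons slice a scalar covariate (log10 abundance, disorder
probability, or length) into half-open bins [start, start+width) anchored
at the covariate floor rounded down to a multiple of the width; each bin
reports group counts, the mean and s.e.m. (sample SD/√n) of log10 degree
per group, and a two-sided rank-sum p on the raw degrees. The rank-sum test
uses the exact permutation distribution when the smaller group has ≤ 8
values and the pooled sample is tie-free, and the tie-corrected normal
approximation without continuity correction otherwise (so balanced samples
give exactly p = 1; a zero-variance degenerate pooled sample returns 1).
ROC curves for phosphoprotein predictors sweep all distinct score
thresholds (prediction = score ≥ threshold) and integrate by trapezoid,
which equals pairwise concordance with ties counted 1/2.

Edge phosphorylation patterns classify every non-self edge as Both, Either
or Neither phosphorylated endpoints; self-edges are excluded (a single
protein is not two interacting proteins) but reported. Pattern significance
uses RER only, so the verdict is independent of the groups' degree
difference. PPBD analysis uses the per-node normalized interaction
probability — the fraction of a protein's distinct partners bearing at
least one phosphoprotein-binding domain (14-3-3, BRCT, C2, FHA, MH2, PBD,
PTB, SH2, WD-40, WW), optionally one family — averaged within groups; no
additional degree matching is performed beyond this per-node
normalization. IKM analysis counts, per kinase, the substrate pairs that
are network edges (the kinase itself need not be a network node; its edges
come from the kinase–substrate table); autophosphorylation entries are
dropped, kinases need ≥ 2 substrates in the network, and a kinase is
significant only when its count beats both the NLS and the RER ensemble at
0.05. Signaling/PPI overlap counts reaction pairs present as edges,
direction ignored.

## The synthetic-data generator

The generator emulates the structure of the study inputs, not their
content. One scenario seed feeds named child streams (network, labels,
covariates, kinases, homologs), so bundles are reproducible end to end.

* **Network**: preferential attachment with m = 3 edges per new node
  (mean degree ≈ 6, matching curated yeast interactomes), n = 2,000 nodes
  by default; exactly m(n−m) edges, connected, heavy-tailed degrees. Assay
  tags are drawn per edge (40/35/25% Y2H/IMM/TAP by default).
* **Labels**: P(phospho | k) = logistic(b0 + b1·log10 k). The null preset
  sets b1 = 0 with b0 = logit(0.593), reproducing the observed ~59%
  phosphoprotein share; the coupling preset uses b0 = 0, b1 = 1. The
  assortative preset instead grows label clumps by randomized
  breadth-first spreading to a 55% target rate, making labels cluster in
  neighborhoods. Phosphoprotein site counts are Zipf(2.5), so a minority
  carries ≥ 2 sites; synthetic residues follow the canonical 72/23/5
  pS/pT/pY proportions.
* **Covariates**: log10 abundance = 2.5 + 0.5·log10 k + N(0, 0.5) —
  degree-driven with noise, no direct label term, so abundance correlates
  with phosphorylation only through degree; disorder = clipped
  N(0.35 + 0.15·phospho (+ slope·log10 k in the confounded preset), 0.2);
  length tracks site count; PPBD tags are assigned at a 5% base rate,
  optionally biased toward partners of phosphoproteins; homolog pairs
  duplicate a node's neighborhood (plus an edge to the template).
* **Kinases**: 10 background kinases draw 20 substrates uniformly (in
  vitro substrate maps carry tens of substrates per kinase); planted
  kinases draw a hub plus 19 of its neighbors, so at least s−1 substrate
  pairs are guaranteed edges.
* **Confounded preset**: b0 = −1.2, b1 = 2.5 (~60% phospho rate). The
  planted coupling is deliberately strong — of the order of the
  several-fold degree contrast real phospho-PPI data display — because the
  scenario exists to test that stratification *preserves* a real
  within-bin gap, and conditioning on a degree-correlated covariate
  necessarily shrinks it.

What the generator does **not** emulate: real sequence content, protein
complexes and their shared-bait artifacts, assay-specific false-positive
structure, correlated multi-source detection bias, duplication-divergence
evolution. Passing recovery tests therefore shows the estimators detect the
planted effects under the stated model, not that the biological claims hold
for any particular real dataset.

## Problem sizes and numerical choices

Analyses and tests run at desk scale: null ensembles of N = 100–1,000
(configurable; conventions in the field use up to 10,000), networks of
400–2,000 nodes, 20-replicate recovery suites, and a 100-dataset
calibration suite; each check states its sizes and computes exact binomial
calibration bands for the trial counts actually used. The RER budget is
10·|E| proposals per replicate in these runs (see above). Percentile
confidence bounds use linear-interpolation percentiles; residue percentage
summaries round to integers; phosphoprotein shares round to 0.1%.

Known limitations:

* Empirical p-values on *small discrete* statistics are conservative: for
  IKM counts with null expectation of order 1, P(p < α) sits well below α,
  so the IKM false-positive rate falls below, not at, the nominal level —
  the joint both-nulls rule compounds this. The degree-curve and pattern
  statistics are effectively continuous and calibrate at nominal rates.
* RER treats the observed graph as exchangeable with uniform simple graphs
  of the same degree sequence; residual structure (e.g. clustering in
  growth models) is not part of the null.
* The NLS O/E analysis conditions on group sizes; it does not model
  uncertainty in the phospho labels themselves.
* Published supplementary tables (the unified catalog and the
  gene-annotation list) are consumed from TSV exports when present; the
  two checks that need them fail cleanly when the files are absent.
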