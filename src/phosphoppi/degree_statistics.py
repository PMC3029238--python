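"""Degree-distribution comparisons between phosphoproteins and
nonphosphoproteins.

The central object is the reverse cumulative degree curve P>=(k): the
proportion of a group's proteins with at least k interaction partners.
Group curves are compared directly (P/N ratio), against the node-label-
shuffling null (O/E ratio with percentile confidence bounds and empirical
significance tiers), and within strata of a confounding covariate
(abundance, disorder, length) using two-sided Wilcoxon-Mann-Whitney
rank-sum tests on the per-protein degrees.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .identifiers_io import CovariateTable
from .network import PhosphoPPI
from .null_models import child_rngs, stars as p_stars


@dataclass
class DegreeCurve:
    """Reverse cumulative degree distribution of one node group."""

    k_values: np.ndarray  # ascending 1..k_max
    p_ge: np.ndarray  # P>=(k), non-increasing, p_ge[0] == 1
    group_size: int

    def at(self, k: int) -> float:
        """P>=(k); 1 below the smallest k, 0 above the largest."""
        if k < self.k_values[0]:
            return 1.0
        if k > self.k_values[-1]:
            return 0.0
        return float(self.p_ge[k - self.k_values[0]])


@dataclass
class OERow:
    """Observed vs NLS-expected phosphoprotein P>=(k) at one degree level."""

    k: int
    observed: float
    expected_mean: float
    ci_low: float  # 2.5th percentile of replicate expected curves
    ci_high: float  # 97.5th percentile
    oe: float
    oe_ci_low: float
    oe_ci_high: float
    p_ge: float  # one-sided: fraction of replicate curves >= observed
    p_le: float
    p_two_sided: float
    stars: str


@dataclass
class StratifiedBin:
    """Within-bin group comparison of log10 degree."""

    bin_start: float
    bin_width: float
    n_phospho: int
    n_nonphospho: int
    mean_log10_k_phospho: float
    mean_log10_k_nonphospho: float
    sem_log10_k_phospho: float
    sem_log10_k_nonphospho: float
    ranksum_p: float


@dataclass
class RocCurve:
    """ROC points (1-specificity, sensitivity) over all score thresholds."""

    points: list[tuple[float, float]]
    auc: float


def curve_from_degrees(
    degrees: Sequence[int], k_max: int | None = None
) -> DegreeCurve:
    degrees = np.asarray(list(degrees), dtype=np.int64)
    if degrees.size == 0:
        raise ValueError("cannot build a degree curve from an empty group")
    if k_max is None:
        k_max = int(degrees.max())
    counts = np.bincount(degrees, minlength=k_max + 1)[: k_max + 1]
    # number with degree >= k, k = 1..k_max
    ge = np.cumsum(counts[::-1])[::-1]
    p_ge = ge[1:] / degrees.size
    return DegreeCurve(np.arange(1, k_max + 1), p_ge, int(degrees.size))


def degree_curve(net: PhosphoPPI, group: str) -> DegreeCurve:
    """P>=(k) for k = 1..max network degree within the given group."""
    members = net.group_nodes(group)
    if not members:
        raise ValueError(f"group {group!r} is empty in this network")
    k_max = max(len(net.graph.adj[v]) for v in net.graph.nodes)
    return curve_from_degrees([net.degree(v) for v in members], k_max)


def pn_ratio(p_curve: DegreeCurve, n_curve: DegreeCurve) -> dict[int, float]:
    """Phospho over nonphospho P>=(k); k absent where the denominator is 0."""
    out: dict[int, float] = {}
    for k in p_curve.k_values:
        denom = n_curve.at(int(k))
        if denom > 0:
            out[int(k)] = p_curve.at(int(k)) / denom
    return out


def oe_analysis(
    net: PhosphoPPI, n_replicates: int, seed: int, ci: bool = True
) -> list[OERow]:
    """Observed phosphoprotein P>=(k) against the NLS expectation.

    Under node label shuffling the phosphoprotein group occupies a uniformly
    random set of network positions of its original size, so the replicate
    curves are computed directly from random degree subsets. The expected
    curve is the per-k replicate mean; confidence bounds are 2.5th/97.5th
    percentiles; significance tiers come from the two-sided empirical tail
    proportion of the observed value within the replicate distribution.
    """
    if ci and n_replicates < 100:
        raise ValueError("CI reporting requires n_replicates >= 100")
    observed = degree_curve(net, "phospho")
    degrees = np.array([net.degree(v) for v in net.graph.nodes], dtype=np.int64)
    n_p = observed.group_size
    k_max = int(observed.k_values[-1])
    reps = np.empty((n_replicates, k_max), dtype=float)
    for i, rng in enumerate(child_rngs(seed, n_replicates)):
        idx = rng.permutation(degrees.size)[:n_p]
        counts = np.bincount(degrees[idx], minlength=k_max + 1)[: k_max + 1]
        reps[i] = np.cumsum(counts[::-1])[::-1][1:] / n_p
    exp_mean = reps.mean(axis=0)
    lo = np.percentile(reps, 2.5, axis=0)
    hi = np.percentile(reps, 97.5, axis=0)
    rows: list[OERow] = []
    for j, k in enumerate(range(1, k_max + 1)):
        obs = observed.p_ge[j]
        col = reps[:, j]
        ge = float(np.mean(col >= obs))
        le = float(np.mean(col <= obs))
        p2 = min(1.0, 2.0 * min(ge, le))
        em = exp_mean[j]
        rows.append(
            OERow(
                k=k,
                observed=float(obs),
                expected_mean=float(em),
                ci_low=float(lo[j]),
                ci_high=float(hi[j]),
                oe=float(obs / em) if em > 0 else math.nan,
                oe_ci_low=float(obs / hi[j]) if hi[j] > 0 else math.nan,
                oe_ci_high=float(obs / lo[j]) if lo[j] > 0 else math.nan,
                p_ge=ge,
                p_le=le,
                p_two_sided=p2,
                stars=p_stars(p2),
            )
        )
    return rows


def rank_sum(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value.

    Exact null distribution when the smaller sample has <= 8 values and the
    pooled data carry no ties; the tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_sum requires two nonempty groups")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if min(a.size, b.size) <= 8 and no_ties:
        p = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
    else:
        # no continuity correction so that balanced samples give exactly p=1
        p = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        ).pvalue
    if math.isnan(p):  # degenerate: zero rank variance (all values tied)
        return 1.0
    return float(p)


def stratified_comparison(
    net: PhosphoPPI,
    table: CovariateTable,
    transform: str = "log10",
    bin_width: float = 0.5,
) -> list[StratifiedBin]:
    """Group degree comparison within half-open covariate bins.

    The covariate (optionally log10-transformed, e.g. raw abundance) is
    sliced into bins [start, start + width) anchored at the covariate floor
    rounded down to a multiple of the width. Each bin reports group counts,
    the mean and s.e.m. of log10(degree) per group, and the two-sided
    rank-sum p on the raw degree values (only when both groups are present).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if transform not in ("log10", "identity"):
        raise ValueError(f"transform must be 'log10' or 'identity', got {transform!r}")
    values: dict[str, float] = {}
    for v in net.graph.nodes:
        if v in table.entries:
            x = float(table.entries[v])
            values[v] = math.log10(x) if transform == "log10" else x
    if not values:
        raise ValueError("no network node is covered by the covariate table")
    vmin = min(values.values())
    anchor = math.floor(vmin / bin_width) * bin_width
    bins: dict[int, tuple[list[int], list[int]]] = {}
    for v, x in values.items():
        idx = int(math.floor((x - anchor) / bin_width))
        ph, nph = bins.setdefault(idx, ([], []))
        (ph if net.is_phospho(v) else nph).append(net.degree(v))
    rows: list[StratifiedBin] = []
    for idx in sorted(bins):
        ph, nph = bins[idx]

        def _mean_sem(vals: list[int]) -> tuple[float, float]:
            if not vals:
                return math.nan, math.nan
            logk = np.log10(np.asarray(vals, dtype=float))
            mean = float(logk.mean())
            sem = float(logk.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else math.nan
            return mean, sem

        mp, sp = _mean_sem(ph)
        mn, sn = _mean_sem(nph)
        p = rank_sum(ph, nph) if ph and nph else math.nan
        rows.append(
            StratifiedBin(
                bin_start=anchor + idx * bin_width,
                bin_width=bin_width,
                n_phospho=len(ph),
                n_nonphospho=len(nph),
                mean_log10_k_phospho=mp,
                mean_log10_k_nonphospho=mn,
                sem_log10_k_phospho=sp,
                sem_log10_k_nonphospho=sn,
                ranksum_p=p,
            )
        )
    return rows


def multisite_curves(net: PhosphoPPI, phospho_set) -> dict[str, DegreeCurve | None]:
    """Degree curves for nonphosphoproteins, single-site and multi-site
    phosphoproteins. An empty group yields None rather than an error."""
    k_max = max(len(net.graph.adj[v]) for v in net.graph.nodes)
    groups: dict[str, list[int]] = {"nonphospho": [], "single_site": [], "multi_site": []}
    for v in net.graph.nodes:
        if not net.is_phospho(v):
            groups["nonphospho"].append(net.degree(v))
        elif phospho_set.site_count(v) >= 2:
            groups["multi_site"].append(net.degree(v))
        else:
            groups["single_site"].append(net.degree(v))
    return {
        name: curve_from_degrees(deg, k_max) if deg else None
        for name, deg in groups.items()
    }


def _roc(scores: Mapping[str, float], labels: Mapping[str, bool]) -> RocCurve:
    nodes = list(scores)
    y = np.array([bool(labels[v]) for v in nodes])
    s = np.array([float(scores[v]) for v in nodes])
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    points: list[tuple[float, float]] = []
    for thr in sorted(set(s), reverse=True):
        pred = s >= thr
        tpr = float((pred & y).sum() / n_pos)
        fpr = float((pred & ~y).sum() / n_neg)
        points.append((fpr, tpr))
    xs = [0.0] + [p[0] for p in points]
    ys = [0.0] + [p[1] for p in points]
    if xs[-1] != 1.0 or ys[-1] != 1.0:
        xs.append(1.0)
        ys.append(1.0)
    auc = float(np.trapezoid(ys, xs))
    return RocCurve(points, auc)


def roc_compare(
    scores_a: Mapping[str, float],
    scores_b: Mapping[str, float],
    labels: Mapping[str, bool],
) -> tuple[RocCurve, RocCurve]:
    """ROC curves of two phosphoprotein predictors over the same node set.

    At each distinct score threshold, sensitivity is the fraction of
    phosphoproteins scoring at/above it and 1-specificity the fraction of
    nonphosphoproteins doing so; the area is computed by the trapezoid rule.
    """
    if set(scores_a) != set(scores_b):
        raise ValueError("both score maps must cover the same node set")
    lab = {v: bool(labels[v]) for v in scores_a}
    n_pos = sum(lab.values())
    if n_pos == 0 or n_pos == len(lab):
        raise ValueError("ROC comparison requires both label classes")
    return _roc(scores_a, lab), _roc(scores_b, lab)
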