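"""Merge phosphoproteome datasets into one nonredundant protein/site catalog.

Sites from all sources are unioned on (canonical accession, position). When
two sources disagree about the residue letter at the same position, the
majority residue wins; ties fall back to a declared source-priority order.
A "nonphosphoprotein" downstream is simply any network protein absent from
the unified catalog — absence of evidence, not evidence of absence.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .identifiers_io import AccessionMap, PhosphoRecord, standardize


@dataclass
class UnifiedPhosphoSet:
    """Nonredundant phosphoprotein/phosphosite catalog.

    proteins: accession -> set of (position, residue)
    per_source: source tag -> set of (accession, position)
    """

    proteins: dict[str, set[tuple[int, str]]] = field(default_factory=dict)
    per_source: dict[str, set[tuple[str, int]]] = field(default_factory=dict)

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_sites(self) -> int:
        return sum(len(sites) for sites in self.proteins.values())

    @property
    def residue_counts(self) -> Counter:
        counts: Counter = Counter()
        for sites in self.proteins.values():
            counts.update(res for _, res in sites)
        return counts

    def site_count(self, accession: str) -> int:
        return len(self.proteins.get(accession, ()))

    def __contains__(self, accession: str) -> bool:
        return accession in self.proteins

    def novel_in(self, source: str) -> tuple[int, int]:
        """(proteins, sites) seen in `source` and in no other source."""
        others_sites: set[tuple[str, int]] = set()
        others_prots: set[str] = set()
        for src, sites in self.per_source.items():
            if src != source:
                others_sites.update(sites)
                others_prots.update(acc for acc, _ in sites)
        own = self.per_source.get(source, set())
        novel_sites = {s for s in own if s not in others_sites}
        novel_prots = {acc for acc, _ in own} - others_prots
        return len(novel_prots), len(novel_sites)


@dataclass
class ValidationReport:
    """Site-vs-sequence consistency flags (counts only; nothing is deleted)."""

    n_checked: int
    out_of_range: list[tuple[str, int, str]]
    residue_mismatch: list[tuple[str, int, str]]

    @property
    def n_flagged(self) -> int:
        return len(self.out_of_range) + len(self.residue_mismatch)


def unify(
    sources: Sequence[Sequence[PhosphoRecord]],
    amap: AccessionMap | None = None,
    source_priority: Sequence[str] | None = None,
) -> UnifiedPhosphoSet:
    """Union phosphosite records from several sources into one catalog.

    ``source_priority`` breaks residue-conflict ties (earlier wins); by
    default sources are ranked in the order given (first list first).
    """
    if not sources:
        raise ValueError("unify requires at least one source record list")
    flat: list[PhosphoRecord] = []
    order: list[str] = []
    for records in sources:
        recs = list(records)
        if amap is not None:
            recs = standardize(recs, amap).records
        for rec in recs:
            flat.append(rec)
            if rec.source not in order:
                order.append(rec.source)
    priority = list(source_priority) if source_priority is not None else order
    rank = {src: i for i, src in enumerate(priority)}

    # residue votes per (accession, position)
    votes: dict[tuple[str, int], Counter] = {}
    best_rank: dict[tuple[str, int, str], int] = {}
    per_source: dict[str, set[tuple[str, int]]] = {}
    for rec in flat:
        key = (rec.accession, rec.site_position)
        votes.setdefault(key, Counter())[rec.residue] += 1
        rkey = (rec.accession, rec.site_position, rec.residue)
        r = rank.get(rec.source, len(rank))
        best_rank[rkey] = min(best_rank.get(rkey, r), r)
        per_source.setdefault(rec.source, set()).add(key)

    unified = UnifiedPhosphoSet(per_source=per_source)
    for (acc, pos), counter in votes.items():
        top = counter.most_common()
        best_count = top[0][1]
        tied = [res for res, c in top if c == best_count]
        if len(tied) == 1:
            residue = tied[0]
        else:
            residue = min(tied, key=lambda res: (best_rank[(acc, pos, res)], res))
        unified.proteins.setdefault(acc, set()).add((pos, residue))
    return unified


def validate_sites(
    unified: UnifiedPhosphoSet, sequences: Mapping[str, str]
) -> ValidationReport:
    """Flag sites inconsistent with protein sequences (overlap only checked)."""
    out_of_range: list[tuple[str, int, str]] = []
    mismatch: list[tuple[str, int, str]] = []
    n_checked = 0
    for acc, sites in unified.proteins.items():
        seq = sequences.get(acc)
        if seq is None:
            continue
        for pos, res in sites:
            n_checked += 1
            if pos > len(seq):
                out_of_range.append((acc, pos, res))
            elif seq[pos - 1] != res:
                mismatch.append((acc, pos, res))
    return ValidationReport(n_checked, out_of_range, mismatch)


def summarize(unified: UnifiedPhosphoSet) -> dict:
    """Protein/site counts, integer residue percentages, novelty, site-count
    distribution."""
    if not unified.proteins:
        raise ValueError("cannot summarize an empty phospho catalog")
    res_counts = unified.residue_counts
    total = sum(res_counts.values())
    residue_percent = {
        res: round(100.0 * res_counts.get(res, 0) / total) for res in "STY"
    }
    novelty = {src: unified.novel_in(src) for src in unified.per_source}
    dist = Counter(len(sites) for sites in unified.proteins.values())
    return {
        "n_proteins": unified.n_proteins,
        "n_sites": unified.n_sites,
        "residue_percent": residue_percent,
        "novel_per_source": {
            src: {"proteins": p, "sites": s} for src, (p, s) in novelty.items()
        },
        "sites_per_protein": dict(sorted(dist.items())),
    }


def write_unified(unified: UnifiedPhosphoSet, path: str | Path) -> None:
    """Write the catalog as phospho TSV with a ``sources`` column."""
    source_of: dict[tuple[str, int], list[str]] = {}
    for src, sites in unified.per_source.items():
        for key in sites:
            source_of.setdefault(key, []).append(src)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("accession\tposition\tresidue\tsources\n")
        for acc in sorted(unified.proteins):
            for pos, res in sorted(unified.proteins[acc]):
                srcs = ";".join(sorted(source_of.get((acc, pos), [])))
                fh.write(f"{acc}\t{pos}\t{res}\t{srcs}\n")


def write_summary(summary: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_catalog_tsv(path: str | Path) -> UnifiedPhosphoSet:
    """Load a previously unified catalog (or any phospho TSV) directly.

    Intended for externally supplied catalog exports; each row's ``sources``
    column (if present) is split on ";" to rebuild provenance.
    """
    from .identifiers_io import _iter_tsv  # shared dialect

    unified = UnifiedPhosphoSet()
    for lineno, parts in _iter_tsv(path):
        if parts[0].lower() == "accession":
            continue
        acc, pos, res = parts[0], int(parts[1]), parts[2]
        unified.proteins.setdefault(acc, set()).add((pos, res))
        srcs = parts[3].split(";") if len(parts) > 3 and parts[3] else [""]
        for src in srcs:
            unified.per_source.setdefault(src, set()).add((acc, pos))
    return unified
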