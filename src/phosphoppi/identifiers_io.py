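"""Readers, writers and accession standardization.

Every upstream data source (interaction lists, phosphosite tables, covariate
tables, kinase-substrate maps) is read here and normalised to canonical
UniProt-style accessions before any integration step. Interaction files come
either as plain tab-separated edge lists or as a reduced two-interactor XML
dialect (only participant accessions and one detection-method string per entry
are read; anything else in the element tree is ignored).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

#: Assay categories used to stratify interaction data.
METHOD_TAGS = ("Y2H", "IMM", "TAP", "other")

#: Default mapping from free-text detection-method strings to category tags.
DEFAULT_METHOD_MAP: dict[str, str] = {
    "y2h": "Y2H",
    "two hybrid": "Y2H",
    "two-hybrid": "Y2H",
    "yeast two-hybrid": "Y2H",
    "imm": "IMM",
    "coip": "IMM",
    "coimmunoprecipitation": "IMM",
    "co-immunoprecipitation": "IMM",
    "immunoprecipitation": "IMM",
    "tap": "TAP",
    "tandem affinity purification": "TAP",
}

PHOSPHO_RESIDUES = frozenset("STY")

COVARIATE_KINDS = ("abundance", "disorder", "length", "go_slim", "ppbd", "homolog_pairs")
_SCALAR_KINDS = ("abundance", "disorder", "length")
_TERM_KINDS = ("go_slim", "ppbd")


class ParseError(ValueError):
    """Malformed input with a locator for the offending line or element."""


@dataclass(frozen=True)
class InteractionRecord:
    """One binary physical interaction with its assay-category tags.

    The pair is unordered: records (a, b) and (b, a) compare equal and merge
    to a single edge downstream.
    """

    interactor_a: str
    interactor_b: str
    methods: frozenset[str] = frozenset()

    @property
    def pair(self) -> tuple[str, str]:
        """Canonical (sorted) endpoint pair."""
        a, b = self.interactor_a, self.interactor_b
        return (a, b) if a <= b else (b, a)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionRecord):
            return NotImplemented
        return self.pair == other.pair and self.methods == other.methods

    def __hash__(self) -> int:
        return hash((self.pair, self.methods))


@dataclass(frozen=True)
class PhosphoRecord:
    """A single phosphosite observation from one source dataset."""

    accession: str
    site_position: int
    residue: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.site_position < 1:
            raise ValueError(f"site_position must be >= 1, got {self.site_position}")
        if self.residue not in PHOSPHO_RESIDUES:
            raise ValueError(f"residue must be one of S/T/Y, got {self.residue!r}")


@dataclass
class CovariateTable:
    """Typed per-protein covariate values.

    ``entries`` maps accession -> scalar (abundance/disorder/length) or term
    set (go_slim/ppbd). For kind ``homolog_pairs`` the data live in ``pairs``
    as a set of sorted accession 2-tuples and ``entries`` stays empty.
    """

    kind: str
    entries: dict = field(default_factory=dict)
    pairs: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.kind not in COVARIATE_KINDS:
            raise ValueError(f"unknown covariate kind {self.kind!r}")

    def __contains__(self, accession: str) -> bool:
        return accession in self.entries

    def __len__(self) -> int:
        return len(self.pairs) if self.kind == "homolog_pairs" else len(self.entries)


class AccessionMap:
    """Synonym -> canonical accession mapping.

    Every canonical accession maps to itself; a synonym maps to exactly one
    canonical entry group. Lookups of unregistered accessions return the
    accession unchanged (callers count these as warnings, not errors).
    """

    def __init__(self, mapping: Mapping[str, str] | None = None):
        self._map: dict[str, str] = {}
        if mapping:
            for syn, canon in mapping.items():
                self.add(syn, canon)

    def add(self, synonym: str, canonical: str) -> None:
        synonym = synonym.strip()
        canonical = canonical.strip()
        existing = self._map.get(synonym)
        if existing is not None and existing != canonical:
            raise ValueError(
                f"synonym {synonym!r} already maps to {existing!r}, cannot remap to {canonical!r}"
            )
        self._map[synonym] = canonical
        self._map.setdefault(canonical, canonical)

    def canonical(self, accession: str) -> str:
        return self._map.get(accession, accession)

    def is_registered(self, accession: str) -> bool:
        return accession in self._map

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AccessionMap":
        """Read a two-column ``synonym<TAB>canonical`` table."""
        amap = cls()
        for lineno, parts in _iter_tsv(path):
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            amap.add(parts[0], parts[1])
        return amap


@dataclass
class ParseResult:
    """Records plus the parse log demanded of interaction readers."""

    records: list[InteractionRecord]
    n_rejected_nary: int = 0
    warnings: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


class StandardizeResult(NamedTuple):
    records: object
    n_unmapped: int


def _iter_tsv(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    """Yield (lineno, fields) for non-empty, non-comment lines."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, [p.strip() for p in line.split("\t")]


def _map_method(raw: str, method_map: Mapping[str, str], warnings: list[str]) -> str:
    tag = method_map.get(raw.strip().lower(), method_map.get(raw.strip()))
    if tag is None:
        if raw.strip() in METHOD_TAGS:
            return raw.strip()
        warnings.append(f"unknown method string {raw!r}, tagged 'other'")
        return "other"
    return tag


def read_interactions(
    path: str | Path,
    format: str = "tsv",
    method_map: Mapping[str, str] | None = None,
) -> ParseResult:
    """Read binary interaction records from a TSV edge list or reduced XML.

    Entries with three or more interactors (bait with multiple preys in one
    assay) are rejected and counted in the parse log; only two-interactor
    entries become records. Method strings are mapped to category tags via
    ``method_map`` (unknown strings tag as "other" with a warning).
    """
    method_map = dict(DEFAULT_METHOD_MAP if method_map is None else method_map)
    if format == "tsv":
        return _read_interactions_tsv(path, method_map)
    if format == "dip_xml":
        return _read_interactions_xml(path, method_map)
    raise ValueError(f"unknown interaction format {format!r}")


def _read_interactions_tsv(path: str | Path, method_map: Mapping[str, str]) -> ParseResult:
    records: list[InteractionRecord] = []
    warnings: list[str] = []
    n_nary = 0
    header_skipped = False
    for lineno, parts in _iter_tsv(path):
        if not header_skipped:
            header_skipped = True
            if parts[0].lower() in ("protein_a", "interactor_a", "accession_a"):
                continue
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected >= 2 columns, got {len(parts)}")
        # n-ary entries arrive as pipe-joined interactor groups
        groups = [p.split("|") for p in parts[:2]]
        n_interactors = sum(len(g) for g in groups)
        if n_interactors > 2:
            n_nary += 1
            continue
        a, b = groups[0][0], groups[1][0]
        if not a or not b:
            raise ParseError(f"{path}:{lineno}: empty interactor accession")
        methods = frozenset(
            _map_method(m, method_map, warnings)
            for m in (parts[2].split(";") if len(parts) > 2 and parts[2] else [])
        )
        records.append(InteractionRecord(a, b, methods))
    return ParseResult(records, n_nary, warnings)


def _read_interactions_xml(path: str | Path, method_map: Mapping[str, str]) -> ParseResult:
    """Reduced two-interactor XML dialect.

    Recognised structure (namespaces ignored)::

        <interactionList>
          <interaction>
            <participant accession="P1"/>
            <participant accession="P2"/>
            <method>two hybrid</method>
          </interaction>
          ...
        </interactionList>

    A participant's accession may also be element text. Everything else is
    skipped; entries with >= 3 participants are rejected and counted.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"{path}: XML parse failure: {exc}") from exc
    records: list[InteractionRecord] = []
    warnings: list[str] = []
    n_nary = 0
    for elem in tree.iter():
        if etree.QName(elem).localname != "interaction":
            continue
        participants = []
        method_raw = None
        for child in elem.iter():
            local = etree.QName(child).localname
            if local == "participant":
                acc = child.get("accession") or (child.text or "").strip()
                if not acc:
                    raise ParseError(
                        f"{path}: interaction at line {elem.sourceline}: "
                        "participant without accession"
                    )
                participants.append(acc.strip())
            elif local == "method" and method_raw is None:
                method_raw = (child.text or "").strip()
        if len(participants) != 2:
            n_nary += 1
            continue
        methods = (
            frozenset([_map_method(method_raw, method_map, warnings)])
            if method_raw
            else frozenset()
        )
        records.append(InteractionRecord(participants[0], participants[1], methods))
    return ParseResult(records, n_nary, warnings)


def write_interactions(records: Iterable[InteractionRecord], path: str | Path) -> None:
    """Write records as ``protein_a<TAB>protein_b<TAB>method`` (";"-joined tags)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\tmethod\n")
        for rec in records:
            fh.write(
                f"{rec.interactor_a}\t{rec.interactor_b}\t"
                f"{';'.join(sorted(rec.methods))}\n"
            )


def read_phospho(path: str | Path, source: str | None = None) -> list[PhosphoRecord]:
    """Read ``accession<TAB>position<TAB>residue[<TAB>source]`` phosphosite rows."""
    records: list[PhosphoRecord] = []
    for lineno, parts in _iter_tsv(path):
        if parts[0].lower() == "accession":
            continue
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
        try:
            pos = int(parts[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer position {parts[1]!r}") from exc
        src = parts[3] if len(parts) > 3 else (source or "")
        try:
            records.append(PhosphoRecord(parts[0], pos, parts[2], src))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_phospho(records: Iterable[PhosphoRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("accession\tposition\tresidue\tsource\n")
        for rec in records:
            fh.write(f"{rec.accession}\t{rec.site_position}\t{rec.residue}\t{rec.source}\n")


def read_covariates(path: str | Path, kind: str) -> CovariateTable:
    """Read a covariate table of the given kind.

    Scalar kinds expect ``accession<TAB>value`` (disorder must lie in [0, 1],
    abundance must be positive, length a positive integer); term kinds expect
    ``accession<TAB>term;term``; homolog_pairs expects two accession columns.
    Duplicate accessions keep the first occurrence with a warning.
    """
    table = CovariateTable(kind)
    n_dup = 0
    for lineno, parts in _iter_tsv(path):
        if parts[0].lower() in ("accession", "accession_a"):
            continue
        if kind == "homolog_pairs":
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 accessions")
            a, b = parts[0], parts[1]
            table.pairs.add((a, b) if a <= b else (b, a))
            continue
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        acc = parts[0]
        if acc in table.entries:
            n_dup += 1
            continue
        if kind in _TERM_KINDS:
            table.entries[acc] = {t.strip() for t in parts[1].split(";") if t.strip()}
        else:
            try:
                value = float(parts[1])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric {kind} value {parts[1]!r}"
                ) from exc
            if kind == "disorder" and not 0.0 <= value <= 1.0:
                raise ParseError(f"{path}:{lineno}: disorder value {value} outside [0, 1]")
            if kind == "abundance" and value <= 0:
                raise ParseError(f"{path}:{lineno}: abundance value {value} must be positive")
            if kind == "length":
                if value <= 0 or value != int(value):
                    raise ParseError(f"{path}:{lineno}: length must be a positive integer")
                value = int(value)
            table.entries[acc] = value
    if n_dup:
        logger.warning("%s: %d duplicate accessions dropped (first kept)", path, n_dup)
    return table


def write_covariates(table: CovariateTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if table.kind == "homolog_pairs":
            fh.write("accession_a\taccession_b\n")
            for a, b in sorted(table.pairs):
                fh.write(f"{a}\t{b}\n")
            return
        fh.write("accession\tvalue\n")
        for acc in sorted(table.entries):
            val = table.entries[acc]
            if isinstance(val, (set, frozenset)):
                val = ";".join(sorted(val))
            fh.write(f"{acc}\t{val}\n")


def read_kinase_map(path: str | Path) -> dict[str, set[str]]:
    """Read ``kinase<TAB>substrate`` rows into kinase -> substrate-set."""
    mapping: dict[str, set[str]] = {}
    for lineno, parts in _iter_tsv(path):
        if parts[0].lower() == "kinase":
            continue
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected kinase and substrate columns")
        mapping.setdefault(parts[0], set()).add(parts[1])
    return mapping


def standardize(records, amap: AccessionMap) -> StandardizeResult:
    """Replace every accession by its canonical form.

    Accepts a list of InteractionRecord or PhosphoRecord, a CovariateTable,
    or a kinase mapping (dict of str -> set). Unmapped accessions pass through
    unchanged and are tallied in ``n_unmapped``. The operation is idempotent.
    """
    unmapped: Counter[str] = Counter()

    def canon(acc: str) -> str:
        if amap.is_registered(acc):
            return amap.canonical(acc)
        unmapped[acc] += 1
        return acc

    if isinstance(records, CovariateTable):
        out = CovariateTable(records.kind)
        for acc, val in records.entries.items():
            out.entries.setdefault(canon(acc), val)
        for a, b in records.pairs:
            ca, cb = canon(a), canon(b)
            out.pairs.add((ca, cb) if ca <= cb else (cb, ca))
        result: object = out
    elif isinstance(records, dict):
        out_map: dict[str, set[str]] = {}
        for kin, subs in records.items():
            out_map.setdefault(canon(kin), set()).update(canon(s) for s in subs)
        result = out_map
    else:
        out_list = []
        for rec in records:
            if isinstance(rec, InteractionRecord):
                out_list.append(
                    InteractionRecord(
                        canon(rec.interactor_a), canon(rec.interactor_b), rec.methods
                    )
                )
            elif isinstance(rec, PhosphoRecord):
                out_list.append(
                    PhosphoRecord(canon(rec.accession), rec.site_position, rec.residue, rec.source)
                )
            else:
                raise TypeError(f"cannot standardize record of type {type(rec).__name__}")
        result = out_list
    n_unmapped = sum(unmapped.values())
    if n_unmapped:
        logger.warning("standardize: %d accessions had no registered synonym", n_unmapped)
    return StandardizeResult(result, n_unmapped)
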