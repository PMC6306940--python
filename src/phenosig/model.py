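"""Core domain types and delimited-text readers/writers.

Tables are plain UTF-8 delimited text in one of three dialects
(``dollar``, ``tab``, ``comma``).  Multi-valued fields use ``;`` as the
intra-field separator.  Dates are ISO-8601 calendar dates; an empty date
field means "no date reported".
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

__all__ = [
    "OUTCOME_CODES",
    "DIALECTS",
    "CaseReport",
    "PhenotypeTerm",
    "PhenotypeHierarchy",
    "DrugConcept",
    "TargetLink",
    "ProteinAnnotation",
    "RejectedRow",
    "ReadReport",
    "read_cases",
    "write_cases",
    "read_hierarchy",
    "write_hierarchy",
    "read_dictionary",
    "write_dictionary",
    "read_links",
    "write_links",
    "read_protein_annotations",
    "write_protein_annotations",
]

#: The closed set of clinical outcome codes (death, life-threatening,
#: hospitalization, disability, congenital anomaly, required intervention,
#: other).
OUTCOME_CODES: frozenset[str] = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

#: Supported field delimiters by dialect name.
DIALECTS: Mapping[str, str] = {"dollar": "$", "tab": "\t", "comma": ","}

_INTRA = ";"

MIN_LEVEL = 1
MAX_LEVEL = 4


class DataError(ValueError):
    """Raised for structurally invalid input tables."""


@dataclass(frozen=True)
class CaseReport:
    """One de-identified adverse-event case report."""

    case_id: str
    report_date: Optional[date]
    drug_mentions: tuple[str, ...]
    indications: frozenset[str]
    reactions: frozenset[str]
    outcomes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.case_id:
            raise DataError("case_id must be non-empty")
        bad = self.outcomes - OUTCOME_CODES
        if bad:
            raise DataError(f"unknown outcome code(s) {sorted(bad)} in case {self.case_id}")


@dataclass(frozen=True)
class PhenotypeTerm:
    """A term in the 4-level phenotype hierarchy (1 broadest, 4 most specific)."""

    term_id: str
    name: str
    level: int
    parent_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not MIN_LEVEL <= self.level <= MAX_LEVEL:
            raise DataError(f"term {self.term_id!r}: level must be in [1, 4], got {self.level}")
        if self.level == MIN_LEVEL and self.parent_id is not None:
            raise DataError(f"level-1 term {self.term_id!r} must not have a parent")
        if self.level > MIN_LEVEL and not self.parent_id:
            raise DataError(f"term {self.term_id!r} at level {self.level} requires a parent")


class PhenotypeHierarchy:
    """A validated 4-level term tree.

    Every non-root term's parent must exist and sit exactly one level above
    it, which also rules out cycles.
    """

    def __init__(self, terms: Iterable[PhenotypeTerm]):
        self._terms: dict[str, PhenotypeTerm] = {}
        for t in terms:
            if t.term_id in self._terms:
                raise DataError(f"duplicate term_id {t.term_id!r}")
            self._terms[t.term_id] = t
        for t in self._terms.values():
            if t.parent_id is None:
                continue
            parent = self._terms.get(t.parent_id)
            if parent is None:
                raise DataError(f"term {t.term_id!r}: parent {t.parent_id!r} not in hierarchy")
            if parent.level != t.level - 1:
                raise DataError(
                    f"term {t.term_id!r} (level {t.level}) has parent "
                    f"{t.parent_id!r} at level {parent.level}; expected level {t.level - 1}"
                )

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def __getitem__(self, term_id: str) -> PhenotypeTerm:
        try:
            return self._terms[term_id]
        except KeyError:
            raise KeyError(f"unknown term {term_id!r}") from None

    def __iter__(self) -> Iterator[PhenotypeTerm]:
        return iter(self._terms.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhenotypeHierarchy):
            return NotImplemented
        return self._terms == other._terms

    def terms_at_level(self, level: int) -> list[PhenotypeTerm]:
        return [t for t in self._terms.values() if t.level == level]

    def ancestor_at_level(self, term_id: str, level: int) -> str:
        """Return the id of the unique ancestor of ``term_id`` at ``level``.

        A term is its own ancestor at its own level.  Asking for a level
        deeper than the term's own is an error.
        """
        term = self[term_id]
        if not MIN_LEVEL <= level <= MAX_LEVEL:
            raise ValueError(f"level must be in [1, 4], got {level}")
        if level > term.level:
            raise ValueError(
                f"term {term_id!r} is at level {term.level}; cannot descend to level {level}"
            )
        while term.level > level:
            term = self[term.parent_id]  # type: ignore[arg-type]
        return term.term_id


@dataclass(frozen=True)
class DrugConcept:
    """A normalized drug with its synonym set and ATC class codes."""

    drug_id: str
    canonical_name: str
    synonyms: frozenset[str]
    atc_codes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.synonyms:
            raise DataError(f"drug {self.drug_id!r}: synonyms must be non-empty")
        if self.canonical_name not in self.synonyms:
            raise DataError(f"drug {self.drug_id!r}: canonical name must be among synonyms")


LINK_ROLES = frozenset({"target", "enzyme", "carrier", "transporter"})
LINK_ACTIONS = frozenset({"agonist", "antagonist", "unknown"})


@dataclass(frozen=True)
class TargetLink:
    """One drug→protein relation with its role and pharmacologic action."""

    drug_id: str
    protein_id: str
    role: str
    action: str = "unknown"

    def __post_init__(self) -> None:
        if self.role not in LINK_ROLES:
            raise DataError(f"unknown link role {self.role!r}")
        if self.action not in LINK_ACTIONS:
            raise DataError(f"unknown link action {self.action!r}")


@dataclass(frozen=True)
class ProteinAnnotation:
    protein_id: str
    gene_symbol: str
    pathway_ids: frozenset[str] = frozenset()


@dataclass(frozen=True)
class RejectedRow:
    line_number: int
    reason: str
    raw: str


@dataclass
class ReadReport:
    """Bookkeeping for rows that could not be turned into records."""

    rejected: list[RejectedRow] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def _delimiter(dialect: str) -> str:
    try:
        return DIALECTS[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}") from None


def _split_multi(value: str) -> list[str]:
    return [v for v in (p.strip() for p in value.split(_INTRA)) if v]


CASE_COLUMNS = ["case_id", "report_date", "drug_mentions", "indications", "reactions", "outcomes"]


def read_cases(
    path: str | Path,
    dialect: str = "tab",
    hierarchy: Optional[PhenotypeHierarchy] = None,
) -> tuple[list[CaseReport], ReadReport]:
    """Read a case table; unparseable rows go to the returned report.

    A duplicate ``case_id`` is always an error (the corpus invariant), as
    is an indication/reaction term absent from ``hierarchy`` when one is
    supplied.
    """
    delim = _delimiter(dialect)
    cases: list[CaseReport] = []
    report = ReadReport()
    seen: set[str] = set()
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != CASE_COLUMNS:
            raise DataError(f"case table must have columns {CASE_COLUMNS}, got {reader.fieldnames}")
        for lineno, row in enumerate(reader, start=2):
            raw = delim.join((row.get(c) or "") for c in CASE_COLUMNS)
            cid = (row.get("case_id") or "").strip()
            if not cid:
                report.rejected.append(RejectedRow(lineno, "missing case_id", raw))
                continue
            if cid in seen:
                raise DataError(f"duplicate case_id {cid!r} at line {lineno}")
            try:
                raw_date = (row.get("report_date") or "").strip()
                rdate = date.fromisoformat(raw_date) if raw_date else None
                case = CaseReport(
                    case_id=cid,
                    report_date=rdate,
                    drug_mentions=tuple(_split_multi(row.get("drug_mentions") or "")),
                    indications=frozenset(_split_multi(row.get("indications") or "")),
                    reactions=frozenset(_split_multi(row.get("reactions") or "")),
                    outcomes=frozenset(_split_multi(row.get("outcomes") or "")),
                )
            except (DataError, ValueError) as exc:
                report.rejected.append(RejectedRow(lineno, str(exc), raw))
                continue
            if hierarchy is not None:
                missing = [t for t in (case.indications | case.reactions) if t not in hierarchy]
                if missing:
                    report.rejected.append(
                        RejectedRow(lineno, f"unknown term(s) {sorted(missing)}", raw)
                    )
                    continue
            seen.add(cid)
            cases.append(case)
    return cases, report


def write_cases(cases: Iterable[CaseReport], path: str | Path, dialect: str = "tab") -> None:
    delim = _delimiter(dialect)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(CASE_COLUMNS)
        for c in cases:
            writer.writerow(
                [
                    c.case_id,
                    c.report_date.isoformat() if c.report_date else "",
                    _INTRA.join(c.drug_mentions),
                    _INTRA.join(sorted(c.indications)),
                    _INTRA.join(sorted(c.reactions)),
                    _INTRA.join(sorted(c.outcomes)),
                ]
            )


HIERARCHY_COLUMNS = ["term_id", "name", "level", "parent_id"]


def read_hierarchy(path: str | Path, dialect: str = "tab") -> PhenotypeHierarchy:
    delim = _delimiter(dialect)
    terms: list[PhenotypeTerm] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != HIERARCHY_COLUMNS:
            raise DataError(
                f"hierarchy table must have columns {HIERARCHY_COLUMNS}, got {reader.fieldnames}"
            )
        for row in reader:
            parent = (row.get("parent_id") or "").strip() or None
            terms.append(
                PhenotypeTerm(
                    term_id=(row.get("term_id") or "").strip(),
                    name=(row.get("name") or "").strip(),
                    level=int(row["level"]),
                    parent_id=parent,
                )
            )
    return PhenotypeHierarchy(terms)


def write_hierarchy(hierarchy: PhenotypeHierarchy, path: str | Path, dialect: str = "tab") -> None:
    delim = _delimiter(dialect)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(HIERARCHY_COLUMNS)
        for t in sorted(hierarchy, key=lambda t: (t.level, t.term_id)):
            writer.writerow([t.term_id, t.name, t.level, t.parent_id or ""])


DICTIONARY_COLUMNS = ["drug_id", "canonical_name", "synonym", "atc_codes"]


def read_dictionary(path: str | Path, dialect: str = "tab") -> dict[str, DrugConcept]:
    """Read a one-row-per-synonym drug dictionary into DrugConcepts."""
    delim = _delimiter(dialect)
    canon: dict[str, str] = {}
    syns: dict[str, set[str]] = {}
    atc: dict[str, set[str]] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != DICTIONARY_COLUMNS:
            raise DataError(
                f"dictionary table must have columns {DICTIONARY_COLUMNS}, got {reader.fieldnames}"
            )
        for row in reader:
            did = (row.get("drug_id") or "").strip()
            if not did:
                raise DataError("dictionary row with empty drug_id")
            cname = (row.get("canonical_name") or "").strip()
            prior = canon.setdefault(did, cname)
            if prior != cname:
                raise DataError(f"drug {did!r}: conflicting canonical names {prior!r} vs {cname!r}")
            syns.setdefault(did, set()).add((row.get("synonym") or "").strip())
            atc.setdefault(did, set()).update(_split_multi(row.get("atc_codes") or ""))
    return {
        did: DrugConcept(
            drug_id=did,
            canonical_name=canon[did],
            synonyms=frozenset(s for s in syns[did] | {canon[did]} if s),
            atc_codes=frozenset(atc[did]),
        )
        for did in canon
    }


def write_dictionary(concepts: Mapping[str, DrugConcept], path: str | Path, dialect: str = "tab") -> None:
    delim = _delimiter(dialect)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(DICTIONARY_COLUMNS)
        for did in sorted(concepts):
            c = concepts[did]
            codes = _INTRA.join(sorted(c.atc_codes))
            for syn in sorted(c.synonyms):
                writer.writerow([c.drug_id, c.canonical_name, syn, codes])


LINK_COLUMNS = ["drug_id", "protein_id", "role", "action"]


def read_links(path: str | Path, dialect: str = "tab") -> list[TargetLink]:
    delim = _delimiter(dialect)
    links: list[TargetLink] = []
    seen: set[tuple[str, str, str]] = set()
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != LINK_COLUMNS:
            raise DataError(f"link table must have columns {LINK_COLUMNS}, got {reader.fieldnames}")
        for row in reader:
            link = TargetLink(
                drug_id=(row.get("drug_id") or "").strip(),
                protein_id=(row.get("protein_id") or "").strip(),
                role=(row.get("role") or "").strip(),
                action=(row.get("action") or "").strip() or "unknown",
            )
            key = (link.drug_id, link.protein_id, link.role)
            if key in seen:
                raise DataError(f"duplicate link {key}")
            seen.add(key)
            links.append(link)
    return links


def write_links(links: Iterable[TargetLink], path: str | Path, dialect: str = "tab") -> None:
    delim = _delimiter(dialect)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(LINK_COLUMNS)
        for l in links:
            writer.writerow([l.drug_id, l.protein_id, l.role, l.action])


ANNOTATION_COLUMNS = ["protein_id", "gene_symbol", "pathway_ids"]


def read_protein_annotations(path: str | Path, dialect: str = "tab") -> dict[str, ProteinAnnotation]:
    delim = _delimiter(dialect)
    out: dict[str, ProteinAnnotation] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != ANNOTATION_COLUMNS:
            raise DataError(
                f"annotation table must have columns {ANNOTATION_COLUMNS}, got {reader.fieldnames}"
            )
        for row in reader:
            pid = (row.get("protein_id") or "").strip()
            if pid in out:
                raise DataError(f"duplicate protein_id {pid!r}")
            out[pid] = ProteinAnnotation(
                protein_id=pid,
                gene_symbol=(row.get("gene_symbol") or "").strip(),
                pathway_ids=frozenset(_split_multi(row.get("pathway_ids") or "")),
            )
    return out


def write_protein_annotations(
    annotations: Mapping[str, ProteinAnnotation], path: str | Path, dialect: str = "tab"
) -> None:
    delim = _delimiter(dialect)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(ANNOTATION_COLUMNS)
        for pid in sorted(annotations):
            a = annotations[pid]
            writer.writerow([a.protein_id, a.gene_symbol, _INTRA.join(sorted(a.pathway_ids))])
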