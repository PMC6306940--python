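"""Expansion of mapped drugs to molecular annotations and cohort carving.

Exposure is case-level presence: a case counts as exposed to a protein,
pathway or ATC class when any of its mapped drugs links to it.  No dose,
duration or suspect/concomitant weighting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Optional, Sequence

from .mapping import MappedCase
from .model import (
    DrugConcept,
    PhenotypeHierarchy,
    ProteinAnnotation,
    TargetLink,
)

__all__ = [
    "AnnotatedCase",
    "CohortSpec",
    "annotate_cases",
    "clean_targets",
    "slice_by_date",
    "select_cohort",
]


@dataclass(frozen=True)
class AnnotatedCase:
    """A mapped case expanded to its molecular entity sets."""

    mapped: MappedCase
    drug_ids: frozenset[str]
    target_ids: frozenset[str]
    enzyme_ids: frozenset[str]
    carrier_ids: frozenset[str]
    transporter_ids: frozenset[str]
    pathway_ids: frozenset[str]
    atc_classes: frozenset[str]
    #: per-target set of pharmacologic actions observed in this case
    target_actions: Mapping[str, frozenset[str]] = field(default_factory=dict)

    @property
    def case_id(self) -> str:
        return self.mapped.case.case_id

    @property
    def report_date(self) -> Optional[date]:
        return self.mapped.case.report_date

    @property
    def indications(self) -> frozenset[str]:
        return self.mapped.case.indications

    @property
    def reactions(self) -> frozenset[str]:
        return self.mapped.case.reactions

    @property
    def outcomes(self) -> frozenset[str]:
        return self.mapped.case.outcomes


def annotate_cases(
    mapped_corpus: Sequence[MappedCase],
    links: Sequence[TargetLink],
    annotations: Optional[Mapping[str, ProteinAnnotation]] = None,
    concepts: Optional[Mapping[str, DrugConcept]] = None,
) -> list[AnnotatedCase]:
    """Expand each case's mapped drugs to targets, enzymes, carriers,
    transporters, pathways and ATC classes.

    Cases with zero mapped drugs keep empty molecular sets but stay in the
    corpus: they still populate the c/d cells of contingency tables.  A
    link referencing a drug absent from ``concepts`` is an error.
    """
    if concepts is not None:
        unknown = sorted({l.drug_id for l in links} - set(concepts))
        if unknown:
            raise ValueError(f"link table references unknown drug_id(s): {unknown}")
    by_drug: dict[str, dict[str, set[str]]] = {}
    actions_by_drug: dict[str, dict[str, set[str]]] = {}
    for l in links:
        by_drug.setdefault(l.drug_id, {}).setdefault(l.role, set()).add(l.protein_id)
        if l.role == "target":
            actions_by_drug.setdefault(l.drug_id, {}).setdefault(l.protein_id, set()).add(l.action)
    out: list[AnnotatedCase] = []
    for mc in mapped_corpus:
        roles: dict[str, set[str]] = {r: set() for r in ("target", "enzyme", "carrier", "transporter")}
        pathways: set[str] = set()
        atc: set[str] = set()
        actions: dict[str, set[str]] = {}
        for did in mc.drug_ids:
            for role, pids in by_drug.get(did, {}).items():
                roles[role] |= pids
            for pid, acts in actions_by_drug.get(did, {}).items():
                actions.setdefault(pid, set()).update(acts)
            if concepts is not None and did in concepts:
                atc |= concepts[did].atc_codes
        if annotations is not None:
            for pid in roles["target"]:
                ann = annotations.get(pid)
                if ann is not None:
                    pathways |= ann.pathway_ids
        out.append(
            AnnotatedCase(
                mapped=mc,
                drug_ids=mc.drug_ids,
                target_ids=frozenset(roles["target"]),
                enzyme_ids=frozenset(roles["enzyme"]),
                carrier_ids=frozenset(roles["carrier"]),
                transporter_ids=frozenset(roles["transporter"]),
                pathway_ids=frozenset(pathways),
                atc_classes=frozenset(atc),
                target_actions={p: frozenset(a) for p, a in actions.items()},
            )
        )
    return out


def clean_targets(links: Iterable[TargetLink]) -> frozenset[str]:
    """Proteins listed only with role=target, never as enzyme, carrier or
    transporter of any drug."""
    targets: set[str] = set()
    other: set[str] = set()
    for l in links:
        (targets if l.role == "target" else other).add(l.protein_id)
    return frozenset(targets - other)


def slice_by_date(corpus: Sequence[AnnotatedCase], cutoff: date) -> list[AnnotatedCase]:
    """Keep cases reported strictly before ``cutoff``; dateless cases drop."""
    return [c for c in corpus if c.report_date is not None and c.report_date < cutoff]


@dataclass(frozen=True)
class CohortSpec:
    """Declarative cohort membership criteria (all set criteria are ANDed)."""

    indication_term: Optional[str] = None
    indication_level: Optional[int] = None
    atc_prefix: Optional[str] = None
    atc_present: bool = True
    target_id: Optional[str] = None
    target_present: bool = True
    action: Optional[str] = None
    date_from: Optional[date] = None
    date_to: Optional[date] = None

    def __post_init__(self) -> None:
        if not any(
            v is not None
            for v in (self.indication_term, self.atc_prefix, self.target_id,
                      self.date_from, self.date_to)
        ):
            raise ValueError("CohortSpec requires at least one criterion")
        if self.indication_term is not None and self.indication_level is None:
            raise ValueError("indication_term requires indication_level")
        if self.action is not None and self.target_id is None:
            raise ValueError("action filter requires target_id")


def _matches(case: AnnotatedCase, spec: CohortSpec, hierarchy: Optional[PhenotypeHierarchy]) -> bool:
    if spec.indication_term is not None:
        assert hierarchy is not None
        hit = False
        for term in case.indications:
            if term not in hierarchy:
                continue
            if hierarchy[term].level < spec.indication_level:
                continue
            if hierarchy.ancestor_at_level(term, spec.indication_level) == spec.indication_term:
                hit = True
                break
        if not hit:
            return False
    if spec.atc_prefix is not None:
        present = any(code.startswith(spec.atc_prefix) for code in case.atc_classes)
        if present != spec.atc_present:
            return False
    if spec.target_id is not None:
        present = spec.target_id in case.target_ids
        if spec.action is not None:
            present = present and spec.action in case.target_actions.get(spec.target_id, frozenset())
        if present != spec.target_present:
            return False
    if spec.date_from is not None or spec.date_to is not None:
        d = case.report_date
        if d is None:
            return False
        if spec.date_from is not None and d < spec.date_from:
            return False
        if spec.date_to is not None and d >= spec.date_to:
            return False
    return True


def select_cohort(
    corpus: Sequence[AnnotatedCase],
    spec: CohortSpec,
    hierarchy: Optional[PhenotypeHierarchy] = None,
) -> tuple[list[AnnotatedCase], list[AnnotatedCase]]:
    """Partition a corpus into (in-cohort, complement).

    The partition is exact: every case lands in exactly one side.
    """
    if spec.indication_term is not None:
        if hierarchy is None:
            raise ValueError("indication criterion requires a hierarchy")
        if spec.indication_term not in hierarchy:
            raise KeyError(f"unknown indication term {spec.indication_term!r}")
        if hierarchy[spec.indication_term].level != spec.indication_level:
            raise ValueError(
                f"term {spec.indication_term!r} is at level "
                f"{hierarchy[spec.indication_term].level}, not {spec.indication_level}"
            )
    ins: list[AnnotatedCase] = []
    outs: list[AnnotatedCase] = []
    for case in corpus:
        (ins if _matches(case, spec, hierarchy) else outs).append(case)
    return ins, outs
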