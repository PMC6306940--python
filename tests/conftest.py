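from __future__ import annotations

from datetime import date
from functools import lru_cache
from typing import Optional

import pytest

from phenosig.integrate import AnnotatedCase
from phenosig.mapping import MappedCase
from phenosig.model import CaseReport, PhenotypeHierarchy, PhenotypeTerm


@pytest.fixture
def toy_hierarchy() -> PhenotypeHierarchy:
    """1 root, 2 level-2, 4 level-3, 8 level-4; one level-3 branch mirrors
    a cluster of near-synonymous coronary terms."""
    terms = [
        PhenotypeTerm("L1_CARD", "cardiac disorders", 1),
        PhenotypeTerm("L2_CORO", "coronary artery disorders", 2, "L1_CARD"),
        PhenotypeTerm("L2_ARRH", "rate and rhythm disorders", 2, "L1_CARD"),
        PhenotypeTerm("L3_CAD", "coronary occlusive events", 3, "L2_CORO"),
        PhenotypeTerm("L3_ISCH", "ischaemic conditions", 3, "L2_CORO"),
        PhenotypeTerm("L3_TACH", "tachyarrhythmias", 3, "L2_ARRH"),
        PhenotypeTerm("L3_BRAD", "bradyarrhythmias", 3, "L2_ARRH"),
        PhenotypeTerm("L4_CAD_DIS", "coronary artery disease", 4, "L3_CAD"),
        PhenotypeTerm("L4_CAD_THR", "coronary artery thrombosis", 4, "L3_CAD"),
        PhenotypeTerm("L4_CAD_RES", "coronary artery restenosis", 4, "L3_CAD"),
        PhenotypeTerm("L4_ANGINA", "angina pectoris", 4, "L3_ISCH"),
        PhenotypeTerm("L4_MI", "myocardial infarction", 4, "L3_ISCH"),
        PhenotypeTerm("L4_SVT", "supraventricular tachycardia", 4, "L3_TACH"),
        PhenotypeTerm("L4_VT", "ventricular tachycardia", 4, "L3_TACH"),
        PhenotypeTerm("L4_SB", "sinus bradycardia", 4, "L3_BRAD"),
    ]
    return PhenotypeHierarchy(terms)


def make_annotated(
    case_id: str,
    *,
    drugs=(),
    targets=(),
    enzymes=(),
    carriers=(),
    transporters=(),
    pathways=(),
    atc=(),
    reactions=(),
    indications=(),
    outcomes=(),
    report_date: Optional[date] = None,
    target_actions: Optional[dict] = None,
) -> AnnotatedCase:
    """Directly assemble an AnnotatedCase, bypassing mapping/annotation."""
    case = CaseReport(
        case_id=case_id,
        report_date=report_date,
        drug_mentions=tuple(drugs),
        indications=frozenset(indications),
        reactions=frozenset(reactions),
        outcomes=frozenset(outcomes),
    )
    mapped = MappedCase(case=case, results=(), drug_ids=frozenset(drugs))
    return AnnotatedCase(
        mapped=mapped,
        drug_ids=frozenset(drugs),
        target_ids=frozenset(targets),
        enzyme_ids=frozenset(enzymes),
        carrier_ids=frozenset(carriers),
        transporter_ids=frozenset(transporters),
        pathway_ids=frozenset(pathways),
        atc_classes=frozenset(atc),
        target_actions={k: frozenset(v) for k, v in (target_actions or {}).items()},
    )


def oracle_levenshtein(s: str, t: str) -> int:
    """Independent recursive edit-distance oracle (memoized)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        cost = 0 if s[i - 1] == t[j - 1] else 1
        return min(rec(i - 1, j) + 1, rec(i, j - 1) + 1, rec(i - 1, j - 1) + cost)

    return rec(len(s), len(t))
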