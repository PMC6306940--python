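"""Disproportionality statistics over annotated case corpora.

The 2x2 contingency table for an (entity, event) pair counts cases:

====================  =========  ============
                      event      no event
====================  =========  ============
entity present        a          b
entity absent         c          d
====================  =========  ============

PRR = a(c+d) / (c(a+b)), identically the ratio of the two reporting
proportions [a/(a+b)] / [c/(c+d)].  Significance is Fisher's exact test;
multiplicity is handled with Benjamini-Hochberg q-values (Storey's pi0
estimate available behind a flag).  q-values are always computed within a
single profile/screen call, never across calls — running the same pair in
a differently scoped screen therefore changes its q, by design.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .integrate import AnnotatedCase
from .model import OUTCOME_CODES, PhenotypeHierarchy

__all__ = [
    "ContingencyTable",
    "SignalFilter",
    "SignalRecord",
    "build_contingency",
    "prr",
    "fisher_exact",
    "qvalues",
    "profile_entity",
    "screen_all",
    "mechanism_profiles",
    "records_to_frame",
]

ENTITY_KINDS = ("drug", "target", "atc_class", "pathway")
EVENT_KINDS = ("reaction", "indication", "outcome")

# below this table total the exact-arithmetic Fisher path is used
_EXACT_FISHER_N = 2000


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class SignalFilter:
    """Thresholds deciding which associations count as flagged signals."""

    min_entity_support: int = 500
    min_cooccurrence: int = 10
    prr_threshold: float = 2.0
    q_threshold: float = 0.05

    def __post_init__(self) -> None:
        if min(self.min_entity_support, self.min_cooccurrence) < 0:
            raise ValueError("support thresholds must be >= 0")
        if self.prr_threshold < 0 or self.q_threshold < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass(frozen=True)
class SignalRecord:
    """One statistically characterized (entity, event) association."""

    entity_id: str
    entity_kind: str
    event_id: str
    event_kind: str
    event_level: Optional[int]
    table: ContingencyTable
    prr: float
    p: float
    q: float
    supported: bool
    strong: bool
    significant: bool


def _entity_set(case: AnnotatedCase, kind: str) -> frozenset[str]:
    if kind == "drug":
        return case.drug_ids
    if kind == "target":
        return case.target_ids
    if kind == "pathway":
        return case.pathway_ids
    if kind == "atc_class":
        return case.atc_classes
    raise ValueError(f"unknown entity kind {kind!r}; expected one of {ENTITY_KINDS}")


def _has_entity(case: AnnotatedCase, kind: str, entity_id: str) -> bool:
    if kind == "atc_class":
        return any(code.startswith(entity_id) for code in case.atc_classes)
    return entity_id in _entity_set(case, kind)


def _event_terms(case: AnnotatedCase, kind: str) -> frozenset[str]:
    if kind == "reaction":
        return case.reactions
    if kind == "indication":
        return case.indications
    if kind == "outcome":
        return case.outcomes
    raise ValueError(f"unknown event kind {kind!r}; expected one of {EVENT_KINDS}")


def _case_events(
    case: AnnotatedCase,
    kind: str,
    level: Optional[int],
    hierarchy: Optional[PhenotypeHierarchy],
) -> set[str]:
    """The case's events rolled up to ``level`` (outcomes ignore level)."""
    terms = _event_terms(case, kind)
    if kind == "outcome" or level is None:
        return set(terms)
    assert hierarchy is not None
    out: set[str] = set()
    for t in terms:
        if t in hierarchy and hierarchy[t].level >= level:
            out.add(hierarchy.ancestor_at_level(t, level))
    return out


def _check_event(event_id: str, kind: str, level: Optional[int],
                 hierarchy: Optional[PhenotypeHierarchy]) -> None:
    if kind == "outcome":
        if event_id not in OUTCOME_CODES:
            raise KeyError(f"unknown outcome code {event_id!r}")
        return
    if hierarchy is None:
        raise ValueError(f"event kind {kind!r} requires a hierarchy")
    if event_id not in hierarchy:
        raise KeyError(f"unknown {kind} term {event_id!r}")
    if level is not None and hierarchy[event_id].level != level:
        raise ValueError(
            f"event {event_id!r} sits at level {hierarchy[event_id].level}, "
            f"not the requested level {level}"
        )


def build_contingency(
    corpus: Sequence[AnnotatedCase],
    entity_kind: str,
    entity_id: str,
    event_kind: str,
    event_id: str,
    event_level: Optional[int] = None,
    hierarchy: Optional[PhenotypeHierarchy] = None,
) -> ContingencyTable:
    """Count the 2x2 cells for one (entity, event) pair.

    A case has the event when any of its terms rolls up to ``event_id`` at
    ``event_level``; each case contributes to exactly one cell.
    """
    if entity_kind not in ENTITY_KINDS:
        raise ValueError(f"unknown entity kind {entity_kind!r}")
    _check_event(event_id, event_kind, event_level, hierarchy)
    a = b = c = d = 0
    for case in corpus:
        has_entity = _has_entity(case, entity_kind, entity_id)
        has_event = event_id in _case_events(case, event_kind, event_level, hierarchy)
        if has_entity:
            if has_event:
                a += 1
            else:
                b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def prr(table: ContingencyTable, permissive: bool = False) -> float:
    """Proportional reporting ratio a(c+d)/(c(a+b)).

    Undefined when no case carries the entity (a+b = 0) or the event never
    occurs without it (c = 0).  By default those raise; with
    ``permissive=True`` they return NaN and +inf respectively (a = 0 with
    c > 0 is well-defined and returns 0.0 either way).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0:
        if permissive:
            return math.nan
        raise ZeroDivisionError("PRR undefined: no case carries the entity (a+b=0)")
    if c == 0:
        if a == 0:
            return math.nan if permissive else _raise_prr_c0()
        if permissive:
            return math.inf
        raise ZeroDivisionError("PRR undefined: event never occurs without entity (c=0)")
    return float(Fraction(a * (c + d), c * (a + b)))


def _raise_prr_c0():
    raise ZeroDivisionError("PRR undefined: a=0 and c=0")


def _fisher_exact_small(a: int, b: int, c: int, d: int, sided: str) -> float:
    """Exact-arithmetic Fisher test via the hypergeometric distribution.

    Works in integers: with row margins r1, r2 and column margin k, the
    probability of a table with entity-event cell x is
    C(r1,x) C(r2,k-x) / C(n,k); only the numerators need comparing.
    """
    r1, r2, k = a + b, c + d, a + c
    lo, hi = max(0, k - r2), min(k, r1)
    weights = {x: math.comb(r1, x) * math.comb(r2, k - x) for x in range(lo, hi + 1)}
    obs = weights[a]
    if sided == "one":
        num = sum(w for x, w in weights.items() if x >= a)
    else:
        num = sum(w for w in weights.values() if w <= obs)
    return float(Fraction(num, math.comb(r1 + r2, k)))


def fisher_exact(table: ContingencyTable, sided: str = "two") -> float:
    """Fisher's exact test p-value for a 2x2 table.

    ``sided="two"`` uses the minimum-likelihood rule (sum of probabilities
    of all tables with fixed margins no more probable than the observed
    one); ``sided="one"`` is the overrepresentation (upper) tail.  Small
    tables (N below 2000) are evaluated in exact integer arithmetic;
    larger ones defer to :func:`scipy.stats.fisher_exact`.
    """
    if sided not in ("one", "two"):
        raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")
    if table.n <= _EXACT_FISHER_N:
        return _fisher_exact_small(table.a, table.b, table.c, table.d, sided)
    alternative = "greater" if sided == "one" else "two-sided"
    return float(_scipy_stats.fisher_exact(table.as_array(), alternative=alternative)[1])


def qvalues(p_list: Iterable[float], method: str = "bh", storey_lambda: float = 0.5) -> np.ndarray:
    """Multiple-testing q-values, mapped back to the input order.

    ``method="bh"`` is the Benjamini-Hochberg step-up
    (q_(i) = min_{j>=i} p_(j) * m / j, capped at 1).  ``method="storey"``
    rescales BH by the pi0 estimate #{p > lambda} / (m (1 - lambda)).
    """
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    if method == "storey":
        pi0 = min(1.0, float(np.mean(p > storey_lambda)) / (1.0 - storey_lambda)) if m else 1.0
        pi0 = max(pi0, 1.0 / m)
        q_sorted = np.minimum(1.0, q_sorted * pi0)
    elif method != "bh":
        raise ValueError(f"unknown q-value method {method!r}")
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def _flags(table: ContingencyTable, prr_value: float, q: float, filt: SignalFilter) -> tuple[bool, bool, bool]:
    supported = table.a >= filt.min_cooccurrence
    strong = (not math.isnan(prr_value)) and prr_value >= filt.prr_threshold
    significant = q < filt.q_threshold
    return supported, strong, significant


def _rank_key(r: SignalRecord):
    flagged = r.supported and r.strong and r.significant
    prr_sort = -1.0 if math.isnan(r.prr) else r.prr
    return (0 if flagged else 1, -prr_sort, -r.table.a, r.event_id)


def _profile_exposure(
    corpus: Sequence[AnnotatedCase],
    exposed: Sequence[bool],
    entity_id: str,
    entity_kind: str,
    event_kind: str,
    event_level: Optional[int],
    filt: SignalFilter,
    hierarchy: Optional[PhenotypeHierarchy],
    qvalue_method: str = "bh",
) -> list[SignalRecord]:
    """Profile one exposure vector against every event observed with it."""
    n_exposed = int(np.count_nonzero(exposed))
    counts_with: dict[str, int] = {}
    counts_total: dict[str, int] = {}
    for case, exp in zip(corpus, exposed):
        evs = _case_events(case, event_kind, event_level, hierarchy)
        for ev in evs:
            counts_total[ev] = counts_total.get(ev, 0) + 1
            if exp:
                counts_with[ev] = counts_with.get(ev, 0) + 1
    n = len(corpus)
    records: list[SignalRecord] = []
    tables: list[ContingencyTable] = []
    events = sorted(counts_with)
    for ev in events:
        a = counts_with[ev]
        b = n_exposed - a
        c = counts_total[ev] - a
        d = n - n_exposed - c
        tables.append(ContingencyTable(a, b, c, d))
    ps = [fisher_exact(t) for t in tables]
    qs = qvalues(ps, method=qvalue_method) if ps else np.array([])
    for ev, t, p, q in zip(events, tables, ps, qs):
        r = prr(t, permissive=True)
        supported, strong, significant = _flags(t, r, float(q), filt)
        records.append(
            SignalRecord(
                entity_id=entity_id,
                entity_kind=entity_kind,
                event_id=ev,
                event_kind=event_kind,
                event_level=event_level,
                table=t,
                prr=r,
                p=float(p),
                q=float(q),
                supported=supported,
                strong=strong,
                significant=significant,
            )
        )
    records.sort(key=_rank_key)
    return records


def profile_entity(
    corpus: Sequence[AnnotatedCase],
    entity_kind: str,
    entity_id: str,
    event_kind: str,
    event_level: Optional[int],
    filt: SignalFilter = SignalFilter(),
    hierarchy: Optional[PhenotypeHierarchy] = None,
    qvalue_method: str = "bh",
) -> list[SignalRecord]:
    """Ranked association profile of one entity against all observed events.

    q-values are computed over this profile's own p-values.  Raises when the
    entity is below ``filt.min_entity_support``.
    """
    if entity_kind not in ENTITY_KINDS:
        raise ValueError(f"unknown entity kind {entity_kind!r}")
    exposed = [_has_entity(c, entity_kind, entity_id) for c in corpus]
    support = sum(exposed)
    if support < filt.min_entity_support:
        raise ValueError(
            f"entity {entity_id!r} has support {support}, below the required "
            f"minimum of {filt.min_entity_support}"
        )
    return _profile_exposure(
        corpus, exposed, entity_id, entity_kind, event_kind, event_level, filt,
        hierarchy, qvalue_method,
    )


@dataclass
class ScreenResult:
    records: list[SignalRecord]
    summary: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def screen_all(
    corpus: Sequence[AnnotatedCase],
    entity_kind: str,
    event_kind: str,
    event_level: Optional[int],
    filt: SignalFilter = SignalFilter(),
    hierarchy: Optional[PhenotypeHierarchy] = None,
    entities: Optional[Iterable[str]] = None,
    qvalue_method: str = "bh",
) -> ScreenResult:
    """Screen every (entity, event) pair in one pass.

    Entities default to all of ``entity_kind`` observed in the corpus that
    meet ``filt.min_entity_support``; events are all of ``event_kind``
    observed at least once (rolled to ``event_level``).  q-values span the
    whole screen.
    """
    if entity_kind not in ENTITY_KINDS:
        raise ValueError(f"unknown entity kind {entity_kind!r}")
    n = len(corpus)
    if n == 0:
        return ScreenResult(records=[], summary={"n_cases": 0, "n_pairs": 0})
    event_sets = [_case_events(c, event_kind, event_level, hierarchy) for c in corpus]
    all_events = sorted(set().union(*event_sets)) if event_sets else []
    if entities is None:
        ent_sets = [_entity_set(c, entity_kind) for c in corpus]
        support: dict[str, int] = {}
        for s in ent_sets:
            for e in s:
                support[e] = support.get(e, 0) + 1
        ents = sorted(e for e, s in support.items() if s >= filt.min_entity_support)
    else:
        ents = sorted(entities)
    if not ents or not all_events:
        return ScreenResult(records=[], summary={"n_cases": n, "n_pairs": 0})
    ev_col = {e: i for i, e in enumerate(all_events)}
    en_col = {e: i for i, e in enumerate(ents)}
    E = np.zeros((n, len(ents)), dtype=bool)
    V = np.zeros((n, len(all_events)), dtype=bool)
    for i, case in enumerate(corpus):
        for e in ents:
            if _has_entity(case, entity_kind, e):
                E[i, en_col[e]] = True
        for ev in event_sets[i]:
            V[i, ev_col[ev]] = True
    a = (E.astype(np.int64).T @ V.astype(np.int64))
    ent_totals = E.sum(axis=0).astype(np.int64)
    ev_totals = V.sum(axis=0).astype(np.int64)
    records: list[SignalRecord] = []
    tables: list[ContingencyTable] = []
    pairs: list[tuple[str, str]] = []
    p_cache: dict[tuple[int, int, int, int], float] = {}
    ps: list[float] = []
    for ei, ent in enumerate(ents):
        for vi, ev in enumerate(all_events):
            aa = int(a[ei, vi])
            bb = int(ent_totals[ei]) - aa
            cc = int(ev_totals[vi]) - aa
            dd = n - aa - bb - cc
            t = ContingencyTable(aa, bb, cc, dd)
            key = (aa, bb, cc, dd)
            p = p_cache.get(key)
            if p is None:
                p = fisher_exact(t)
                p_cache[key] = p
            tables.append(t)
            pairs.append((ent, ev))
            ps.append(p)
    qs = qvalues(ps, method=qvalue_method)
    for (ent, ev), t, p, q in zip(pairs, tables, ps, qs):
        r = prr(t, permissive=True)
        supported, strong, significant = _flags(t, r, float(q), filt)
        records.append(
            SignalRecord(ent, entity_kind, ev, event_kind, event_level, t,
                         r, float(p), float(q), supported, strong, significant)
        )
    n_pairs = len(records)
    n_sig = sum(r.significant for r in records)
    n_str = sum(r.supported and r.strong for r in records)
    n_flag = sum(r.supported and r.strong and r.significant for r in records)
    summary = {
        "n_cases": n,
        "n_entities": len(ents),
        "n_events": len(all_events),
        "n_pairs": n_pairs,
        "n_significant": n_sig,
        "frac_significant": n_sig / n_pairs if n_pairs else 0.0,
        "n_supported_strong": n_str,
        "frac_supported_strong": n_str / n_pairs if n_pairs else 0.0,
        "n_flagged": n_flag,
    }
    records.sort(key=lambda r: (_rank_key(r), r.entity_id))
    return ScreenResult(records=records, summary=summary)


def mechanism_profiles(
    corpus: Sequence[AnnotatedCase],
    target_id: str,
    event_kind: str,
    event_level: Optional[int],
    filt: SignalFilter = SignalFilter(),
    hierarchy: Optional[PhenotypeHierarchy] = None,
) -> tuple[list[SignalRecord], list[SignalRecord]]:
    """Separate reaction profiles for agonist- and antagonist-mediated
    exposure to one target.

    Cases carrying both actions for the target (conflicts) are excluded
    from both sides; each side's corpus is the full corpus minus the cases
    exposed exclusively under the other action and minus conflicts, so each
    N equals its partition size.
    """
    ag_ids: set[str] = set()
    an_ids: set[str] = set()
    for case in corpus:
        acts = case.target_actions.get(target_id, frozenset())
        if "agonist" in acts:
            ag_ids.add(case.case_id)
        if "antagonist" in acts:
            an_ids.add(case.case_id)
    both = ag_ids & an_ids
    ag_only, an_only = ag_ids - both, an_ids - both
    if not ag_only:
        warnings.warn(f"target {target_id!r}: no agonist-only exposed cases")
    if not an_only:
        warnings.warn(f"target {target_id!r}: no antagonist-only exposed cases")

    def _side(exposed_ids: set[str], excluded_ids: set[str]) -> list[SignalRecord]:
        sub = [c for c in corpus if c.case_id not in excluded_ids and c.case_id not in both]
        exposed = [c.case_id in exposed_ids for c in sub]
        if not any(exposed):
            return []
        return _profile_exposure(
            sub, exposed, target_id, "target", event_kind, event_level, filt, hierarchy
        )

    return _side(ag_only, an_only), _side(an_only, ag_only)


def records_to_frame(records: Sequence[SignalRecord]) -> pd.DataFrame:
    """Flatten signal records to the canonical delimited-output columns."""
    return pd.DataFrame(
        [
            {
                "entity_id": r.entity_id,
                "entity_kind": r.entity_kind,
                "event_id": r.event_id,
                "event_kind": r.event_kind,
                "event_level": r.event_level,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "prr": r.prr,
                "p": r.p,
                "q": r.q,
                "supported": r.supported,
                "strong": r.strong,
                "significant": r.significant,
            }
            for r in records
        ],
        columns=[
            "entity_id", "entity_kind", "event_id", "event_kind", "event_level",
            "a", "b", "c", "d", "prr", "p", "q", "supported", "strong", "significant",
        ],
    )
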