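"""Direct target-level signals versus indirect drug-mediated signals.

The direct route builds the case-level 2x2 for (target, effect).  The
indirect route counts drugs: those co-reported with the effect, those
targeting the protein, both, and neither, and evaluates PRR/Fisher on that
drug-level 2x2; the per-drug case-level PRR spread (max/mean/min over the
targeting drugs) quantifies how unevenly the effect is carried.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .integrate import AnnotatedCase
from .model import DIALECTS, PhenotypeHierarchy, TargetLink
from .signals import (
    ContingencyTable,
    SignalFilter,
    SignalRecord,
    _case_events,
    build_contingency,
    fisher_exact,
    prr,
)

__all__ = [
    "BenchmarkPair",
    "DirectSignal",
    "IndirectSignal",
    "direct_signal",
    "indirect_signal",
    "recapitulation",
    "read_benchmark_pairs",
    "write_benchmark_pairs",
]


@dataclass(frozen=True)
class BenchmarkPair:
    """A known protein-effect pair with one or two effect-term synonyms."""

    protein_id: str
    effect_terms: tuple[tuple[str, int], ...]  # (term_id, level), 1-2 entries

    def __post_init__(self) -> None:
        if not 1 <= len(self.effect_terms) <= 2:
            raise ValueError("a benchmark pair carries one or two effect terms")


@dataclass(frozen=True)
class DirectSignal:
    pair: BenchmarkPair
    evaluable: bool
    reason: str = ""
    record: Optional[SignalRecord] = None
    term_used: Optional[str] = None
    level_used: Optional[int] = None

    @property
    def flagged(self) -> bool:
        r = self.record
        return bool(r and r.supported and r.strong and r.significant)


@dataclass(frozen=True)
class IndirectSignal:
    pair: BenchmarkPair
    table: ContingencyTable  # drug-level counts
    prr_indirect: float
    p_indirect: float
    spread_max: float
    spread_mean: float
    spread_min: float
    term_used: str
    level_used: int

    def flagged(self, filt: SignalFilter) -> bool:
        return (
            self.table.a >= filt.min_cooccurrence
            and not math.isnan(self.prr_indirect)
            and self.prr_indirect >= filt.prr_threshold
            and self.p_indirect < filt.q_threshold
        )


def _candidate_terms(
    term_id: str, level: int, hierarchy: PhenotypeHierarchy
) -> list[tuple[str, int]]:
    """The term itself, then its ancestors from one level up to the root."""
    out = [(term_id, level)]
    for lv in range(level - 1, 0, -1):
        out.append((hierarchy.ancestor_at_level(term_id, lv), lv))
    return out


def _choose_term(
    corpus: Sequence[AnnotatedCase],
    pair: BenchmarkPair,
    hierarchy: PhenotypeHierarchy,
    min_cooccurrence: int,
    exposed: Sequence[bool],
) -> Optional[tuple[str, int, int]]:
    """Pick the synonym/level to evaluate: prefer each synonym at its own
    (most specific) level, fall back to ancestors while the co-occurrence
    count stays below ``min_cooccurrence``; across synonyms take the
    best-supported choice.  Returns (term, level, a) or None if no synonym
    co-occurs with the target at all."""
    best: Optional[tuple[str, int, int]] = None
    for term_id, level in pair.effect_terms:
        picked: Optional[tuple[str, int, int]] = None
        for cand, lv in _candidate_terms(term_id, level, hierarchy):
            a = 0
            for case, exp in zip(corpus, exposed):
                if exp and cand in _case_events(case, "reaction", lv, hierarchy):
                    a += 1
            if a >= min_cooccurrence:
                picked = (cand, lv, a)
                break
            if a > 0 and (picked is None or a > picked[2]):
                picked = (cand, lv, a)
        if picked and (best is None or picked[2] > best[2]):
            best = picked
    return best


def direct_signal(
    corpus: Sequence[AnnotatedCase],
    pair: BenchmarkPair,
    filt: SignalFilter,
    hierarchy: PhenotypeHierarchy,
) -> DirectSignal:
    """Case-level signal for the pair's best-supported effect synonym."""
    exposed = [pair.protein_id in c.target_ids for c in corpus]
    if not any(exposed):
        return DirectSignal(pair, evaluable=False, reason="no case exposed to protein")
    choice = _choose_term(corpus, pair, hierarchy, filt.min_cooccurrence, exposed)
    if choice is None:
        return DirectSignal(pair, evaluable=False, reason="no effect synonym observed with protein")
    term, level, _ = choice
    table = build_contingency(corpus, "target", pair.protein_id, "reaction", term, level, hierarchy)
    p = fisher_exact(table)
    r = prr(table, permissive=True)
    supported = table.a >= filt.min_cooccurrence
    strong = (not math.isnan(r)) and r >= filt.prr_threshold
    significant = p < filt.q_threshold  # single test: q = p
    record = SignalRecord(
        entity_id=pair.protein_id,
        entity_kind="target",
        event_id=term,
        event_kind="reaction",
        event_level=level,
        table=table,
        prr=r,
        p=p,
        q=p,
        supported=supported,
        strong=strong,
        significant=significant,
    )
    return DirectSignal(pair, evaluable=True, record=record, term_used=term, level_used=level)


def indirect_signal(
    corpus: Sequence[AnnotatedCase],
    pair: BenchmarkPair,
    links: Sequence[TargetLink],
    hierarchy: PhenotypeHierarchy,
    term: Optional[str] = None,
    level: Optional[int] = None,
    min_cooccurrence: int = 10,
) -> IndirectSignal:
    """Drug-level signal for the pair, after the approach that aggregates
    per-drug effect co-reporting.

    When ``term`` is not given, the same synonym-selection rule as the
    direct route is applied so both routes evaluate the same effect.
    """
    targeting_all = {l.drug_id for l in links if l.role == "target" and l.protein_id == pair.protein_id}
    observed: set[str] = set()
    for c in corpus:
        observed |= c.drug_ids
    targeting = targeting_all & observed
    if not targeting:
        raise ValueError(f"no observed drug targets protein {pair.protein_id!r}")
    if term is None:
        exposed = [pair.protein_id in c.target_ids for c in corpus]
        choice = _choose_term(corpus, pair, hierarchy, min_cooccurrence, exposed)
        if choice is None:
            term, level = pair.effect_terms[0]
        else:
            term, level, _ = choice
    assert level is not None
    coreported: set[str] = set()
    for c in corpus:
        if term in _case_events(c, "reaction", level, hierarchy):
            coreported |= c.drug_ids
    a = len(targeting & coreported)
    b = len(targeting - coreported)
    c_ = len(coreported - targeting)
    d = len(observed - targeting - coreported)
    table = ContingencyTable(a, b, c_, d)
    drug_prrs = []
    for did in sorted(targeting):
        t = build_contingency(corpus, "drug", did, "reaction", term, level, hierarchy)
        drug_prrs.append(prr(t, permissive=True))
    arr = np.array(drug_prrs, dtype=float)
    return IndirectSignal(
        pair=pair,
        table=table,
        prr_indirect=prr(table, permissive=True),
        p_indirect=fisher_exact(table),
        spread_max=float(np.nanmax(arr)),
        spread_mean=float(np.nanmean(arr)),
        spread_min=float(np.nanmin(arr)),
        term_used=term,
        level_used=level,
    )


@dataclass
class RecapitulationRow:
    pair: BenchmarkPair
    direct: Optional[DirectSignal]
    indirect: Optional[IndirectSignal]
    direct_flagged: bool
    indirect_flagged: bool


@dataclass
class RecapitulationResult:
    rows: list[RecapitulationRow]
    n_direct: int
    n_indirect: int

    @property
    def ratio(self) -> float:
        """direct recapitulation total over indirect total."""
        if self.n_indirect == 0:
            return math.inf if self.n_direct else math.nan
        return self.n_direct / self.n_indirect


def recapitulation(
    corpus: Sequence[AnnotatedCase],
    pairs: Sequence[BenchmarkPair],
    filt: SignalFilter,
    links: Sequence[TargetLink],
    hierarchy: PhenotypeHierarchy,
) -> RecapitulationResult:
    """Score every benchmark pair under both routes with the same filter."""
    rows: list[RecapitulationRow] = []
    for pair in pairs:
        ds = direct_signal(corpus, pair, filt, hierarchy)
        try:
            ins = indirect_signal(
                corpus, pair, links, hierarchy,
                term=ds.term_used, level=ds.level_used,
                min_cooccurrence=filt.min_cooccurrence,
            ) if ds.evaluable else None
        except ValueError:
            ins = None
        rows.append(
            RecapitulationRow(
                pair=pair,
                direct=ds,
                indirect=ins,
                direct_flagged=ds.flagged,
                indirect_flagged=bool(ins and ins.flagged(filt)),
            )
        )
    return RecapitulationResult(
        rows=rows,
        n_direct=sum(r.direct_flagged for r in rows),
        n_indirect=sum(r.indirect_flagged for r in rows),
    )


PAIR_COLUMNS = ["protein_id", "effect_term_1", "level_1", "effect_term_2", "level_2"]


def read_benchmark_pairs(path: str | Path, dialect: str = "tab") -> list[BenchmarkPair]:
    delim = DIALECTS[dialect]
    pairs: list[BenchmarkPair] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != PAIR_COLUMNS:
            raise ValueError(f"benchmark pair table must have columns {PAIR_COLUMNS}")
        for row in reader:
            terms = [((row.get("effect_term_1") or "").strip(), int(row["level_1"]))]
            t2 = (row.get("effect_term_2") or "").strip()
            if t2:
                terms.append((t2, int(row["level_2"])))
            pairs.append(BenchmarkPair((row.get("protein_id") or "").strip(), tuple(terms)))
    return pairs


def write_benchmark_pairs(pairs: Sequence[BenchmarkPair], path: str | Path, dialect: str = "tab") -> None:
    delim = DIALECTS[dialect]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(PAIR_COLUMNS)
        for p in pairs:
            row = [p.protein_id, p.effect_terms[0][0], p.effect_terms[0][1]]
            if len(p.effect_terms) > 1:
                row += [p.effect_terms[1][0], p.effect_terms[1][1]]
            else:
                row += ["", ""]
            writer.writerow(row)
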