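"""Normalization of verbatim drug-mention strings to drug concepts.

The matcher is staged: blacklist exclusion, exact synonym match, whole-token
part match, then bounded edit-distance match.  The fuzzy stage never accepts
a candidate more than ``max_distance`` (default 5) edits away.  Multi-drug
phrases (parts joined by ``+``, ``/`` or `` and ``) are split and each part
is mapped independently; the union of matches is returned.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .model import CaseReport, DrugConcept

__all__ = [
    "DEFAULT_BLACKLIST",
    "DEFAULT_MAX_DISTANCE",
    "MappingResult",
    "CoverageStats",
    "UnmappedName",
    "MappedCase",
    "SynonymIndex",
    "normalize_string",
    "levenshtein",
    "map_name",
    "map_corpus",
]

DEFAULT_MAX_DISTANCE = 5
DEFAULT_BLACKLIST = frozenset({"unknown", "unk"})

_NONWORD = re.compile(r"[\W_]+", re.UNICODE)
# multi-drug separators, applied to the raw verbatim (normalization would
# collapse "+" and "/" into spaces before they could be seen)
_SPLIT = re.compile(r"[+/]|\s+and\s+", re.IGNORECASE)

# part matches shorter than this are rejected as spurious
_MIN_PART_LEN = 4


def normalize_string(s: str) -> str:
    """Case-fold, collapse punctuation runs to single spaces, strip ends.

    Idempotent and deterministic.
    """
    return _NONWORD.sub(" ", s.casefold()).strip()


def levenshtein(s: str, t: str, cap: Optional[int] = None) -> int:
    """Plain edit distance (substitute/insert/delete each cost 1).

    With ``cap`` set, returns any value > cap as soon as the distance is
    known to exceed it (band pruning).
    """
    if s == t:
        return 0
    m, n = len(s), len(t)
    if m == 0 or n == 0:
        return max(m, n)
    if cap is not None and abs(m - n) > cap:
        return cap + 1
    prev = list(range(n + 1))
    for i, cs in enumerate(s, start=1):
        cur = [i] + [0] * n
        best = i
        for j, ct in enumerate(t, start=1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (cs != ct))
            if cur[j] < best:
                best = cur[j]
        if cap is not None and best > cap:
            return cap + 1
        prev = cur
    return prev[n]


@dataclass(frozen=True)
class MappingResult:
    """Outcome of normalizing one verbatim drug string."""

    verbatim: str
    matches: frozenset[str]
    stage: str  # exact | part | fuzzy | blacklist | unmapped
    distance: int = 0
    nearest_distance: Optional[int] = None  # filled for unmapped names

    def __post_init__(self) -> None:
        if self.stage in ("blacklist", "unmapped") and self.matches:
            raise ValueError(f"stage={self.stage} must carry no matches")
        if self.stage in ("exact", "part") and self.distance != 0:
            raise ValueError(f"stage={self.stage} must have distance 0")

    @property
    def ambiguous(self) -> bool:
        return len(self.matches) > 1

    @property
    def mapped(self) -> bool:
        return bool(self.matches)


@dataclass(frozen=True)
class CoverageStats:
    """Mapping coverage over distinct names and over case reports."""

    frac_names_mapped: float
    frac_reports_mapped: float

    def __post_init__(self) -> None:
        for v in (self.frac_names_mapped, self.frac_reports_mapped):
            if not 0.0 <= v <= 1.0:
                raise ValueError("coverage fractions must lie in [0, 1]")


@dataclass(frozen=True)
class UnmappedName:
    verbatim: str
    n_occurrences: int
    nearest_distance: Optional[int]


@dataclass(frozen=True)
class MappedCase:
    """A case report annotated with per-mention mapping results."""

    case: CaseReport
    results: tuple[MappingResult, ...]
    drug_ids: frozenset[str]

    @property
    def case_id(self) -> str:
        return self.case.case_id


class SynonymIndex:
    """Pre-built lookup structures over a drug dictionary.

    Holds the normalized-synonym → drug-id map, a token-span index for the
    part stage, and per-synonym character-count vectors used as a cheap
    lower bound (half the L1 count difference never exceeds the edit
    distance) to prune fuzzy candidates.
    """

    def __init__(self, concepts: Mapping[str, DrugConcept]):
        if not concepts:
            raise ValueError("dictionary must be non-empty")
        self.concepts = dict(concepts)
        self.syn_to_drugs: dict[str, frozenset[str]] = {}
        acc: dict[str, set[str]] = {}
        for c in concepts.values():
            for syn in c.synonyms:
                norm = normalize_string(syn)
                if norm:
                    acc.setdefault(norm, set()).add(c.drug_id)
        self.syn_to_drugs = {s: frozenset(d) for s, d in acc.items()}
        self._synonyms = sorted(self.syn_to_drugs)
        # character-count matrix for the prune; unseen chars bucket to col 0
        alphabet = sorted({ch for s in self._synonyms for ch in s})
        self._char_col = {ch: i + 1 for i, ch in enumerate(alphabet)}
        counts = np.zeros((len(self._synonyms), len(alphabet) + 1), dtype=np.int32)
        for i, s in enumerate(self._synonyms):
            for ch in s:
                counts[i, self._char_col[ch]] += 1
        self._counts = counts
        self._lengths = np.array([len(s) for s in self._synonyms], dtype=np.int32)

    def _count_vector(self, s: str) -> np.ndarray:
        v = np.zeros(self._counts.shape[1], dtype=np.int32)
        for ch in s:
            v[self._char_col.get(ch, 0)] += 1
        return v

    def fuzzy_candidates(self, s: str, cap: int) -> list[str]:
        """Synonyms whose edit distance to ``s`` could be ≤ cap."""
        lb_len = np.abs(self._lengths - len(s))
        lb_cnt = np.abs(self._counts - self._count_vector(s)).sum(axis=1) // 2
        keep = np.flatnonzero(np.maximum(lb_len, lb_cnt) <= cap)
        return [self._synonyms[i] for i in keep]

    def nearest(self, s: str) -> tuple[Optional[int], frozenset[str]]:
        """Exact minimum edit distance over the whole dictionary."""
        best: Optional[int] = None
        drugs: set[str] = set()
        for syn in self._synonyms:
            d = levenshtein(s, syn, cap=None if best is None else best)
            if best is None or d < best:
                best, drugs = d, set(self.syn_to_drugs[syn])
            elif d == best:
                drugs |= self.syn_to_drugs[syn]
        return best, frozenset(drugs)


def _normalize_blacklist(blacklist: Iterable[str]) -> frozenset[str]:
    return frozenset(normalize_string(b) for b in blacklist)


def _match_single(
    norm: str, index: SynonymIndex, max_distance: int
) -> tuple[str, frozenset[str], int]:
    """Map one normalized phrase (no multi-drug separators left)."""
    drugs = index.syn_to_drugs.get(norm)
    if drugs:
        return "exact", drugs, 0
    # part stage: any contiguous token span equal to a synonym of length ≥ 4
    tokens = norm.split()
    if len(tokens) > 1:
        part_hits: set[str] = set()
        for i in range(len(tokens)):
            for j in range(i + 1, len(tokens) + 1):
                span = " ".join(tokens[i:j])
                if len(span) >= _MIN_PART_LEN and span in index.syn_to_drugs:
                    part_hits |= index.syn_to_drugs[span]
        if part_hits:
            return "part", frozenset(part_hits), 0
    # fuzzy stage: bounded minimum edit distance
    best: Optional[int] = None
    hits: set[str] = set()
    for syn in index.fuzzy_candidates(norm, max_distance):
        cap = max_distance if best is None else best
        d = levenshtein(norm, syn, cap=cap)
        if d > max_distance:
            continue
        if best is None or d < best:
            best, hits = d, set(index.syn_to_drugs[syn])
        elif d == best:
            hits |= index.syn_to_drugs[syn]
    if best is not None:
        return "fuzzy", frozenset(hits), best
    return "unmapped", frozenset(), 0


_STAGE_ORDER = {"exact": 0, "part": 1, "fuzzy": 2}


def map_name(
    verbatim: str,
    index: SynonymIndex,
    blacklist: Iterable[str] = DEFAULT_BLACKLIST,
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> MappingResult:
    """Map one verbatim drug mention to zero or more drug concepts.

    Pure function of its arguments; corpus context never changes the result.
    """
    bl = _normalize_blacklist(blacklist)
    norm = normalize_string(verbatim)
    if not norm:
        return MappingResult(verbatim=verbatim, matches=frozenset(), stage="unmapped",
                             nearest_distance=None)
    if norm in bl:
        return MappingResult(verbatim=verbatim, matches=frozenset(), stage="blacklist")
    parts = [p for p in (normalize_string(raw) for raw in _SPLIT.split(verbatim)) if p]
    if len(parts) > 1:
        stage_rank: Optional[int] = None
        distance = 0
        matches: set[str] = set()
        saw_blacklist = False
        for part in parts:
            if part in bl:
                saw_blacklist = True
                continue
            st, hits, d = _match_single(part, index, max_distance)
            if st == "unmapped":
                continue
            matches |= hits
            stage_rank = _STAGE_ORDER[st] if stage_rank is None else max(stage_rank, _STAGE_ORDER[st])
            distance = max(distance, d)
        if matches:
            stage = [k for k, v in _STAGE_ORDER.items() if v == stage_rank][0]
            return MappingResult(verbatim=verbatim, matches=frozenset(matches),
                                 stage=stage, distance=distance)
        if saw_blacklist:
            return MappingResult(verbatim=verbatim, matches=frozenset(), stage="blacklist")
        nearest, _ = index.nearest(norm)
        return MappingResult(verbatim=verbatim, matches=frozenset(), stage="unmapped",
                             nearest_distance=nearest)
    st, hits, d = _match_single(norm, index, max_distance)
    if st == "unmapped":
        nearest, _ = index.nearest(norm)
        return MappingResult(verbatim=verbatim, matches=frozenset(), stage="unmapped",
                             nearest_distance=nearest)
    return MappingResult(verbatim=verbatim, matches=hits, stage=st, distance=d)


def map_corpus(
    corpus: Sequence[CaseReport],
    concepts: Mapping[str, DrugConcept],
    blacklist: Iterable[str] = DEFAULT_BLACKLIST,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    include_ambiguous: bool = False,
) -> tuple[list[MappedCase], CoverageStats, list[UnmappedName]]:
    """Map every mention in a corpus.

    Returns the annotated corpus, coverage statistics, and a report of
    unmapped names with their nearest-synonym distances.  Ambiguous fuzzy
    matches are excluded from each case's expanded ``drug_ids`` unless
    ``include_ambiguous`` is set (they are still recorded in the
    per-mention results).
    """
    index = concepts if isinstance(concepts, SynonymIndex) else SynonymIndex(concepts)
    cache: dict[str, MappingResult] = {}
    occurrences: dict[str, int] = {}
    mapped_cases: list[MappedCase] = []
    for case in corpus:
        results = []
        drug_ids: set[str] = set()
        for mention in case.drug_mentions:
            res = cache.get(mention)
            if res is None:
                res = map_name(mention, index, blacklist, max_distance)
                cache[mention] = res
            occurrences[mention] = occurrences.get(mention, 0) + 1
            results.append(res)
            if res.mapped and (include_ambiguous or not (res.stage == "fuzzy" and res.ambiguous)):
                drug_ids |= res.matches
        mapped_cases.append(
            MappedCase(case=case, results=tuple(results), drug_ids=frozenset(drug_ids))
        )
    distinct = [r for r in cache.values() if r.stage != "blacklist"]
    n_names = len(distinct)
    n_mapped_names = sum(1 for r in distinct if r.mapped)
    frac_names = n_mapped_names / n_names if n_names else 0.0
    n_reports_mapped = sum(1 for mc in mapped_cases if any(r.mapped for r in mc.results))
    frac_reports = n_reports_mapped / len(mapped_cases) if mapped_cases else 0.0
    unmapped = sorted(
        (
            UnmappedName(r.verbatim, occurrences[r.verbatim], r.nearest_distance)
            for r in cache.values()
            if r.stage == "unmapped"
        ),
        key=lambda u: (-u.n_occurrences, u.verbatim),
    )
    return mapped_cases, CoverageStats(frac_names, frac_reports), unmapped
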