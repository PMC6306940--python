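"""Synthetic world and case-corpus generation.

Produces a complete toy dataset — phenotype hierarchy, drug dictionary,
drug→protein link table, protein annotations — plus case corpora with
planted protein-reaction effects, character-level name corruption, and
blacklist-token noise, together with the ground truth needed to score
every downstream stage.

Planted effects act at the protein level: any drug hitting a planted
protein confers the configured risk multiplier on the paired reaction.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import model
from .mapping import levenshtein
from .model import (
    CaseReport,
    DrugConcept,
    PhenotypeHierarchy,
    PhenotypeTerm,
    ProteinAnnotation,
    TargetLink,
)

__all__ = [
    "PlantedSignal",
    "CorruptionSpec",
    "ProtectiveOutcome",
    "GeneratorConfig",
    "World",
    "GroundTruth",
    "generate_world",
    "generate_cases",
    "write_world",
    "write_ground_truth",
    "read_ground_truth",
]

DEFAULT_BLACKLIST_TOKENS = ("UNKNOWN", "UNK")


@dataclass(frozen=True)
class PlantedSignal:
    protein_id: str
    term_id: str
    multiplier: float

    def __post_init__(self) -> None:
        if self.multiplier < 1.0:
            raise ValueError("risk multiplier must be >= 1")


@dataclass(frozen=True)
class CorruptionSpec:
    typo_prob: float = 0.0
    max_edits: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.typo_prob <= 1.0:
            raise ValueError("typo_prob must lie in [0, 1]")
        if not 0 <= self.max_edits <= 3:
            raise ValueError("max_edits must lie in [0, 3]")


@dataclass(frozen=True)
class ProtectiveOutcome:
    """Outcome whose rate depends on exposure to an ATC class prefix."""

    atc_prefix: str
    outcome: str
    rate_exposed: float
    rate_unexposed: float

    def __post_init__(self) -> None:
        if self.outcome not in model.OUTCOME_CODES:
            raise ValueError(f"unknown outcome code {self.outcome!r}")
        for r in (self.rate_exposed, self.rate_unexposed):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_cases: int = 1000
    n_drugs: int = 20
    n_proteins: int = 15
    n_reaction_leaves: int = 24
    n_indication_leaves: int = 6
    background_reaction_prob: float = 0.01
    planted_signals: tuple[PlantedSignal, ...] = ()
    corruption: CorruptionSpec = field(default_factory=CorruptionSpec)
    blacklist_mention_prob: float = 0.0
    protective_outcome: Optional[ProtectiveOutcome] = None
    date_range: tuple[date, date] = (date(2004, 1, 1), date(2016, 12, 31))
    missing_date_prob: float = 0.0
    #: fraction of proteins additionally linked with a non-target role
    nontarget_role_frac: float = 0.25
    drugs_per_case: tuple[int, int] = (1, 3)
    targets_per_drug: tuple[int, int] = (1, 3)
    #: minimum pairwise edit distance between generated synonyms; > 5 keeps
    #: bounded fuzzy matching unambiguous even after max_edits corruptions
    min_synonym_separation: int = 6
    brand_name_prob: float = 0.5
    atc_prefix_pool: tuple[str, ...] = ("C07A", "N02B", "J01C", "L01X", "A10B", "R03A")

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_drugs", "n_proteins", "n_reaction_leaves",
                     "n_indication_leaves"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("background_reaction_prob", "blacklist_mention_prob",
                     "missing_date_prob", "nontarget_role_frac", "brand_name_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.date_range[0] > self.date_range[1]:
            raise ValueError("date_range start must not exceed end")
        for lo, hi in (self.drugs_per_case, self.targets_per_drug):
            if not 1 <= lo <= hi:
                raise ValueError("per-case/per-drug ranges must satisfy 1 <= lo <= hi")


@dataclass
class World:
    hierarchy: PhenotypeHierarchy
    concepts: dict[str, DrugConcept]
    links: list[TargetLink]
    annotations: dict[str, ProteinAnnotation]
    reaction_leaves: list[str]
    indication_leaves: list[str]
    blacklist: tuple[str, ...] = DEFAULT_BLACKLIST_TOKENS


@dataclass
class GroundTruth:
    """Everything needed to score downstream stages without re-deriving it."""

    planted_signals: tuple[PlantedSignal, ...]
    #: (case_id, mention index) → intended drug_id (None for noise tokens)
    mention_map: dict[tuple[str, int], Optional[str]]
    #: case_id → true drug exposure (pre-corruption)
    exposure: dict[str, frozenset[str]]


_CONSONANTS = "bcdfghklmnprstvz"
_VOWELS = "aeiou"


def _word(rng: np.random.Generator, n_syllables: int) -> str:
    parts = []
    for _ in range(n_syllables):
        parts.append(_CONSONANTS[rng.integers(len(_CONSONANTS))])
        parts.append(_VOWELS[rng.integers(len(_VOWELS))])
    return "".join(parts)


def _distinct_name(rng: np.random.Generator, existing: list[str], min_sep: int) -> str:
    for _ in range(1000):
        name = _word(rng, int(rng.integers(3, 6)))
        if all(levenshtein(name, e, cap=min_sep) >= min_sep for e in existing):
            return name
    raise RuntimeError("could not generate a sufficiently separated drug name")


def _build_subtree(prefix: str, n_leaves: int, level_offset: int = 0) -> list[PhenotypeTerm]:
    """A 4-level binary-ish tree with ``n_leaves`` level-4 terms."""
    terms: list[PhenotypeTerm] = []
    leaves = [f"{prefix}4_{i:04d}" for i in range(n_leaves)]
    parents3 = [f"{prefix}3_{i:04d}" for i in range((n_leaves + 1) // 2)]
    parents2 = [f"{prefix}2_{i:04d}" for i in range((len(parents3) + 1) // 2)]
    parents1 = [f"{prefix}1_{i:04d}" for i in range((len(parents2) + 1) // 2)]
    for i, tid in enumerate(parents1):
        terms.append(PhenotypeTerm(tid, f"{prefix} class {tid}", 1, None))
    for i, tid in enumerate(parents2):
        terms.append(PhenotypeTerm(tid, f"{prefix} group {tid}", 2, parents1[i // 2]))
    for i, tid in enumerate(parents3):
        terms.append(PhenotypeTerm(tid, f"{prefix} family {tid}", 3, parents2[i // 2]))
    for i, tid in enumerate(leaves):
        terms.append(PhenotypeTerm(tid, f"{prefix} term {tid}", 4, parents3[i // 2]))
    return terms


def generate_world(config: GeneratorConfig) -> World:
    """Deterministically build the vocabularies and link tables.

    World generation consumes its own substream of the seed, so the same
    structural configuration always yields the same world regardless of the
    planted signals or case-level noise settings.
    """
    rng = np.random.default_rng([config.seed, 0])
    terms = _build_subtree("R", config.n_reaction_leaves) + _build_subtree(
        "I", config.n_indication_leaves
    )
    hierarchy = PhenotypeHierarchy(terms)
    reaction_leaves = sorted(t.term_id for t in hierarchy.terms_at_level(4)
                             if t.term_id.startswith("R"))
    indication_leaves = sorted(t.term_id for t in hierarchy.terms_at_level(4)
                               if t.term_id.startswith("I"))

    names: list[str] = []
    concepts: dict[str, DrugConcept] = {}
    prefixes = list(config.atc_prefix_pool)
    if config.protective_outcome and config.protective_outcome.atc_prefix not in prefixes:
        prefixes.insert(0, config.protective_outcome.atc_prefix)
    for i in range(config.n_drugs):
        did = f"D{i:04d}"
        canonical = _distinct_name(rng, names, config.min_synonym_separation)
        names.append(canonical)
        synonyms = {canonical}
        if rng.random() < config.brand_name_prob:
            brand = _distinct_name(rng, names, config.min_synonym_separation)
            names.append(brand)
            synonyms.add(brand)
        prefix = prefixes[int(rng.integers(len(prefixes)))]
        code = f"{prefix}{rng.integers(10)}{rng.integers(10)}"
        concepts[did] = DrugConcept(did, canonical, frozenset(synonyms), frozenset({code}))

    proteins = [f"P{i:04d}" for i in range(config.n_proteins)]
    links: list[TargetLink] = []
    actions = ("agonist", "antagonist", "unknown")
    for did in sorted(concepts):
        lo, hi = config.targets_per_drug
        k = int(rng.integers(lo, hi + 1))
        k = min(k, config.n_proteins)
        chosen = rng.choice(config.n_proteins, size=k, replace=False)
        for pi in sorted(int(x) for x in chosen):
            action = actions[int(rng.integers(3))]
            links.append(TargetLink(did, proteins[pi], "target", action))
    n_noisy = int(round(config.nontarget_role_frac * config.n_proteins))
    noisy = rng.choice(config.n_proteins, size=n_noisy, replace=False)
    drug_ids = sorted(concepts)
    for pi in sorted(int(x) for x in noisy):
        role = ("enzyme", "transporter", "carrier")[int(rng.integers(3))]
        did = drug_ids[int(rng.integers(len(drug_ids)))]
        links.append(TargetLink(did, proteins[pi], role, "unknown"))

    pathway_pool = [f"PW{i:03d}" for i in range(max(3, config.n_proteins // 5))]
    annotations = {}
    for i, pid in enumerate(proteins):
        n_pw = int(rng.integers(0, 3))
        pws = rng.choice(len(pathway_pool), size=n_pw, replace=False) if n_pw else []
        annotations[pid] = ProteinAnnotation(
            pid, f"GENE{i:04d}", frozenset(pathway_pool[int(j)] for j in pws)
        )
    return World(
        hierarchy=hierarchy,
        concepts=concepts,
        links=links,
        annotations=annotations,
        reaction_leaves=reaction_leaves,
        indication_leaves=indication_leaves,
    )


def _corrupt(rng: np.random.Generator, name: str, max_edits: int) -> str:
    n_edits = int(rng.integers(1, max_edits + 1))
    s = list(name)
    for _ in range(n_edits):
        op = int(rng.integers(3))
        letters = string.ascii_lowercase
        if op == 0 and s:  # substitute
            i = int(rng.integers(len(s)))
            s[i] = letters[int(rng.integers(26))]
        elif op == 1:  # insert
            i = int(rng.integers(len(s) + 1))
            s.insert(i, letters[int(rng.integers(26))])
        elif s:  # delete
            i = int(rng.integers(len(s)))
            del s[i]
    return "".join(s)


def generate_cases(
    config: GeneratorConfig, world: World
) -> tuple[list[CaseReport], GroundTruth]:
    """Generate the case corpus and its ground truth.

    A case exposed to a drug targeting a planted protein experiences the
    paired reaction with probability ``min(1, multiplier * background)``;
    all other (case, leaf) draws use the background probability.
    """
    for ps in config.planted_signals:
        if ps.term_id not in world.hierarchy:
            raise ValueError(f"planted term {ps.term_id!r} not in world hierarchy")
    rng = np.random.default_rng([config.seed, 1])
    drug_ids = sorted(world.concepts)
    syn_lists = {d: sorted(world.concepts[d].synonyms) for d in drug_ids}
    targets_by_drug: dict[str, set[str]] = {}
    for l in world.links:
        if l.role == "target":
            targets_by_drug.setdefault(l.drug_id, set()).add(l.protein_id)
    planted_by_protein: dict[str, list[PlantedSignal]] = {}
    for ps in config.planted_signals:
        planted_by_protein.setdefault(ps.protein_id, []).append(ps)

    leaves = world.reaction_leaves
    leaf_idx = {t: i for i, t in enumerate(leaves)}
    bg = config.background_reaction_prob
    start, end = config.date_range
    span = (end - start).days + 1
    other_outcomes = sorted(model.OUTCOME_CODES)
    prot = config.protective_outcome

    cases: list[CaseReport] = []
    mention_map: dict[tuple[str, int], Optional[str]] = {}
    exposure: dict[str, frozenset[str]] = {}
    lo, hi = config.drugs_per_case
    hi = min(hi, len(drug_ids))
    for i in range(config.n_cases):
        cid = f"C{i:07d}"
        k = int(rng.integers(lo, hi + 1))
        chosen = sorted(int(x) for x in rng.choice(len(drug_ids), size=k, replace=False))
        case_drugs = [drug_ids[j] for j in chosen]
        exposed_proteins: set[str] = set()
        for d in case_drugs:
            exposed_proteins |= targets_by_drug.get(d, set())
        probs = np.full(len(leaves), bg)
        for p in exposed_proteins:
            for ps in planted_by_protein.get(p, ()):  # planted risk
                j = leaf_idx.get(ps.term_id)
                if j is not None:
                    probs[j] = min(1.0, ps.multiplier * bg)
        draws = rng.random(len(leaves))
        reactions = frozenset(leaves[j] for j in np.flatnonzero(draws < probs))

        indications = frozenset(
            {world.indication_leaves[int(rng.integers(len(world.indication_leaves)))]}
        )

        outcomes: set[str] = set()
        if prot is not None:
            exposed_class = any(
                code.startswith(prot.atc_prefix)
                for d in case_drugs
                for code in world.concepts[d].atc_codes
            )
            rate = prot.rate_exposed if exposed_class else prot.rate_unexposed
            if rng.random() < rate:
                outcomes.add(prot.outcome)
        for code in other_outcomes:
            if prot is not None and code == prot.outcome:
                continue
            if rng.random() < 0.02:
                outcomes.add(code)

        rdate: Optional[date] = start + timedelta(days=int(rng.integers(span)))
        if config.missing_date_prob and rng.random() < config.missing_date_prob:
            rdate = None

        mentions: list[str] = []
        for d in case_drugs:
            syns = syn_lists[d]
            name = syns[int(rng.integers(len(syns)))]
            if config.corruption.typo_prob and config.corruption.max_edits > 0 \
                    and rng.random() < config.corruption.typo_prob:
                name = _corrupt(rng, name, config.corruption.max_edits)
            mention_map[(cid, len(mentions))] = d
            mentions.append(name)
        if config.blacklist_mention_prob and rng.random() < config.blacklist_mention_prob:
            token = world.blacklist[int(rng.integers(len(world.blacklist)))]
            mention_map[(cid, len(mentions))] = None
            mentions.append(token)

        cases.append(
            CaseReport(
                case_id=cid,
                report_date=rdate,
                drug_mentions=tuple(mentions),
                indications=indications,
                reactions=reactions,
                outcomes=frozenset(outcomes),
            )
        )
        exposure[cid] = frozenset(case_drugs)
    truth = GroundTruth(
        planted_signals=tuple(config.planted_signals),
        mention_map=mention_map,
        exposure=exposure,
    )
    return cases, truth


def write_world(world: World, outdir: str | Path, dialect: str = "tab") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model.write_hierarchy(world.hierarchy, outdir / "hierarchy.tsv", dialect)
    model.write_dictionary(world.concepts, outdir / "drug_dictionary.tsv", dialect)
    model.write_links(world.links, outdir / "target_links.tsv", dialect)
    model.write_protein_annotations(world.annotations, outdir / "protein_annotations.tsv", dialect)
    (outdir / "blacklist.txt").write_text("\n".join(world.blacklist) + "\n", encoding="utf-8")


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "planted_signals": [
            {"protein_id": s.protein_id, "term_id": s.term_id, "multiplier": s.multiplier}
            for s in truth.planted_signals
        ],
        "mention_map": [
            {"case_id": cid, "mention_index": idx, "drug_id": did}
            for (cid, idx), did in sorted(truth.mention_map.items())
        ],
        "exposure": {cid: sorted(drugs) for cid, drugs in sorted(truth.exposure.items())},
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return GroundTruth(
        planted_signals=tuple(
            PlantedSignal(s["protein_id"], s["term_id"], s["multiplier"])
            for s in payload["planted_signals"]
        ),
        mention_map={
            (m["case_id"], m["mention_index"]): m["drug_id"] for m in payload["mention_map"]
        },
        exposure={cid: frozenset(d) for cid, d in payload["exposure"].items()},
    )
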