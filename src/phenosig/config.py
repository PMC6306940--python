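"""Pipeline configuration and end-to-end orchestration."""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import integrate, mapping, model, signals

log = logging.getLogger("phenosig")

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    cases: str = ""
    dictionary: str = ""
    hierarchy: str = ""
    links: str = ""
    annotations: str = ""
    blacklist: str = ""
    dialect: str = "tab"
    out_dir: str = "phenosig_out"
    seed: int = 0
    max_distance: int = mapping.DEFAULT_MAX_DISTANCE
    include_ambiguous: bool = False
    entity_kind: str = "target"
    event_kind: str = "reaction"
    event_levels: tuple[int, ...] = (2, 4)
    min_support: int = 500
    min_cooccurrence: int = 10
    prr_threshold: float = 2.0
    q_threshold: float = 0.05

    def signal_filter(self) -> signals.SignalFilter:
        return signals.SignalFilter(
            min_entity_support=self.min_support,
            min_cooccurrence=self.min_cooccurrence,
            prr_threshold=self.prr_threshold,
            q_threshold=self.q_threshold,
        )

    def validate_paths(self) -> None:
        for fname in ("cases", "dictionary", "hierarchy", "links"):
            value = getattr(self, fname)
            if not value:
                raise ValueError(f"pipeline config field {fname!r} is required")
            if not Path(value).exists():
                raise FileNotFoundError(f"pipeline config field {fname!r}: no such file {value!r}")
        for fname in ("annotations", "blacklist"):
            value = getattr(self, fname)
            if value and not Path(value).exists():
                raise FileNotFoundError(f"pipeline config field {fname!r}: no such file {value!r}")


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load a flat TOML config; keyword overrides win over file values."""
    data = tomllib.loads(Path(path).read_text(encoding="utf-8"))
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    if "event_levels" in data:
        data["event_levels"] = tuple(data["event_levels"])
    return PipelineConfig(**data)


def _stage(name: str, summary_rows: list[dict], **info) -> None:
    row = {"stage": name, **info}
    summary_rows.append(row)
    log.info("%s: %s", name, info)


def run_pipeline(config: PipelineConfig) -> Path:
    """Read, map, annotate and screen; write all artifacts to ``out_dir``.

    Deterministic given the config.  Any stage failure aborts with the
    stage name in the exception message.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary_rows: list[dict] = []
    stage = "read"
    try:
        hierarchy = model.read_hierarchy(config.hierarchy, config.dialect)
        concepts = model.read_dictionary(config.dictionary, config.dialect)
        links = model.read_links(config.links, config.dialect)
        annotations = (
            model.read_protein_annotations(config.annotations, config.dialect)
            if config.annotations
            else None
        )
        blacklist = (
            frozenset(
                l.strip() for l in Path(config.blacklist).read_text(encoding="utf-8").splitlines()
                if l.strip()
            )
            if config.blacklist
            else mapping.DEFAULT_BLACKLIST
        )
        cases, read_report = model.read_cases(config.cases, config.dialect, hierarchy)
        _stage(stage, summary_rows, n_cases=len(cases), n_rejected=read_report.n_rejected,
               n_drugs=len(concepts), n_links=len(links), n_terms=len(hierarchy))

        stage = "map"
        mapped, coverage, unmapped = mapping.map_corpus(
            cases, concepts, blacklist, config.max_distance, config.include_ambiguous
        )
        _stage(stage, summary_rows,
               frac_names_mapped=coverage.frac_names_mapped,
               frac_reports_mapped=coverage.frac_reports_mapped,
               n_unmapped_names=len(unmapped))
        with open(out / "mapping_report.tsv", "w", encoding="utf-8") as fh:
            fh.write("verbatim\tn_occurrences\tnearest_distance\n")
            for u in unmapped:
                fh.write(f"{u.verbatim}\t{u.n_occurrences}\t{u.nearest_distance}\n")
        (out / "coverage.json").write_text(
            json.dumps(
                {
                    "frac_names_mapped": coverage.frac_names_mapped,
                    "frac_reports_mapped": coverage.frac_reports_mapped,
                },
                indent=1,
            ),
            encoding="utf-8",
        )

        stage = "annotate"
        annotated = integrate.annotate_cases(mapped, links, annotations, concepts)
        n_with_targets = sum(1 for c in annotated if c.target_ids)
        _stage(stage, summary_rows, n_annotated=len(annotated), n_with_targets=n_with_targets)

        stage = "screen"
        filt = config.signal_filter()
        for level in config.event_levels:
            result = signals.screen_all(
                annotated, config.entity_kind, config.event_kind, level, filt, hierarchy
            )
            result.to_frame().to_csv(out / f"screen_level{level}.tsv", sep="\t", index=False)
            _stage(f"screen_level{level}", summary_rows, **result.summary)
    except Exception as exc:
        (out / "run_summary.jsonl").write_text(
            "\n".join(json.dumps(r) for r in summary_rows + [{"stage": stage, "error": str(exc)}])
            + "\n",
            encoding="utf-8",
        )
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    (out / "run_summary.jsonl").write_text(
        "\n".join(json.dumps(r) for r in summary_rows) + "\n", encoding="utf-8"
    )
    return out
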