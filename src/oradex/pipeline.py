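"""End-to-end orchestration: note text -> candidate pair table.

``process_note`` runs one note through section detection, sentence
segmentation, entity matching, negation flagging, both pairing rules, and
the audit filters.  ``run_pipeline`` maps it over a corpus and returns the
pairs plus a per-stage run log (resource version and counts), keeping every
step deterministic for identical inputs and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import yaml

from oradex.corpus_io import NoteRecord
from oradex.extract import detect_negation, match_entities
from oradex.lexicon import LexiconBundle, load_lexicons
from oradex.pairing import (
    CandidateORADE,
    PairingConfig,
    apply_antidote_rule,
    apply_filters,
    apply_trigger_rule,
)
from oradex.preprocess import segment_note


@dataclass
class PipelineConfig:
    window: int = 3
    filters_enabled: tuple[str, ...] = ("pain_indication", "medication_change", "negated_ae")
    cross_section_windows: bool = False
    scan_whole_note: bool = False
    fuzzy_threshold: Optional[float] = None
    include_narcotics: bool = False
    resource_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "filters_enabled" in data:
            data["filters_enabled"] = tuple(data["filters_enabled"])
        return cls(**data)

    def pairing(self) -> PairingConfig:
        return PairingConfig(
            window=self.window,
            filters_enabled=frozenset(self.filters_enabled),
            cross_section_windows=self.cross_section_windows,
        )


@dataclass
class RunLog:
    lexicon_version: str = ""
    notes: int = 0
    sections: int = 0
    sentences: int = 0
    mentions_by_type: dict[str, int] = field(default_factory=dict)
    pairs_before_filters: int = 0
    pairs_flagged: int = 0
    pairs_unfiltered: int = 0

    def as_dict(self) -> dict:
        return {
            "lexicon_version": self.lexicon_version,
            "notes": self.notes,
            "sections": self.sections,
            "sentences": self.sentences,
            "mentions_by_type": dict(sorted(self.mentions_by_type.items())),
            "pairs_before_filters": self.pairs_before_filters,
            "pairs_flagged": self.pairs_flagged,
            "pairs_unfiltered": self.pairs_unfiltered,
        }


def process_note(
    note: NoteRecord,
    bundle: LexiconBundle,
    config: PipelineConfig | None = None,
    ae_recognizer: Callable[[str], list[tuple[int, int, str]]] | None = None,
    log: RunLog | None = None,
) -> list[CandidateORADE]:
    """Extract filtered candidate pairs from a single note."""
    cfg = config or PipelineConfig()
    header_config = bundle.section_config or None
    sections, sentences = segment_note(
        note.text,
        header_config=header_config,
        abbreviations=bundle.abbreviations,
        scan_whole_note=cfg.scan_whole_note,
    )
    mentions = match_entities(
        sentences,
        bundle,
        ae_recognizer=ae_recognizer,
        note_id=note.note_id,
        fuzzy_threshold=cfg.fuzzy_threshold,
    )
    mentions = detect_negation(mentions, sentences, bundle)
    pcfg = cfg.pairing()
    pairs = apply_trigger_rule(mentions, sentences, pcfg) + apply_antidote_rule(
        mentions, sentences, pcfg
    )
    pairs = apply_filters(pairs, mentions, sentences, pcfg, bundle=bundle)
    if log is not None:
        log.notes += 1
        log.sections += len(sections)
        log.sentences += len(sentences)
        for m in mentions:
            log.mentions_by_type[m.entity_type] = log.mentions_by_type.get(m.entity_type, 0) + 1
        log.pairs_before_filters += len(pairs)
        log.pairs_flagged += sum(p.filtered for p in pairs)
        log.pairs_unfiltered += sum(not p.filtered for p in pairs)
    return pairs


def run_pipeline(
    notes: Sequence[NoteRecord],
    config: PipelineConfig | None = None,
    bundle: LexiconBundle | None = None,
    ae_recognizer: Callable[[str], list[tuple[int, int, str]]] | None = None,
) -> tuple[list[CandidateORADE], RunLog]:
    """Run the full extraction over a corpus; returns (pairs, run log)."""
    cfg = config or PipelineConfig()
    if bundle is None:
        bundle = load_lexicons(cfg.resource_dir, include_narcotics=cfg.include_narcotics)
    log = RunLog(lexicon_version=bundle.version)
    pairs: list[CandidateORADE] = []
    for note in notes:
        pairs.extend(process_note(note, bundle, cfg, ae_recognizer, log))
    return pairs, log
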