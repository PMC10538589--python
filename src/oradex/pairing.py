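"""Candidate ORADE pair generation and false-positive filtering.

Two rules emit candidate (opioid drug, adverse event) pairs around anchor
sentences, searching a +/-``window`` sentence context (default 3, never
crossing section boundaries unless configured otherwise):

* trigger-phrase rule — anchors are sentences containing a trigger phrase
  (e.g. "contributed to", "secondary to") with an opioid mention in the
  same sentence or within the window;
* antidote rule — anchors are sentences mentioning a reversal agent
  (naloxone/Narcan), indirect evidence of an opioid adverse event nearby.

Three audit filters then *flag* (never delete) the common false-positive
patterns: pain-indication pairs, medication switch events, and negated
adverse-event mentions.  Candidate pairs are hypothetical signals; no
causality is implied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import pandas as pd

from oradex.extract import EntityMention, PhraseMatcher
from oradex.lexicon import LexiconBundle
from oradex.preprocess import SentenceSpan

FILTER_NAMES = ("pain_indication", "medication_change", "negated_ae")


@dataclass(frozen=True)
class PairingConfig:
    window: int = 3
    filters_enabled: frozenset[str] = frozenset(FILTER_NAMES)
    cross_section_windows: bool = False

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")
        unknown = set(self.filters_enabled) - set(FILTER_NAMES)
        if unknown:
            raise ValueError(f"unknown filter names: {sorted(unknown)}")


@dataclass(frozen=True)
class CandidateORADE:
    """A (drug, AE) candidate pair with full rule provenance."""

    note_id: str
    drug: EntityMention
    ae: EntityMention
    generic_drug: str
    drug_class: str
    drug_kind: str
    ae_pt: str
    ae_llt: Optional[str]
    rule: str  # trigger_phrase | antidote
    trigger_used: Optional[str]
    sentence_distance: int  # |anchor sentence - AE sentence|
    drug_distance: int  # |anchor sentence - drug sentence|
    section: Optional[str] = None
    filtered: bool = False
    filter_reason: Optional[str] = None


def _section_of(sentences: Sequence[SentenceSpan]) -> dict[int, str]:
    return {s.sentence_index: s.section for s in sentences}


def _in_window(a: int, b: int, cfg: PairingConfig, sections: dict[int, str]) -> bool:
    if abs(a - b) > cfg.window:
        return False
    if cfg.cross_section_windows:
        return True
    return sections.get(a) == sections.get(b)


def _make_pair(
    note_id: str,
    drug: EntityMention,
    ae: EntityMention,
    anchor_index: int,
    rule: str,
    trigger_used: Optional[str],
    sections: dict[int, str],
) -> CandidateORADE:
    return CandidateORADE(
        note_id=note_id,
        drug=drug,
        ae=ae,
        generic_drug=drug.normalized,
        drug_class=drug.drug_class or "",
        drug_kind=drug.drug_kind or "",
        ae_pt=ae.normalized,
        ae_llt=ae.ae_llt,
        rule=rule,
        trigger_used=trigger_used,
        sentence_distance=abs(anchor_index - ae.sentence_index),
        drug_distance=abs(anchor_index - drug.sentence_index),
        section=sections.get(anchor_index),
    )


def _dedup_smallest(pairs: list[CandidateORADE]) -> list[CandidateORADE]:
    """Collapse duplicates by (drug mention, AE mention), keeping the pair
    with the smallest sentence distance (then drug distance)."""
    best: dict[tuple, CandidateORADE] = {}
    order: list[tuple] = []
    for p in pairs:
        key = (p.drug.start, p.drug.end, p.ae.start, p.ae.end)
        if key not in best:
            best[key] = p
            order.append(key)
        else:
            q = best[key]
            if (p.sentence_distance, p.drug_distance) < (q.sentence_distance, q.drug_distance):
                best[key] = p
    return [best[k] for k in order]


def apply_trigger_rule(
    mentions: Sequence[EntityMention],
    sentences: Sequence[SentenceSpan],
    config: PairingConfig | None = None,
) -> list[CandidateORADE]:
    """Link opioid mentions to adverse events via trigger phrases.

    Anchor sentences contain a trigger phrase and have an opioid mention in
    the same sentence or within the window; every opioid within the window
    of an anchor is paired with every adverse event within the window.
    """
    cfg = config or PairingConfig()
    sections = _section_of(sentences)
    note_id = mentions[0].note_id if mentions else ""
    drugs = [m for m in mentions if m.entity_type == "opioid_drug"]
    aes = [m for m in mentions if m.entity_type == "adverse_event"]
    triggers = [m for m in mentions if m.entity_type == "trigger_phrase"]

    pairs: list[CandidateORADE] = []
    for trig in triggers:
        anchor = trig.sentence_index
        near_drugs = [d for d in drugs if _in_window(anchor, d.sentence_index, cfg, sections)]
        if not near_drugs:
            continue
        near_aes = [a for a in aes if _in_window(anchor, a.sentence_index, cfg, sections)]
        for d in near_drugs:
            for a in near_aes:
                pairs.append(
                    _make_pair(note_id, d, a, anchor, "trigger_phrase", trig.normalized, sections)
                )
    return _dedup_smallest(pairs)


def apply_antidote_rule(
    mentions: Sequence[EntityMention],
    sentences: Sequence[SentenceSpan],
    config: PairingConfig | None = None,
) -> list[CandidateORADE]:
    """Link opioid mentions to adverse events around antidote mentions.

    Anchor sentences mention a reversal agent; drugs and adverse events
    within the window are exhaustively paired.  The antidote itself is never
    emitted as a drug or an adverse event.
    """
    cfg = config or PairingConfig()
    sections = _section_of(sentences)
    note_id = mentions[0].note_id if mentions else ""
    antidote_surfaces = {m.normalized for m in mentions if m.entity_type == "antidote"}
    drugs = [m for m in mentions if m.entity_type == "opioid_drug"]
    aes = [
        m
        for m in mentions
        if m.entity_type == "adverse_event" and m.normalized not in antidote_surfaces
    ]
    anchors = sorted({m.sentence_index for m in mentions if m.entity_type == "antidote"})

    pairs: list[CandidateORADE] = []
    for anchor in anchors:
        for d in drugs:
            if not _in_window(anchor, d.sentence_index, cfg, sections):
                continue
            for a in aes:
                if not _in_window(anchor, a.sentence_index, cfg, sections):
                    continue
                pairs.append(_make_pair(note_id, d, a, anchor, "antidote", None, sections))
    return _dedup_smallest(pairs)


_CHANGE_RE = re.compile(
    r"\b(?:chang(?:e|ed|ing)|switch(?:ed|ing)?)\s+"
    r"(?:from\s+(?:[^\s]+\s+){1,5}?)?to\s+",
    re.IGNORECASE,
)


def _switch_targets(text: str, bundle: LexiconBundle) -> set[str]:
    """Generic names of drugs appearing as the target of a change/switch
    construction ("changed/switched [from X] to Y") in ``text``."""
    matcher = PhraseMatcher({d.surface: d.surface.casefold() for d in bundle.drugs})
    targets: set[str] = set()
    for m in _CHANGE_RE.finditer(text):
        tail = text[m.end() :]
        hits = matcher.find(tail)
        if hits and hits[0][0] == 0:
            key = hits[0][3]
            entry = bundle.drug_by_surface.get(key)
            if entry is not None:
                targets.add(entry.generic_name.casefold())
    return targets


def apply_filters(
    pairs: Sequence[CandidateORADE],
    mentions: Sequence[EntityMention],
    sentences: Sequence[SentenceSpan],
    config: PairingConfig | None = None,
    bundle: LexiconBundle | None = None,
    pain_tokens: Sequence[str] | None = None,
) -> list[CandidateORADE]:
    """Flag (never delete) pairs matching a false-positive pattern.

    Filters run in fixed order — pain_indication, medication_change,
    negated_ae — and the first match sets ``filter_reason``:

    1. pain_indication: the AE surface or preferred term contains a pain
       token (the event is the indication for the opioid, not its effect);
    2. medication_change: the AE's or drug's sentence contains a
       change/switch construction whose target drug is the paired drug
       (the AE is the reason for switching *to* the drug, which therefore
       cannot have caused it);
    3. negated_ae: the AE mention is negated.
    """
    cfg = config or PairingConfig()
    if pain_tokens is None:
        pain_tokens = bundle.pain_tokens if bundle is not None else ["pain"]
    pain_set = {t.casefold() for t in pain_tokens}
    sent_by_index = {s.sentence_index: s for s in sentences}

    switch_cache: dict[int, set[str]] = {}

    def targets_in_sentence(idx: int) -> set[str]:
        if bundle is None:
            return set()
        if idx not in switch_cache:
            sent = sent_by_index.get(idx)
            switch_cache[idx] = _switch_targets(sent.text, bundle) if sent else set()
        return switch_cache[idx]

    out: list[CandidateORADE] = []
    for p in pairs:
        reason = None
        if "pain_indication" in cfg.filters_enabled:
            ae_tokens = set(p.ae.surface.casefold().split()) | set(p.ae_pt.casefold().split())
            if ae_tokens & pain_set:
                reason = "pain_indication"
        if reason is None and "medication_change" in cfg.filters_enabled:
            targets = targets_in_sentence(p.ae.sentence_index) | targets_in_sentence(
                p.drug.sentence_index
            )
            if p.generic_drug.casefold() in targets:
                reason = "medication_change"
        if reason is None and "negated_ae" in cfg.filters_enabled:
            if p.ae.negated:
                reason = "negated_ae"
        if reason is not None:
            out.append(replace(p, filtered=True, filter_reason=reason))
        else:
            out.append(replace(p, filtered=False, filter_reason=None) if p.filtered else p)
    return out


def unfiltered(pairs: Sequence[CandidateORADE]) -> list[CandidateORADE]:
    return [p for p in pairs if not p.filtered]


_COUNT_ROWS = [
    "unique_opioid_drugs",
    "unique_aes",
    "unique_candidate_pairs",
    "discharge_summaries",
    "unique_patients",
]


def aggregate_pairs(
    pairs: Sequence[CandidateORADE],
    notes: Sequence,
) -> pd.DataFrame:
    """Per rule-stratum summary counts over unfiltered pairs.

    Strata: found by the trigger-phrase rule (``trigger_phrase`` column),
    found only by the antidote rule (``antidote_only``), found by both
    (``both``), and the union (``total``).  Uniqueness follows generic-drug
    reporting: unique pair = (generic drug, preferred term); brands collapse
    to generics.
    """
    subject_of = {n.note_id: n.subject_id for n in notes}
    keys: dict[tuple[str, str, str], set[str]] = {}
    for p in unfiltered(pairs):
        key = (p.note_id, p.generic_drug.casefold(), p.ae_pt.casefold())
        keys.setdefault(key, set()).add(p.rule)

    def counts(selected: list[tuple[str, str, str]]) -> dict[str, int]:
        return {
            "unique_opioid_drugs": len({k[1] for k in selected}),
            "unique_aes": len({k[2] for k in selected}),
            "unique_candidate_pairs": len({(k[1], k[2]) for k in selected}),
            "discharge_summaries": len({k[0] for k in selected}),
            "unique_patients": len({subject_of.get(k[0], k[0]) for k in selected}),
        }

    strata = {
        "trigger_phrase": [k for k, r in keys.items() if "trigger_phrase" in r],
        "antidote_only": [k for k, r in keys.items() if r == {"antidote"}],
        "both": [k for k, r in keys.items() if {"trigger_phrase", "antidote"} <= r],
        "total": list(keys),
    }
    table = {name: counts(sel) for name, sel in strata.items()}
    return pd.DataFrame(table, index=_COUNT_ROWS).loc[_COUNT_ROWS]


def drug_ae_patient_counts(
    pairs: Sequence[CandidateORADE],
    notes: Sequence,
    count_notes: bool = False,
) -> pd.DataFrame:
    """Unique patient (or note) counts per (generic drug, preferred term)."""
    subject_of = {n.note_id: n.subject_id for n in notes}
    rows: dict[tuple[str, str, str], set[str]] = {}
    for p in unfiltered(pairs):
        unit = p.note_id if count_notes else subject_of.get(p.note_id, p.note_id)
        rows.setdefault((p.generic_drug, p.ae_pt, p.ae_llt or ""), set()).add(unit)
    data = [
        {"generic_drug": d, "ae_pt": pt, "ae_llt": llt, "count": len(units)}
        for (d, pt, llt), units in sorted(rows.items())
    ]
    return pd.DataFrame(data, columns=["generic_drug", "ae_pt", "ae_llt", "count"])
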