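"""Typed entity mention detection and negation flagging.

Four entity types are matched per sentence: opioid drugs, antidotes,
trigger phrases, and adverse events.  Drug/antidote/trigger matching is
dictionary-driven (case-insensitive, word-boundary anchored, multi-word
phrases matched as token sequences, longest-match-first with leftmost
tie-breaks).  Adverse-event candidates come from a pluggable recognizer —
the shipped default is a dictionary matcher over the packaged synonym
table, and any external model honoring the same span contract can replace
it.  Negation follows the ConText convention for these cue types: a cue
negates mentions after it in the same sentence until a termination cue.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, replace
from typing import Callable, Optional, Protocol, Sequence

from oradex.lexicon import LexiconBundle, clean_phrase, normalize_ae, tokenize
from oradex.preprocess import SentenceSpan


class ExtractionError(RuntimeError):
    """Raised when the AE recognizer fails on a sentence."""

    def __init__(self, message: str, sentence_index: int):
        super().__init__(f"{message} (sentence_index={sentence_index})")
        self.sentence_index = sentence_index


@dataclass(frozen=True)
class EntityMention:
    """A located surface mention; offsets are absolute note positions."""

    note_id: str
    sentence_index: int
    start: int
    end: int
    surface: str
    entity_type: str  # opioid_drug | antidote | trigger_phrase | adverse_event
    normalized: str  # generic drug name, canonical trigger, or AE preferred term
    negated: bool = False  # meaningful for adverse_event only
    drug_class: Optional[str] = None
    drug_kind: Optional[str] = None
    ae_llt: Optional[str] = None
    concept_id: Optional[str] = None
    unmapped: bool = False


class Recognizer(Protocol):
    """Contract for adverse-event candidate recognizers: given sentence
    text, return (start, end, surface) spans relative to the sentence."""

    def __call__(self, text: str) -> list[tuple[int, int, str]]: ...


class PhraseMatcher:
    """Token-sequence phrase matcher: case-insensitive, word-boundary
    anchored, longest-match-first, non-overlapping, leftmost wins ties."""

    def __init__(self, phrases: dict[str, str]):
        # phrase (casefolded token tuple) -> canonical value
        self.table: dict[tuple[str, ...], str] = {}
        self.max_len = 0
        for phrase, value in phrases.items():
            toks = tuple(t for _, _, t in tokenize(phrase))
            if toks:
                self.table[toks] = value
                self.max_len = max(self.max_len, len(toks))

    def find(self, text: str) -> list[tuple[int, int, str, str]]:
        """Return (start, end, surface, canonical) matches over ``text``."""
        tokens = tokenize(text)
        out = []
        i = 0
        while i < len(tokens):
            hit = None
            for n in range(min(self.max_len, len(tokens) - i), 0, -1):
                key = tuple(t for _, _, t in tokens[i : i + n])
                if key in self.table:
                    hit = (tokens[i][0], tokens[i + n - 1][1], self.table[key], n)
                    break
            if hit:
                start, end, value, n = hit
                out.append((start, end, text[start:end], value))
                i += n
            else:
                i += 1
        return out


class DictionaryRecognizer:
    """Default AE recognizer: matches the packaged synonym table."""

    def __init__(self, bundle: LexiconBundle):
        self._matcher = PhraseMatcher({syn: syn for syn in bundle.synonym_to_concept})

    def __call__(self, text: str) -> list[tuple[int, int, str]]:
        return [(s, e, surf) for s, e, surf, _ in self._matcher.find(text)]


class ExternalRecognizer:
    """Adapter for an external recognizer command.

    The command receives the sentence text on stdin and must emit one
    tab-separated ``start\\tend\\tsurface`` triple per line.
    """

    def __init__(self, command: str):
        self.command = command

    def __call__(self, text: str) -> list[tuple[int, int, str]]:
        proc = subprocess.run(
            self.command,
            shell=True,
            input=text,
            capture_output=True,
            text=True,
            check=True,
        )
        spans = []
        for line in proc.stdout.splitlines():
            if not line.strip():
                continue
            start_s, end_s, surface = line.split("\t", 2)
            spans.append((int(start_s), int(end_s), surface))
        return spans


def _build_matchers(bundle: LexiconBundle):
    drugs = PhraseMatcher({d.surface: d.surface.casefold() for d in bundle.drugs})
    triggers = PhraseMatcher({t.phrase: t.phrase.casefold() for t in bundle.triggers})
    antidotes = PhraseMatcher({a: a.casefold() for a in bundle.antidotes})
    return drugs, triggers, antidotes


def match_entities(
    sentences: Sequence[SentenceSpan],
    bundle: LexiconBundle,
    ae_recognizer: Callable[[str], list[tuple[int, int, str]]] | None = None,
    note_id: str = "",
    fuzzy_threshold: float | None = None,
) -> list[EntityMention]:
    """Find all typed entity mentions in one note's sentences.

    AE candidate spans from the recognizer are normalized through the
    synonym table; spans that fail to map are kept with the cleaned raw
    phrase as ``normalized`` and flagged ``unmapped``.
    """
    if ae_recognizer is None:
        ae_recognizer = DictionaryRecognizer(bundle)
    drug_matcher, trigger_matcher, antidote_matcher = _build_matchers(bundle)

    mentions: list[EntityMention] = []
    for sent in sentences:
        for start, end, surface, key in drug_matcher.find(sent.text):
            entry = bundle.drug_by_surface[key]
            mentions.append(
                EntityMention(
                    note_id=note_id,
                    sentence_index=sent.sentence_index,
                    start=sent.start + start,
                    end=sent.start + end,
                    surface=surface,
                    entity_type="opioid_drug",
                    normalized=entry.generic_name,
                    drug_class=entry.drug_class,
                    drug_kind=entry.kind,
                )
            )
        for start, end, surface, key in trigger_matcher.find(sent.text):
            mentions.append(
                EntityMention(
                    note_id=note_id,
                    sentence_index=sent.sentence_index,
                    start=sent.start + start,
                    end=sent.start + end,
                    surface=surface,
                    entity_type="trigger_phrase",
                    normalized=key,
                )
            )
        for start, end, surface, key in antidote_matcher.find(sent.text):
            mentions.append(
                EntityMention(
                    note_id=note_id,
                    sentence_index=sent.sentence_index,
                    start=sent.start + start,
                    end=sent.start + end,
                    surface=surface,
                    entity_type="antidote",
                    normalized=key,
                )
            )
        try:
            spans = ae_recognizer(sent.text)
        except Exception as exc:  # noqa: BLE001 - contract: attribute the sentence
            raise ExtractionError(f"AE recognizer failed: {exc}", sent.sentence_index) from exc
        spans = _longest_nonoverlapping(spans)
        for start, end, surface in spans:
            concept = normalize_ae(surface, bundle, fuzzy_threshold) if surface else None
            mentions.append(
                EntityMention(
                    note_id=note_id,
                    sentence_index=sent.sentence_index,
                    start=sent.start + start,
                    end=sent.start + end,
                    surface=surface,
                    entity_type="adverse_event",
                    normalized=concept.preferred_term if concept else clean_phrase(surface, bundle),
                    ae_llt=concept.lower_level_term if concept else None,
                    concept_id=concept.concept_id if concept else None,
                    unmapped=concept is None,
                )
            )
    mentions.sort(key=lambda m: (m.sentence_index, m.start, m.entity_type))
    return mentions


def _longest_nonoverlapping(
    spans: list[tuple[int, int, str]],
) -> list[tuple[int, int, str]]:
    """Enforce the per-type non-overlap invariant: longest first, leftmost
    wins among equal lengths."""
    chosen: list[tuple[int, int, str]] = []
    for span in sorted(spans, key=lambda s: (-(s[1] - s[0]), s[0])):
        if all(span[1] <= c[0] or span[0] >= c[1] for c in chosen):
            chosen.append(span)
    return sorted(chosen, key=lambda s: s[0])


def detect_negation(
    mentions: Sequence[EntityMention],
    sentences: Sequence[SentenceSpan],
    bundle: LexiconBundle,
) -> list[EntityMention]:
    """Flag negated adverse-event mentions.

    An AE mention is negated when a negation cue precedes it in the same
    sentence with no termination cue between the cue and the mention.  The
    pass only toggles flags: it never adds, removes, or re-spans mentions,
    and running it twice is a no-op.
    """
    sent_by_index = {s.sentence_index: s for s in sentences}
    neg_matcher = PhraseMatcher({c: c for c in bundle.negation_cues})
    term_matcher = PhraseMatcher({c: c for c in bundle.termination_cues})

    cue_cache: dict[int, tuple[list[tuple[int, int]], list[tuple[int, int]]]] = {}

    def cues_for(sentence_index: int):
        if sentence_index not in cue_cache:
            sent = sent_by_index[sentence_index]
            negs = [(sent.start + s, sent.start + e) for s, e, _, _ in neg_matcher.find(sent.text)]
            terms = [(sent.start + s, sent.start + e) for s, e, _, _ in term_matcher.find(sent.text)]
            cue_cache[sentence_index] = (negs, terms)
        return cue_cache[sentence_index]

    out: list[EntityMention] = []
    for m in mentions:
        if m.entity_type != "adverse_event" or m.sentence_index not in sent_by_index:
            out.append(m)
            continue
        negs, terms = cues_for(m.sentence_index)
        negated = any(
            ne <= m.start and not any(ne <= ts and te <= m.start for ts, te in terms)
            for _, ne in negs
        )
        out.append(replace(m, negated=negated) if negated != m.negated else m)
    return out
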