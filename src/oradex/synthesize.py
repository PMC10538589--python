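"""Synthetic discharge-summary generator with exact gold labels.

Every note carries the three canonical narrative sections plus decoy
headers, templated filler prose, and optionally planted events:

* true ORADE narratives (drug + trigger phrase + adverse event within a
  bounded sentence distance),
* antidote rescue narratives (naloxone reversal with the drug and event
  nearby),
* and the three classic false-positive confounders: pain-indication
  sentences, medication-switch sentences, and negated adverse events.

Templates are plain-text resources with ``{DRUG}/{TRIGGER}/{AE}/{ANTIDOTE}``
slot markers.  Generation is fully deterministic: one pseudo-random stream
per note, derived from (seed, note index), so a corpus prefix is stable
when ``n_notes`` grows.  The generator emulates the lexical structure of
discharge summaries, not their clinical richness; see the methods note for
what that implies about test coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from oradex.corpus_io import GoldLabel, GoldPair, NoteRecord
from oradex.lexicon import AEConcept, DrugEntry, LexiconBundle

_SLOTS = ("{DRUG}", "{TRIGGER}", "{AE}", "{ANTIDOTE}")


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    n_notes: int = 100
    seed: int = 0
    p_true_orade: float = 0.5
    p_antidote_event: float = 0.15
    p_indication_confounder: float = 0.25
    p_switch_confounder: float = 0.15
    p_negation_confounder: float = 0.10
    max_distance: int = 2
    reference_window: int = 3  # pairs planted farther than this are flagged out_of_window
    drug_weights: Optional[dict[str, float]] = None  # by drug surface
    ae_weights: Optional[dict[str, float]] = None  # by concept_id

    def __post_init__(self) -> None:
        if self.n_notes < 0:
            raise SimConfigError("n_notes must be >= 0")
        if self.max_distance < 0:
            raise SimConfigError("max_distance must be >= 0")
        for name in (
            "p_true_orade",
            "p_antidote_event",
            "p_indication_confounder",
            "p_switch_confounder",
            "p_negation_confounder",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class Plant:
    """Audit record for a planted surface form."""

    note_id: str
    entity_type: str
    surface: str
    start: int
    end: int


@dataclass
class _Sentence:
    text: str
    plants: list[tuple[str, str, int, int]] = field(default_factory=list)  # type, surface, local start/end


def load_templates(path: str | Path | None = None) -> dict[str, list[str]]:
    """Parse the template resource into named groups."""
    if path is None:
        from oradex.lexicon import _default_resource_dir

        path = _default_resource_dir() / "templates.txt"
    groups: dict[str, list[str]] = {}
    current: Optional[str] = None
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            groups[current] = []
        elif current is not None:
            groups[current].append(line)
    return groups


_SLOT_TYPES = {
    "{DRUG}": "opioid_drug",
    "{TRIGGER}": "trigger_phrase",
    "{AE}": "adverse_event",
    "{ANTIDOTE}": "antidote",
}


def _realize(template: str, values: dict[str, str]) -> _Sentence:
    """Fill slots left-to-right, recording the span of each filled value."""
    text = template
    plants: list[tuple[str, str, int, int]] = []
    while True:
        hits = [(text.index(s), s) for s in _SLOT_TYPES if s in text]
        if not hits:
            break
        idx, slot = min(hits)
        value = values[slot]
        text = text[:idx] + value + text[idx + len(slot) :]
        plants.append((_SLOT_TYPES[slot], value, idx, idx + len(value)))
    return _Sentence(text=text, plants=plants)


def _choice(rng: np.random.Generator, items: Sequence, weights: Optional[Sequence[float]] = None):
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
        return items[int(rng.choice(len(items), p=w))]
    return items[int(rng.integers(0, len(items)))]


class _Sampler:
    def __init__(self, config: SimConfig, bundle: LexiconBundle, templates: dict[str, list[str]]):
        self.config = config
        self.bundle = bundle
        self.templates = templates
        self.drugs = list(bundle.drugs)
        pain = set(bundle.pain_tokens)
        self.pain_concepts = [
            c for c in bundle.ae_concepts if set(c.preferred_term.casefold().split()) & pain
        ]
        self.safe_concepts = [
            c
            for c in bundle.ae_concepts
            if not any(
                set(s.casefold().split()) & pain for s in c.synonyms
            )
        ]
        if not self.safe_concepts and (config.p_true_orade > 0 or config.p_antidote_event > 0):
            raise SimConfigError("AE lexicon has no non-pain concepts to plant true events from")
        self.triggers = [t.phrase for t in bundle.triggers]
        self.antidotes = list(bundle.antidotes)

    def drug(self, rng) -> DrugEntry:
        if self.config.drug_weights:
            weights = [self.config.drug_weights.get(d.surface, 0.0) for d in self.drugs]
            if sum(weights) > 0:
                return _choice(rng, self.drugs, weights)
        return _choice(rng, self.drugs)

    def concept(self, rng, pool: Sequence[AEConcept]) -> tuple[AEConcept, str]:
        if self.config.ae_weights:
            weights = [self.config.ae_weights.get(c.concept_id, 0.0) for c in pool]
            if sum(weights) > 0:
                c = _choice(rng, pool, weights)
                return c, _choice(rng, list(c.synonyms))
        c = _choice(rng, pool)
        return c, _choice(rng, list(c.synonyms))

    def filler(self, rng) -> _Sentence:
        return _Sentence(text=_choice(rng, self.templates["filler"]))

    def tmpl(self, rng, group: str) -> str:
        return _choice(rng, self.templates[group])


def _trigger_event(s: _Sampler, rng) -> tuple[list[_Sentence], GoldPair]:
    cfg = s.config
    drug = s.drug(rng)
    concept, synonym = s.concept(rng, s.safe_concepts)
    trigger = _choice(rng, s.triggers)
    d = int(rng.integers(0, cfg.max_distance + 1))
    values = {"{DRUG}": drug.surface, "{TRIGGER}": trigger, "{AE}": synonym}
    if d == 0:
        sentences = [_realize(s.tmpl(rng, "trigger_combined"), values)]
    else:
        sentences = [_realize(s.tmpl(rng, "drug_intro"), values)]
        sentences += [s.filler(rng) for _ in range(d - 1)]
        sentences.append(_realize(s.tmpl(rng, "trigger_anchor"), values))
    gold = GoldPair(drug.generic_name, concept.preferred_term, out_of_window=d > cfg.reference_window)
    return sentences, gold


def _antidote_event(s: _Sampler, rng) -> tuple[list[_Sentence], GoldPair]:
    cfg = s.config
    drug = s.drug(rng)
    concept, synonym = s.concept(rng, s.safe_concepts)
    antidote = _choice(rng, s.antidotes)
    values = {"{DRUG}": drug.surface, "{AE}": synonym, "{ANTIDOTE}": antidote}
    if cfg.max_distance == 0:
        sentences = [_realize(s.tmpl(rng, "antidote_combined"), values)]
        worst = 0
    else:
        d_ae = int(rng.integers(1, cfg.max_distance + 1))
        d_drug = int(rng.integers(d_ae, cfg.max_distance + 1))
        if d_drug == d_ae:
            first = _realize("He developed {AE} while on {DRUG}.", values)
            sentences = [first] + [s.filler(rng) for _ in range(d_ae - 1)]
        else:
            sentences = [_realize(s.tmpl(rng, "drug_intro"), values)]
            sentences += [s.filler(rng) for _ in range(d_drug - d_ae - 1)]
            sentences.append(_realize(s.tmpl(rng, "ae_event"), values))
            sentences += [s.filler(rng) for _ in range(d_ae - 1)]
        sentences.append(_realize(s.tmpl(rng, "antidote_rescue"), values))
        worst = d_drug
    gold = GoldPair(drug.generic_name, concept.preferred_term, out_of_window=worst > cfg.reference_window)
    return sentences, gold


def _indication_confounder(s: _Sampler, rng) -> list[_Sentence]:
    drug = s.drug(rng)
    pool = s.pain_concepts or s.safe_concepts
    _, synonym = s.concept(rng, pool)
    values = {"{DRUG}": drug.surface, "{AE}": synonym}
    return [_realize(s.tmpl(rng, "indication"), values)]


def _switch_confounder(s: _Sampler, rng) -> list[_Sentence]:
    drug = s.drug(rng)
    _, synonym = s.concept(rng, s.safe_concepts)
    values = {"{DRUG}": drug.surface, "{AE}": synonym}
    return [_realize(s.tmpl(rng, "switch"), values)]


def _negation_confounder(s: _Sampler, rng) -> list[_Sentence]:
    drug = s.drug(rng)
    _, synonym = s.concept(rng, s.safe_concepts)
    trigger = _choice(rng, s.triggers)
    values = {"{DRUG}": drug.surface, "{TRIGGER}": trigger, "{AE}": synonym}
    return [
        _realize(s.tmpl(rng, "negation_concern"), values),
        _realize(s.tmpl(rng, "negation_denial"), values),
    ]


_COURSE_HEADERS = ["BRIEF HOSPITAL COURSE:", "HOSPITAL COURSE:", "Brief Hospital Course:"]
_HPI_HEADERS = ["HISTORY OF PRESENT ILLNESS:", "History of Present Illness:"]


def _assemble_note(
    note_id: str,
    hpi_sentences: list[_Sentence],
    course_sentences: list[_Sentence],
    course_header: str,
    hpi_header: str,
    rng,
) -> tuple[str, list[Plant]]:
    plants: list[Plant] = []
    parts: list[str] = []
    pos = 0

    def emit(chunk: str) -> None:
        nonlocal pos
        parts.append(chunk)
        pos += len(chunk)

    month = int(rng.integers(1, 13))
    day = int(rng.integers(1, 28))
    year = int(rng.integers(2101, 2199))
    emit(f"Admission Date: [**{year}-{month}-{day}**]    Discharge Date: [**{year}-{month}-{day + 1}**]\n\n")
    emit("Service: MEDICINE\n\n")

    for header, sentences in ((hpi_header, hpi_sentences), (course_header, course_sentences)):
        emit(header + "\n")
        for sent in sentences:
            for entity_type, surface, ls, le in sent.plants:
                plants.append(Plant(note_id, entity_type, surface, pos + ls, pos + le))
            emit(sent.text + "\n")
        emit("\n")

    emit("DISCHARGE MEDICATIONS:\n")
    emit("1. Acetaminophen 325 mg PO Q6H as needed.\n\n")
    emit("DISCHARGE CONDITION:\nStable.\n")
    return "".join(parts), plants


def generate_corpus(
    config: SimConfig,
    bundle: LexiconBundle,
    templates: dict[str, list[str]] | None = None,
    return_plants: bool = False,
):
    """Generate ``(notes, gold)`` (plus plant audit records if requested).

    Each note draws independent Bernoulli events: a true trigger-context
    ORADE, an antidote rescue narrative, and the three confounders.  Event
    blocks are separated by enough filler sentences that context windows of
    different blocks never overlap, so gold labels stay exact.
    """
    if templates is None:
        templates = load_templates()
    for group in ("filler", "drug_intro", "trigger_anchor", "trigger_combined"):
        if group not in templates or not templates[group]:
            raise SimConfigError(f"template group {group!r} missing from template resource")
    sampler = _Sampler(config, bundle, templates)
    guard = max(config.reference_window, config.max_distance) + 1

    notes: list[NoteRecord] = []
    gold: list[GoldLabel] = []
    plants: list[Plant] = []
    for i in range(config.n_notes):
        rng = np.random.default_rng([config.seed, i])
        note_id = f"note{i:05d}"
        subject_id = f"subj{i:05d}"
        hadm_id = f"hadm{i:05d}"

        blocks: list[list[_Sentence]] = []
        gold_pairs: list[GoldPair] = []
        has_true = rng.random() < config.p_true_orade
        has_antidote = rng.random() < config.p_antidote_event
        has_indic = rng.random() < config.p_indication_confounder
        has_switch = rng.random() < config.p_switch_confounder
        has_neg = rng.random() < config.p_negation_confounder

        if has_true:
            sents, gp = _trigger_event(sampler, rng)
            blocks.append(sents)
            gold_pairs.append(gp)
        if has_antidote:
            sents, gp = _antidote_event(sampler, rng)
            blocks.append(sents)
            gold_pairs.append(gp)
        if has_indic:
            blocks.append(_indication_confounder(sampler, rng))
        if has_switch:
            blocks.append(_switch_confounder(sampler, rng))
        if has_neg:
            blocks.append(_negation_confounder(sampler, rng))

        hpi = [sampler.filler(rng) for _ in range(int(rng.integers(2, 4)))]
        course: list[_Sentence] = [sampler.filler(rng)]
        for j, block in enumerate(blocks):
            if j > 0:
                course += [sampler.filler(rng) for _ in range(guard)]
            course += block
        course.append(sampler.filler(rng))

        text, note_plants = _assemble_note(
            note_id,
            hpi,
            course,
            _choice(rng, _COURSE_HEADERS),
            _choice(rng, _HPI_HEADERS),
            rng,
        )
        has_orade = bool(gold_pairs)
        icd9 = ["E935.2"] if has_orade else (["401.9"] if rng.random() < 0.5 else [])
        notes.append(
            NoteRecord(
                note_id=note_id,
                subject_id=subject_id,
                hadm_id=hadm_id,
                category="Discharge summary",
                icd9_codes=icd9,
                text=text,
            )
        )
        gold.append(GoldLabel(note_id=note_id, has_orade=has_orade, pairs=gold_pairs))
        plants.extend(note_plants)

    if return_plants:
        return notes, gold, plants
    return notes, gold


def generate_demographics(notes: Sequence[NoteRecord], seed: int = 0) -> pd.DataFrame:
    """Uniformly sampled synthetic demographics per patient (no clinical
    realism claimed); for exercising the report backends only."""
    rng = np.random.default_rng([seed, 915_217])
    subjects = sorted({n.subject_id for n in notes})
    return pd.DataFrame(
        {
            "subject_id": subjects,
            "age": rng.integers(18, 95, size=len(subjects)),
            "gender": rng.choice(["F", "M"], size=len(subjects)),
            "ethnicity": rng.choice(
                ["WHITE", "BLACK/AFRICAN AMERICAN", "HISPANIC/LATINO", "ASIAN", "OTHER"],
                size=len(subjects),
            ),
        }
    )
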