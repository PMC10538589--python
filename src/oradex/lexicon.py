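"""Versioned lexical resources: opioid drugs, trigger phrases, antidote
terms, adverse-event synonym tables, negation cues, and abbreviations.

The adverse-event vocabulary is a small packaged synonym -> preferred-term
(PT) / lower-level-term (LLT) table covering the opioid ADE domain.  It
stands in for licensed terminology services (UMLS/MedDRA), which cannot be
redistributed; :func:`normalize_ae` is the single lookup point, so a
licensed mapper can be swapped in behind the same call.
"""

from __future__ import annotations

import difflib
import logging
import re
import string
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Optional

import pandas as pd

logger = logging.getLogger(__name__)

DRUG_KINDS = {"generic", "brand", "replaced_discontinued"}
DRUG_CLASSES = {"natural", "semisynthetic", "synthetic"}


class LexiconError(ValueError):
    """Raised when a resource file violates a lexicon invariant."""


@dataclass(frozen=True)
class DrugEntry:
    surface: str
    generic_name: str
    kind: str  # generic | brand | replaced_discontinued
    drug_class: str  # natural | semisynthetic | synthetic


@dataclass(frozen=True)
class TriggerPhrase:
    phrase: str
    source: str  # published_base | curated


@dataclass(frozen=True)
class AEConcept:
    concept_id: str
    preferred_term: str
    lower_level_term: Optional[str]
    synonyms: tuple[str, ...]


@dataclass
class LexiconBundle:
    """All lexical resources, validated, with fast case-folded indexes."""

    drugs: list[DrugEntry]
    triggers: list[TriggerPhrase]
    antidotes: list[str]
    ae_concepts: list[AEConcept]
    negation_cues: list[str]
    termination_cues: list[str]
    pain_tokens: list[str]
    abbreviations: list[str]
    ae_abbreviation_map: dict[str, str] = field(default_factory=dict)
    version: str = "unversioned"
    section_config: list[tuple[str, str]] = field(default_factory=list)

    # derived indexes, built in __post_init__
    drug_by_surface: dict[str, DrugEntry] = field(default_factory=dict, repr=False)
    synonym_to_concept: dict[str, AEConcept] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._validate()
        self.drug_by_surface = {d.surface.casefold(): d for d in self.drugs}
        self.synonym_to_concept = {}
        for concept in self.ae_concepts:
            for syn in concept.synonyms:
                self.synonym_to_concept[syn.casefold()] = concept

    def _validate(self) -> None:
        if not self.drugs:
            raise LexiconError("drug lexicon is empty")
        seen_drug: dict[str, DrugEntry] = {}
        for d in self.drugs:
            key = d.surface.casefold()
            if key in seen_drug and seen_drug[key].generic_name != d.generic_name:
                raise LexiconError(
                    f"drug surface {d.surface!r} maps to both "
                    f"{seen_drug[key].generic_name!r} and {d.generic_name!r}"
                )
            seen_drug[key] = d
            if d.kind == "generic" and d.surface.casefold() != d.generic_name.casefold():
                raise LexiconError(
                    f"generic drug surface {d.surface!r} must map to itself, got {d.generic_name!r}"
                )
        antidote_set = {a.casefold() for a in self.antidotes}
        overlap = antidote_set & set(seen_drug)
        if overlap:
            raise LexiconError(f"surfaces listed as both drug and antidote: {sorted(overlap)}")

        seen_trigger = set()
        for t in self.triggers:
            if not t.phrase.strip():
                raise LexiconError("empty trigger phrase")
            key = t.phrase.casefold()
            if key in seen_trigger:
                raise LexiconError(f"duplicate trigger phrase after case folding: {t.phrase!r}")
            seen_trigger.add(key)
        if not self.triggers:
            logger.warning("trigger lexicon is empty; the trigger-phrase rule will find nothing")

        syn_owner: dict[str, str] = {}
        for concept in self.ae_concepts:
            if concept.preferred_term.casefold() not in {s.casefold() for s in concept.synonyms}:
                raise LexiconError(
                    f"preferred term {concept.preferred_term!r} is not listed among the "
                    f"synonyms of concept {concept.concept_id}"
                )
            for syn in concept.synonyms:
                key = syn.casefold()
                if key in syn_owner and syn_owner[key] != concept.concept_id:
                    raise LexiconError(
                        f"synonym {syn!r} maps to both concept {syn_owner[key]} "
                        f"and concept {concept.concept_id}"
                    )
                syn_owner[key] = concept.concept_id

    @property
    def curated_trigger_count(self) -> int:
        return sum(1 for t in self.triggers if t.source == "curated")

    def drug_lookup(self, surface: str) -> Optional[DrugEntry]:
        return self.drug_by_surface.get(surface.casefold())


def _default_resource_dir() -> Path:
    return Path(importlib_resources.files("oradex")) / "resources" / "default"


def _read_csv(path: Path) -> pd.DataFrame:
    with open(path, encoding="utf-8", errors="strict") as fh:
        return pd.read_csv(fh, dtype=str, keep_default_na=False)


def load_lexicons(
    resource_dir: str | Path | None = None,
    include_narcotics: bool = False,
) -> LexiconBundle:
    """Load and validate the lexicon bundle from ``resource_dir``.

    With no argument the packaged default resources are used.  The generic
    term "narcotics" is excluded from the drug lexicon by default (it cannot
    be resolved to a specific opioid); ``include_narcotics=True`` adds it as
    an unresolvable class-less entry.
    """
    root = Path(resource_dir) if resource_dir is not None else _default_resource_dir()

    drugs_df = _read_csv(root / "drugs.csv")
    drugs = [
        DrugEntry(row["surface"], row["generic"], row["kind"], row["class"])
        for _, row in drugs_df.iterrows()
    ]
    for d in drugs:
        if d.kind not in DRUG_KINDS:
            raise LexiconError(f"unknown drug kind {d.kind!r} for surface {d.surface!r}")
        if d.drug_class not in DRUG_CLASSES | {"unspecified"}:
            raise LexiconError(f"unknown drug class {d.drug_class!r} for surface {d.surface!r}")
    if include_narcotics:
        drugs.append(DrugEntry("narcotics", "narcotics", "generic", "unspecified"))

    triggers_df = _read_csv(root / "triggers.csv")
    triggers = [TriggerPhrase(r["phrase"], r["source"]) for _, r in triggers_df.iterrows()]

    ae_df = _read_csv(root / "ae_concepts.csv")
    concepts: list[AEConcept] = []
    for cid, grp in ae_df.groupby("concept_id", sort=True):
        pts = grp["preferred_term"].unique()
        llts = grp["lower_level_term"].unique()
        if len(pts) != 1 or len(llts) != 1:
            raise LexiconError(f"concept {cid} has inconsistent PT/LLT rows")
        concepts.append(
            AEConcept(
                concept_id=str(cid),
                preferred_term=pts[0],
                lower_level_term=llts[0] or None,
                synonyms=tuple(grp["synonym"]),
            )
        )

    cues_df = _read_csv(root / "cues.csv")
    negation = [r["cue"] for _, r in cues_df.iterrows() if r["type"] == "negation"]
    termination = [r["cue"] for _, r in cues_df.iterrows() if r["type"] == "termination"]

    abbreviations = [
        line.strip()
        for line in (root / "abbreviations.txt").read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.startswith("#")
    ]
    antidotes = [
        line.strip()
        for line in (root / "antidotes.txt").read_text(encoding="utf-8").splitlines()
        if line.strip()
    ]

    ae_abbrev: dict[str, str] = {}
    ae_abbrev_path = root / "ae_abbreviations.csv"
    if ae_abbrev_path.exists():
        for _, r in _read_csv(ae_abbrev_path).iterrows():
            ae_abbrev[r["short"].casefold()] = r["expansion"].casefold()

    version = "unversioned"
    version_path = root / "VERSION"
    if version_path.exists():
        version = version_path.read_text(encoding="utf-8").strip()

    section_config: list[tuple[str, str]] = []
    sections_path = root / "sections.csv"
    if sections_path.exists():
        for _, r in _read_csv(sections_path).iterrows():
            section_config.append((r["pattern"], r["canonical"]))

    bundle = LexiconBundle(
        drugs=drugs,
        triggers=triggers,
        antidotes=antidotes,
        ae_concepts=concepts,
        negation_cues=negation,
        termination_cues=termination,
        pain_tokens=["pain"],
        abbreviations=abbreviations,
        ae_abbreviation_map=ae_abbrev,
        version=version,
        section_config=section_config,
    )
    logger.info(
        "loaded lexicon bundle %s: %d drug surfaces, %d triggers (%d curated), "
        "%d AE concepts, %d antidotes",
        bundle.version,
        len(bundle.drugs),
        len(bundle.triggers),
        bundle.curated_trigger_count,
        len(bundle.ae_concepts),
        len(bundle.antidotes),
    )
    return bundle


_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


def clean_phrase(raw: str, bundle: LexiconBundle | None = None) -> str:
    """Normalization pipeline shared by lookup and matching: case fold,
    strip punctuation, collapse whitespace, expand known abbreviations."""
    s = raw.casefold().translate(_PUNCT_TABLE)
    tokens = s.split()
    if bundle is not None and bundle.ae_abbreviation_map:
        tokens = [bundle.ae_abbreviation_map.get(t, t) for t in tokens]
        s = " ".join(tokens)
        tokens = s.split()
    return " ".join(tokens)


def normalize_ae(
    raw_phrase: str,
    bundle: LexiconBundle,
    fuzzy_threshold: float | None = None,
) -> Optional[AEConcept]:
    """Map a raw adverse-event phrase to its concept, or ``None`` if unmapped.

    Exact synonym lookup runs after the cleaning pipeline; fuzzy matching
    (difflib ratio >= ``fuzzy_threshold``) is only attempted when a threshold
    is given, and ties break on the lexicographically smallest synonym so
    results never depend on iteration order.
    """
    if not raw_phrase:
        raise ValueError("raw_phrase must be non-empty")
    cleaned = clean_phrase(raw_phrase, bundle)
    concept = bundle.synonym_to_concept.get(cleaned)
    if concept is not None:
        return concept
    if fuzzy_threshold is None:
        return None
    best_ratio = 0.0
    best_syn: Optional[str] = None
    for syn in sorted(bundle.synonym_to_concept):
        ratio = difflib.SequenceMatcher(None, cleaned, syn).ratio()
        if ratio > best_ratio or (ratio == best_ratio and best_syn is not None and syn < best_syn):
            best_ratio, best_syn = ratio, syn
    if best_syn is not None and best_ratio >= fuzzy_threshold:
        return bundle.synonym_to_concept[best_syn]
    return None


_WORD_RE = re.compile(r"\[\*\*.*?\*\*\]|[A-Za-z0-9]+")


def tokenize(text: str) -> list[tuple[int, int, str]]:
    """Tokenize into (start, end, casefolded token) triples.

    Alphanumeric runs are tokens; hyphens split; de-identification
    placeholders ``[** ... **]`` are single atomic tokens.
    """
    return [(m.start(), m.end(), m.group(0).casefold()) for m in _WORD_RE.finditer(text)]
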