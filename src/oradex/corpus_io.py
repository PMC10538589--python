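"""Reading and writing note corpora, gold labels, and candidate-pair tables.

All formats are plain text (UTF-8, strict decoding).  Notes travel either as
JSONL (one object per line) or as CSV in the MIMIC-III NOTEEVENTS dialect
(RFC-4180 quoting, embedded newlines inside quoted TEXT fields).  Candidate
pairs round-trip through a flat CSV carrying full provenance so that
``read_pairs(write_pairs(pairs))`` reconstructs equal objects.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from oradex.extract import EntityMention
from oradex.pairing import CandidateORADE


class CorpusFormatError(ValueError):
    """Raised when an input file does not conform to the expected format."""


@dataclass
class NoteRecord:
    """One discharge summary.

    ``text`` is preserved byte-for-byte through read/write round trips and
    may contain de-identification placeholders of the form ``[** ... **]``.
    """

    note_id: str
    subject_id: str = ""
    hadm_id: str = ""
    category: str = "Discharge summary"
    icd9_codes: list[str] = field(default_factory=list)
    text: str = ""


@dataclass(frozen=True)
class GoldPair:
    generic_drug: str
    ae_preferred_term: str
    out_of_window: bool = False


@dataclass
class GoldLabel:
    """Note-level adjudication: does the note document an ORADE, and which
    (generic drug, preferred term) pairs were planted/annotated."""

    note_id: str
    has_orade: bool
    pairs: list[GoldPair] = field(default_factory=list)


# ---------------------------------------------------------------------------
# notes
# ---------------------------------------------------------------------------

_MIMIC_REQUIRED = ("SUBJECT_ID", "HADM_ID", "CATEGORY", "TEXT")


def _check_unique_ids(records: Sequence[NoteRecord]) -> None:
    seen: dict[str, int] = {}
    dups = []
    for rec in records:
        if rec.note_id in seen:
            dups.append(rec.note_id)
        seen[rec.note_id] = 1
    if dups:
        raise CorpusFormatError(f"duplicate note_id values: {sorted(set(dups))}")


def read_notes(path: str | Path, format: str = "jsonl") -> list[NoteRecord]:
    """Read a note corpus.

    Parameters
    ----------
    path
        Input file.
    format
        ``"jsonl"`` (one JSON object per line, fields as in
        :class:`NoteRecord`) or ``"mimic_csv"`` (NOTEEVENTS dialect with
        columns SUBJECT_ID, HADM_ID, CATEGORY, TEXT and optional ROW_ID and
        ICD9_CODES; quoted fields may contain embedded newlines).
    """
    path = Path(path)
    if format == "jsonl":
        records = []
        with open(path, encoding="utf-8", errors="strict") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"unreadable JSONL row {lineno}: {exc}") from exc
                if "note_id" not in obj:
                    raise CorpusFormatError(f"row {lineno}: missing required field 'note_id'")
                records.append(
                    NoteRecord(
                        note_id=str(obj["note_id"]),
                        subject_id=str(obj.get("subject_id", "")),
                        hadm_id=str(obj.get("hadm_id", "")),
                        category=str(obj.get("category", "Discharge summary")),
                        icd9_codes=[str(c) for c in obj.get("icd9_codes", [])],
                        text=str(obj.get("text", "")),
                    )
                )
        _check_unique_ids(records)
        return records
    if format == "mimic_csv":
        with open(path, encoding="utf-8", errors="strict") as fh:
            df = pd.read_csv(fh, dtype=str, keep_default_na=False)
        for col in _MIMIC_REQUIRED:
            if col not in df.columns:
                raise CorpusFormatError(f"mimic_csv is missing required column {col}")
        records = []
        for i, row in enumerate(df.itertuples(index=False)):
            row = row._asdict()
            note_id = row.get("ROW_ID") or f"row{i}"
            codes = [c for c in str(row.get("ICD9_CODES", "")).split(";") if c]
            records.append(
                NoteRecord(
                    note_id=str(note_id),
                    subject_id=row["SUBJECT_ID"],
                    hadm_id=row["HADM_ID"],
                    category=row["CATEGORY"],
                    icd9_codes=codes,
                    text=row["TEXT"],
                )
            )
        _check_unique_ids(records)
        return records
    raise ValueError(f"unknown note format: {format!r}")


def write_notes(records: Iterable[NoteRecord], path: str | Path, format: str = "jsonl") -> None:
    """Write a note corpus; inverse of :func:`read_notes`."""
    path = Path(path)
    records = list(records)
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(
                    json.dumps(
                        {
                            "note_id": rec.note_id,
                            "subject_id": rec.subject_id,
                            "hadm_id": rec.hadm_id,
                            "category": rec.category,
                            "icd9_codes": rec.icd9_codes,
                            "text": rec.text,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
        return
    if format == "mimic_csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["ROW_ID", "SUBJECT_ID", "HADM_ID", "CATEGORY", "ICD9_CODES", "TEXT"])
            for rec in records:
                writer.writerow(
                    [
                        rec.note_id,
                        rec.subject_id,
                        rec.hadm_id,
                        rec.category,
                        ";".join(rec.icd9_codes),
                        rec.text,
                    ]
                )
        return
    raise ValueError(f"unknown note format: {format!r}")


def load_diagnoses(path: str | Path) -> dict[str, list[str]]:
    """Read a diagnoses CSV (columns HADM_ID, ICD9_CODE) into hadm_id -> codes."""
    with open(path, encoding="utf-8", errors="strict") as fh:
        df = pd.read_csv(fh, dtype=str, keep_default_na=False)
    for col in ("HADM_ID", "ICD9_CODE"):
        if col not in df.columns:
            raise CorpusFormatError(f"diagnoses CSV is missing required column {col}")
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.HADM_ID, []).append(row.ICD9_CODE)
    return out


def attach_icd9(records: Sequence[NoteRecord], diagnoses: dict[str, list[str]]) -> list[NoteRecord]:
    """Merge separately stored diagnosis codes onto notes by hadm_id."""
    out = []
    for rec in records:
        extra = diagnoses.get(rec.hadm_id, [])
        merged = list(dict.fromkeys(rec.icd9_codes + extra))
        out.append(
            NoteRecord(rec.note_id, rec.subject_id, rec.hadm_id, rec.category, merged, rec.text)
        )
    return out


def filter_by_icd9(records: Sequence[NoteRecord], codes: set[str]) -> list[NoteRecord]:
    """Retain exactly the records whose icd9_codes intersect ``codes``.

    This is the optional metadata prescreen (e.g. ICD-9 E935.2, opioids
    causing adverse effects in therapeutic use); order is preserved and the
    operation is idempotent.
    """
    if not codes:
        raise ValueError("codes must be non-empty")
    return [rec for rec in records if set(rec.icd9_codes) & codes]


# ---------------------------------------------------------------------------
# gold labels
# ---------------------------------------------------------------------------


def write_gold(labels: Iterable[GoldLabel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["note_id", "has_orade", "generic_drug", "ae_preferred_term", "out_of_window"])
        for lab in labels:
            if lab.pairs:
                for p in lab.pairs:
                    writer.writerow(
                        [lab.note_id, int(lab.has_orade), p.generic_drug, p.ae_preferred_term, int(p.out_of_window)]
                    )
            else:
                writer.writerow([lab.note_id, int(lab.has_orade), "", "", ""])


def read_gold(path: str | Path) -> list[GoldLabel]:
    by_note: dict[str, GoldLabel] = {}
    order: list[str] = []
    with open(path, encoding="utf-8", errors="strict") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            nid = row["note_id"]
            if nid not in by_note:
                by_note[nid] = GoldLabel(note_id=nid, has_orade=bool(int(row["has_orade"])))
                order.append(nid)
            if row.get("generic_drug"):
                by_note[nid].pairs.append(
                    GoldPair(
                        generic_drug=row["generic_drug"],
                        ae_preferred_term=row["ae_preferred_term"],
                        out_of_window=bool(int(row["out_of_window"] or 0)),
                    )
                )
    return [by_note[n] for n in order]


# ---------------------------------------------------------------------------
# candidate pairs
# ---------------------------------------------------------------------------

_PAIR_COLUMNS = [
    "note_id",
    "drug_surface",
    "generic_drug",
    "drug_class",
    "drug_kind",
    "drug_sentence",
    "drug_start",
    "drug_end",
    "ae_surface",
    "ae_pt",
    "ae_llt",
    "ae_unmapped",
    "ae_negated",
    "ae_sentence",
    "ae_start",
    "ae_end",
    "rule",
    "trigger_used",
    "sentence_distance",
    "drug_distance",
    "section",
    "filtered",
    "filter_reason",
]


def write_pairs(pairs: Iterable[CandidateORADE], path: str | Path) -> None:
    """Serialize candidate pairs to CSV with full provenance columns."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PAIR_COLUMNS)
        for p in pairs:
            writer.writerow(
                [
                    p.note_id,
                    p.drug.surface,
                    p.generic_drug,
                    p.drug_class,
                    p.drug_kind,
                    p.drug.sentence_index,
                    p.drug.start,
                    p.drug.end,
                    p.ae.surface,
                    p.ae_pt,
                    p.ae_llt or "",
                    int(p.ae.unmapped),
                    int(p.ae.negated),
                    p.ae.sentence_index,
                    p.ae.start,
                    p.ae.end,
                    p.rule,
                    p.trigger_used or "",
                    p.sentence_distance,
                    p.drug_distance,
                    p.section or "",
                    int(p.filtered),
                    p.filter_reason or "",
                ]
            )


def read_pairs(path: str | Path) -> list[CandidateORADE]:
    """Inverse of :func:`write_pairs`."""
    out: list[CandidateORADE] = []
    with open(path, encoding="utf-8", errors="strict") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _PAIR_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise CorpusFormatError(f"pairs CSV is missing columns: {missing}")
        for row in reader:
            drug = EntityMention(
                note_id=row["note_id"],
                sentence_index=int(row["drug_sentence"]),
                start=int(row["drug_start"]),
                end=int(row["drug_end"]),
                surface=row["drug_surface"],
                entity_type="opioid_drug",
                normalized=row["generic_drug"],
                drug_class=row["drug_class"],
                drug_kind=row["drug_kind"],
            )
            ae = EntityMention(
                note_id=row["note_id"],
                sentence_index=int(row["ae_sentence"]),
                start=int(row["ae_start"]),
                end=int(row["ae_end"]),
                surface=row["ae_surface"],
                entity_type="adverse_event",
                normalized=row["ae_pt"],
                ae_llt=row["ae_llt"] or None,
                unmapped=bool(int(row["ae_unmapped"])),
                negated=bool(int(row["ae_negated"])),
            )
            out.append(
                CandidateORADE(
                    note_id=row["note_id"],
                    drug=drug,
                    ae=ae,
                    generic_drug=row["generic_drug"],
                    drug_class=row["drug_class"],
                    drug_kind=row["drug_kind"],
                    ae_pt=row["ae_pt"],
                    ae_llt=row["ae_llt"] or None,
                    rule=row["rule"],
                    trigger_used=row["trigger_used"] or None,
                    sentence_distance=int(row["sentence_distance"]),
                    drug_distance=int(row["drug_distance"]),
                    section=row["section"] or None,
                    filtered=bool(int(row["filtered"])),
                    filter_reason=row["filter_reason"] or None,
                )
            )
    return out


_FRAME_COLUMNS = [
    "note_id",
    "drug_surface",
    "generic_drug",
    "drug_class",
    "drug_kind",
    "ae_surface",
    "ae_pt",
    "ae_llt",
    "rule",
    "trigger_used",
    "sentence_distance",
    "drug_distance",
    "section",
    "filtered",
    "filter_reason",
]


def pairs_to_frame(pairs: Sequence[CandidateORADE]) -> pd.DataFrame:
    """Candidate pairs as a tidy DataFrame (one row per pair)."""
    rows = [
        {
            "note_id": p.note_id,
            "drug_surface": p.drug.surface,
            "generic_drug": p.generic_drug,
            "drug_class": p.drug_class,
            "drug_kind": p.drug_kind,
            "ae_surface": p.ae.surface,
            "ae_pt": p.ae_pt,
            "ae_llt": p.ae_llt,
            "rule": p.rule,
            "trigger_used": p.trigger_used,
            "sentence_distance": p.sentence_distance,
            "drug_distance": p.drug_distance,
            "section": p.section,
            "filtered": p.filtered,
            "filter_reason": p.filter_reason,
        }
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=_FRAME_COLUMNS)
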