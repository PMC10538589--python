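"""Section detection and sentence segmentation for discharge summaries.

Only three narrative sections are analyzed by default — "brief hospital
course", "hospital course", and "history of present illness" — because these
carry the bulk of adverse-event narrative in discharge summaries.  Text
outside recognized sections is excluded unless ``scan_whole_note`` is set.

Offsets are 0-based half-open character positions into the original note
text; every downstream span shares this convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

CANONICAL_SECTIONS = (
    "brief_hospital_course",
    "hospital_course",
    "history_of_present_illness",
)

#: default header variants (pattern, canonical name); patterns are matched
#: case-insensitively at the beginning of a line, with an optional colon.
DEFAULT_HEADER_CONFIG: list[tuple[str, str]] = [
    ("brief hospital course", "brief_hospital_course"),
    ("hospital course", "hospital_course"),
    ("hospital course by systems", "hospital_course"),
    ("hospital course by system", "hospital_course"),
    ("summary of hospital course", "hospital_course"),
    ("history of present illness", "history_of_present_illness"),
    ("history of the present illness", "history_of_present_illness"),
    ("hpi", "history_of_present_illness"),
]


@dataclass(frozen=True)
class SectionSpan:
    canonical_name: str
    header_text: str
    start: int  # first character of section content
    end: int  # start of the next recognized header, or end of note


@dataclass(frozen=True)
class SentenceSpan:
    sentence_index: int  # 0-based, global over the note's extracted sections
    section: str
    start: int
    end: int
    text: str


# a line that looks like some section header: short, ends with a colon, no
# sentence punctuation before the colon.  Used only to terminate sections.
_GENERIC_HEADER_RE = re.compile(r"^\s*[A-Za-z][^.:!?\n]{0,60}:\s*$")


def _compile_headers(header_config: Sequence[tuple[str, str]]):
    # longest patterns first so "brief hospital course" beats "hospital course"
    ordered = sorted(header_config, key=lambda pc: -len(pc[0]))
    compiled = []
    for pattern, canonical in ordered:
        rx = re.compile(
            r"^\s*" + re.escape(pattern).replace(r"\ ", r"\s+") + r"\s*(:|\n|$)",
            re.IGNORECASE,
        )
        compiled.append((rx, canonical))
    return compiled


def detect_sections(
    text: str,
    header_config: Sequence[tuple[str, str]] | None = None,
    scan_whole_note: bool = False,
) -> list[SectionSpan]:
    """Locate target sections in a note.

    A section starts after its header line (or after the colon if prose
    follows on the same line) and ends at the next line that looks like a
    header — either another target header or any short ``Something:`` line —
    or at the end of the note.  A note with no recognized header yields an
    empty list unless ``scan_whole_note`` is set, in which case the whole
    note is returned as one ``whole_note`` pseudo-section.
    """
    if header_config is None:
        header_config = DEFAULT_HEADER_CONFIG
    if not header_config:
        raise ValueError("header_config must be non-empty")
    compiled = _compile_headers(header_config)

    # line offsets
    lines: list[tuple[int, str]] = []
    pos = 0
    for line in text.splitlines(keepends=True):
        lines.append((pos, line))
        pos += len(line)

    sections: list[SectionSpan] = []
    open_section: Optional[dict] = None

    def close(at: int) -> None:
        nonlocal open_section
        if open_section is not None:
            start, end = open_section["start"], at
            if start < end:
                sections.append(
                    SectionSpan(
                        canonical_name=open_section["canonical"],
                        header_text=open_section["header"],
                        start=start,
                        end=end,
                    )
                )
            open_section = None

    for line_start, line in lines:
        target = None
        for rx, canonical in compiled:
            m = rx.match(line)
            if m:
                target = (m, canonical)
                break
        if target is not None:
            m, canonical = target
            close(line_start)
            # content begins after the matched header (and colon); if the
            # rest of the line is blank, it begins on the next line.
            content_start = line_start + m.end()
            open_section = {
                "canonical": canonical,
                "header": line[: m.end()].rstrip("\n"),
                "start": content_start,
            }
        elif _GENERIC_HEADER_RE.match(line):
            close(line_start)
    close(len(text))

    if not sections and scan_whole_note and text.strip():
        return [SectionSpan("whole_note", "", 0, len(text))]
    return sections


_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s|$)")
_PLACEHOLDER_RE = re.compile(r"\[\*\*.*?\*\*\]")
_TRAILING_TOKEN_RE = re.compile(r"([A-Za-z](?:[A-Za-z.])*)$")


def split_sentences(
    section: SectionSpan,
    note_text: str,
    abbreviations: Sequence[str] | None = None,
) -> list[SentenceSpan]:
    """Segment one section into sentences.

    Boundaries fall after runs of sentence-final punctuation (``. ! ?``)
    followed by whitespace, except inside decimal numbers, inside
    de-identification placeholders ``[** ... **]``, and after known
    abbreviations (e.g. ``q.``, ``mg.``, ``Dr.``).  Blank lines and
    ``#``-prefixed list items force boundaries.  Sentence indexes here are
    local (0-based within the section); :func:`segment_note` renumbers them
    globally.
    """
    abbrev_set = {a.casefold().rstrip(".") for a in (abbreviations or ())}
    seg = note_text[section.start : section.end]
    protected = [(m.start(), m.end()) for m in _PLACEHOLDER_RE.finditer(seg)]

    def in_placeholder(i: int) -> bool:
        return any(s <= i < e for s, e in protected)

    boundaries: set[int] = set()
    for m in _BOUNDARY_RE.finditer(seg):
        if in_placeholder(m.start()):
            continue
        # decimal guard: digit '.' digit has no following whitespace, so it
        # never reaches here; guard anyway for "1." list markers mid-number
        before = seg[: m.start()]
        tok = _TRAILING_TOKEN_RE.search(before)
        if tok and tok.group(1).casefold().rstrip(".") in abbrev_set:
            continue
        boundaries.add(m.end())
    # blank lines force boundaries; '#'-prefixed lines start new sentences
    for m in re.finditer(r"\n[ \t]*\n", seg):
        boundaries.add(m.start())
    for m in re.finditer(r"\n(?=[ \t]*#)", seg):
        boundaries.add(m.start())

    cuts = sorted(b for b in boundaries if 0 < b < len(seg))
    pieces = []
    prev = 0
    for cut in cuts + [len(seg)]:
        pieces.append((prev, cut))
        prev = cut

    out: list[SentenceSpan] = []
    for raw_start, raw_end in pieces:
        chunk = seg[raw_start:raw_end]
        stripped = chunk.strip()
        if not stripped:
            continue
        lead = len(chunk) - len(chunk.lstrip())
        start = section.start + raw_start + lead
        end = start + len(stripped)
        out.append(
            SentenceSpan(
                sentence_index=len(out),
                section=section.canonical_name,
                start=start,
                end=end,
                text=note_text[start:end],
            )
        )
    return out


def segment_note(
    text: str,
    header_config: Sequence[tuple[str, str]] | None = None,
    abbreviations: Sequence[str] | None = None,
    scan_whole_note: bool = False,
) -> tuple[list[SectionSpan], list[SentenceSpan]]:
    """Detect sections and segment them, assigning global sentence indexes
    in document order."""
    sections = detect_sections(text, header_config, scan_whole_note=scan_whole_note)
    sentences: list[SentenceSpan] = []
    for section in sections:
        for sent in split_sentences(section, text, abbreviations):
            sentences.append(
                SentenceSpan(
                    sentence_index=len(sentences),
                    section=sent.section,
                    start=sent.start,
                    end=sent.end,
                    text=sent.text,
                )
            )
    return sections, sentences
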