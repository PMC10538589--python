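"""Section detection and clinical sentence segmentation."""

import random
import re

import pytest
from hypothesis import given, settings, strategies as st

from oradex.preprocess import (
    DEFAULT_HEADER_CONFIG,
    SectionSpan,
    detect_sections,
    segment_note,
    split_sentences,
)

ANTIDOTE_PASSAGE = (
    "He received dilaudid q 2 hr at 7:30 am, 9:30 am, 11:30 am. "
    "Code blue was called for respiratory arrest (unwitnessed). "
    "0.4 mg of Narcan IV was administered followed by 1 mg of IV Narcan. "
    "This resulted in improvement of his respiratory status and regain of his consciousness."
)


@pytest.fixture()
def abbrevs(bundle):
    return bundle.abbreviations


class TestDetectSections:
    def test_single_section_ends_at_next_header(self):
        text = (
            "HISTORY OF PRESENT ILLNESS:\nSome prose here. More prose.\n"
            "DISCHARGE MEDICATIONS:\n1. Senna.\n"
        )
        spans = detect_sections(text)
        assert [s.canonical_name for s in spans] == ["history_of_present_illness"]
        content = text[spans[0].start : spans[0].end]
        assert "Some prose here" in content and "Senna" not in content

    def test_empty_text_yields_no_sections(self):
        assert detect_sections("") == []

    def test_brief_variant_beats_plain_hospital_course(self):
        text = "BRIEF HOSPITAL COURSE:\nStuff happened.\n"
        spans = detect_sections(text)
        assert [s.canonical_name for s in spans] == ["brief_hospital_course"]

    def test_scan_whole_note_fallback(self):
        text = "No headers at all. Just prose."
        assert detect_sections(text) == []
        spans = detect_sections(text, scan_whole_note=True)
        assert len(spans) == 1 and spans[0].start == 0 and spans[0].end == len(text)

    def test_randomized_headers_match_line_scanning_oracle(self):
        """100 synthetic notes, random header order/casing, versus an
        independent line-scan oracle over the same header set."""
        rng = random.Random(11)
        headers = [(p, c) for p, c in DEFAULT_HEADER_CONFIG if p != "hpi"]
        for _ in range(100):
            chosen = rng.sample(headers, rng.randint(1, 4))
            lines = ["Admission Date: [**2101-1-1**]", ""]
            for pattern, _canonical in chosen:
                lines.append(rng.choice([pattern.upper(), pattern.title()]) + ":")
                for _ in range(rng.randint(1, 3)):
                    lines.append("Filler prose sentence number %d." % rng.randint(0, 9))
                if rng.random() < 0.5:
                    lines.append("DISCHARGE DIAGNOSIS:")
                    lines.append("Something.")
            text = "\n".join(lines) + "\n"
            spans = detect_sections(text)
            oracle = self._line_scan_oracle(text)
            assert [(s.canonical_name, s.start, s.end) for s in spans] == oracle

    @staticmethod
    def _line_scan_oracle(text):
        """Independent reimplementation: scan lines; a target header line
        opens a section; any short 'Xxx:' line closes it."""
        by_pattern = sorted(DEFAULT_HEADER_CONFIG, key=lambda pc: -len(pc[0]))
        out = []
        open_sec = None
        pos = 0
        for line in text.splitlines(keepends=True):
            stripped = line.rstrip("\n")
            matched = None
            for pattern, canonical in by_pattern:
                if stripped.lower().startswith(pattern) and stripped[len(pattern):] in (":", ""):
                    matched = (canonical, pos + len(pattern) + (1 if stripped.endswith(":") else 0))
                    break
            is_generic = re.match(r"^\s*[A-Za-z][^.:!?\n]{0,60}:\s*$", line)
            if matched:
                if open_sec:
                    out.append((open_sec[0], open_sec[1], pos))
                open_sec = matched
            elif is_generic and open_sec:
                out.append((open_sec[0], open_sec[1], pos))
                open_sec = None
            pos += len(line)
        if open_sec:
            out.append((open_sec[0], open_sec[1], len(text)))
        return [(c, s, e) for c, s, e in out if s < e]


class TestSplitSentences:
    def _split(self, body, abbrevs):
        section = SectionSpan("hospital_course", "", 0, len(body))
        return split_sentences(section, body, abbrevs)

    def test_antidote_passage_splits_into_four_sentences(self, abbrevs):
        sents = self._split(ANTIDOTE_PASSAGE, abbrevs)
        assert len(sents) == 4
        assert sents[0].text.endswith("11:30 am.")
        assert sents[2].text.startswith("0.4 mg")  # decimal not split

    def test_single_terminal_period(self, abbrevs):
        sents = self._split("No further apneic events.", abbrevs)
        assert [s.text for s in sents] == ["No further apneic events."]

    def test_bare_letters_split_without_abbreviation_matches(self, abbrevs):
        sents = self._split("a. b. c.", abbrevs)
        assert [s.text for s in sents] == ["a.", "b.", "c."]

    def test_abbreviations_suppress_boundaries(self, abbrevs):
        sents = self._split("Seen by Dr. Smith today. Plan unchanged.", abbrevs)
        assert len(sents) == 2
        assert sents[0].text == "Seen by Dr. Smith today."

    def test_placeholder_is_atomic(self, abbrevs):
        body = "Discharged on [**2173-8-28**] in stable condition. Follow up arranged."
        sents = self._split(body, abbrevs)
        assert len(sents) == 2
        assert "[**2173-8-28**]" in sents[0].text

    def test_blank_lines_and_hash_items_force_boundaries(self, abbrevs):
        body = "First problem addressed\n\n# Constipation: treated aggressively\n# Pain: controlled"
        sents = self._split(body, abbrevs)
        assert len(sents) == 3

    def test_sentences_cover_all_non_whitespace(self, abbrevs):
        body = ANTIDOTE_PASSAGE + "\nShe was seen by Dr. Jones at 0.5 mg dosing. Final line."
        sents = self._split(body, abbrevs)
        covered = "".join(s.text for s in sents)
        assert sorted(covered.replace(" ", "")) == sorted(
            body.replace(" ", "").replace("\n", "")
        )
        for s in sents:
            assert body[s.start : s.end] == s.text

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="ab .!?\n#[]*0123456789", max_size=200))
    def test_coverage_property_on_arbitrary_text(self, body):
        section = SectionSpan("hospital_course", "", 0, len(body))
        sents = split_sentences(section, body, [])
        joined = "".join(s.text for s in sents)
        stripped = re.sub(r"\s", "", body)
        assert re.sub(r"\s", "", joined) == stripped
        for prev, cur in zip(sents, sents[1:]):
            assert prev.end <= cur.start
        assert [s.sentence_index for s in sents] == list(range(len(sents)))


class TestSegmentNote:
    def test_global_indexes_are_a_bijection(self, abbrevs):
        text = (
            "HISTORY OF PRESENT ILLNESS:\nOne. Two. Three.\n\n"
            "HOSPITAL COURSE:\nFour. Five.\n\nDISCHARGE MEDICATIONS:\nIgnored. Lines.\n"
        )
        _, sents = segment_note(text, abbreviations=abbrevs)
        assert [s.sentence_index for s in sents] == list(range(5))
        assert {s.section for s in sents} == {"history_of_present_illness", "hospital_course"}

    def test_unrelated_header_does_not_perturb_other_sections(self, abbrevs):
        base = "HOSPITAL COURSE:\nAlpha one. Beta two.\n\n"
        _, before = segment_note(base, abbreviations=abbrevs)
        _, after = segment_note(base + "DISCHARGE CONDITION:\nStable.\n", abbreviations=abbrevs)
        assert [(s.text, s.start, s.end) for s in before] == [
            (s.text, s.start, s.end) for s in after
        ]
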