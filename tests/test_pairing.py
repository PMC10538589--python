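"""Pairing rules, context-window semantics, audit filters, aggregation."""

import numpy as np
import pytest

from oradex.corpus_io import NoteRecord
from oradex.extract import detect_negation, match_entities
from oradex.pairing import (
    PairingConfig,
    aggregate_pairs,
    apply_antidote_rule,
    apply_filters,
    apply_trigger_rule,
    unfiltered,
)
from oradex.preprocess import SectionSpan, split_sentences


def _prep(text, bundle, note_id="n1"):
    section = SectionSpan("hospital_course", "", 0, len(text))
    sents = split_sentences(section, text, bundle.abbreviations)
    mentions = detect_negation(match_entities(sents, bundle, note_id=note_id), sents, bundle)
    return mentions, sents


# ---------------------------------------------------------------------------
# independent brute-force oracle
# ---------------------------------------------------------------------------


def _window_ok(a, b, window, sections):
    return abs(a - b) <= window and sections[a] == sections[b]


def _oracle_pairs(mentions, sentences, window, rule):
    """Enumerate every (anchor, drug, AE) triple within the window and keep
    the minimal distances per (drug span, AE span)."""
    sections = {s.sentence_index: s.section for s in sentences}
    drugs = [m for m in mentions if m.entity_type == "opioid_drug"]
    aes = [m for m in mentions if m.entity_type == "adverse_event"]
    if rule == "trigger_phrase":
        anchors = [m.sentence_index for m in mentions if m.entity_type == "trigger_phrase"]
    else:
        anchors = [m.sentence_index for m in mentions if m.entity_type == "antidote"]
    best = {}
    for anchor in anchors:
        for d in drugs:
            if not _window_ok(anchor, d.sentence_index, window, sections):
                continue
            for a in aes:
                if not _window_ok(anchor, a.sentence_index, window, sections):
                    continue
                key = (d.start, d.end, a.start, a.end)
                dist = (abs(anchor - a.sentence_index), abs(anchor - d.sentence_index))
                if key not in best or dist < best[key]:
                    best[key] = dist
    return {k: v for k, v in best.items()}


def _as_dict(pairs):
    return {
        (p.drug.start, p.drug.end, p.ae.start, p.ae.end): (p.sentence_distance, p.drug_distance)
        for p in pairs
    }


def _random_note_text(rng, bundle):
    """Random sequence of sentences with planted drug/trigger/AE/antidote."""
    drugs = [d.surface for d in bundle.drugs]
    aes = sorted(bundle.synonym_to_concept)
    triggers = [t.phrase for t in bundle.triggers]
    sentences = []
    for _ in range(rng.integers(3, 12)):
        kind = rng.choice(["filler", "drug", "ae", "trigger", "antidote", "drug_ae"])
        if kind == "filler":
            sentences.append("The day was uneventful overall")
        elif kind == "drug":
            sentences.append(f"He received {drugs[rng.integers(len(drugs))]} as scheduled")
        elif kind == "ae":
            sentences.append(f"Nursing documented {aes[rng.integers(len(aes))]} overnight")
        elif kind == "trigger":
            sentences.append(f"This was {triggers[rng.integers(len(triggers))]} the regimen")
        elif kind == "antidote":
            sentences.append("Narcan was administered at that time")
        else:
            sentences.append(
                f"He got {drugs[rng.integers(len(drugs))]} and then "
                f"{aes[rng.integers(len(aes))]} occurred"
            )
    return ". ".join(sentences) + "."


@pytest.mark.parametrize("rule_name,apply_rule", [
    ("trigger_phrase", apply_trigger_rule),
    ("antidote", apply_antidote_rule),
])
def test_rules_match_brute_force_oracle_on_200_random_notes(bundle, rule_name, apply_rule):
    rng = np.random.default_rng(17)
    cfg = PairingConfig(window=3)
    for i in range(200):
        text = _random_note_text(rng, bundle)
        mentions, sents = _prep(text, bundle, note_id=f"n{i}")
        got = _as_dict(apply_rule(mentions, sents, cfg))
        want = _oracle_pairs(mentions, sents, 3, rule_name)
        assert got == want, text


def test_trigger_rule_worked_example(bundle):
    text = (
        "It is noteworthy that the patient had received 0.5 mg Ativan x2 and morphine "
        "earlier in the afternoon and there is a concern that this may have "
        "contributed to his altered mental status."
    )
    mentions, sents = _prep(text, bundle)
    pairs = apply_trigger_rule(mentions, sents)
    assert len(pairs) == 1
    p = pairs[0]
    assert (p.generic_drug, p.ae_pt) == ("morphine", "mental state abnormal")
    assert p.rule == "trigger_phrase" and p.trigger_used == "contributed to"
    assert p.sentence_distance == 0 and p.drug_distance == 0


def test_antidote_rule_worked_example(bundle):
    text = (
        "He received dilaudid q 2 hr at 7:30 am, 9:30 am, 11:30 am. "
        "Code blue was called for respiratory arrest (unwitnessed). "
        "0.4 mg of Narcan IV was administered followed by 1 mg of IV Narcan. "
        "This resulted in improvement of his respiratory status and regain of his consciousness."
    )
    mentions, sents = _prep(text, bundle)
    pairs = apply_antidote_rule(mentions, sents)
    assert len(pairs) == 1
    p = pairs[0]
    assert p.drug.surface.lower() == "dilaudid"
    assert (p.generic_drug, p.ae_pt) == ("hydromorphone", "respiratory arrest")
    assert p.rule == "antidote"
    assert p.drug_distance == 2 and p.sentence_distance == 1


def test_no_trigger_no_pairs(bundle):
    mentions, sents = _prep("He received morphine. Nausea was documented.", bundle)
    assert apply_trigger_rule(mentions, sents) == []


def test_antidote_without_opioid_in_window_yields_nothing(bundle):
    text = (
        "Narcan was given empirically. " + "The day passed. " * 5
        + "Later he received morphine without incident."
    )
    mentions, sents = _prep(text, bundle)
    assert apply_antidote_rule(mentions, sents, PairingConfig(window=3)) == []


def test_shrinking_window_never_adds_pairs(bundle):
    rng = np.random.default_rng(23)
    for i in range(40):
        text = _random_note_text(rng, bundle)
        mentions, sents = _prep(text, bundle)
        prev = None
        for window in (4, 3, 2, 1, 0):
            cur = set(_as_dict(apply_trigger_rule(mentions, sents, PairingConfig(window=window))))
            cur |= set(_as_dict(apply_antidote_rule(mentions, sents, PairingConfig(window=window))))
            if prev is not None:
                assert cur <= prev
            prev = cur


def test_windows_do_not_cross_sections_by_default(bundle):
    text = (
        "HISTORY OF PRESENT ILLNESS:\nHe was on morphine at home.\n\n"
        "BRIEF HOSPITAL COURSE:\nThis admission was complicated by hypotension.\n"
    )
    from oradex.preprocess import segment_note

    _, sents = segment_note(text, abbreviations=bundle.abbreviations)
    mentions = detect_negation(match_entities(sents, bundle, note_id="n1"), sents, bundle)
    assert apply_trigger_rule(mentions, sents, PairingConfig(window=3)) == []
    crossed = apply_trigger_rule(mentions, sents, PairingConfig(window=3, cross_section_windows=True))
    assert len(crossed) == 1


class TestFilters:
    def _run(self, text, bundle):
        mentions, sents = _prep(text, bundle)
        pairs = apply_trigger_rule(mentions, sents) + apply_antidote_rule(mentions, sents)
        return apply_filters(pairs, mentions, sents, bundle=bundle), pairs

    def test_pain_indication_flagged(self, bundle):
        flagged, _ = self._run(
            "She was given fentanyl for the back pain with subsequent hypotension.", bundle
        )
        reasons = {(p.generic_drug, p.ae_pt): p.filter_reason for p in flagged}
        assert reasons[("fentanyl", "back pain")] == "pain_indication"
        assert reasons[("fentanyl", "hypotension")] is None

    def test_medication_change_flags_switch_target_only(self, bundle):
        flagged, _ = self._run(
            "She was changed from Percocet to Ultram due to nausea, which resolved.", bundle
        )
        reasons = {(p.generic_drug, p.ae_pt): p.filter_reason for p in flagged}
        assert reasons[("tramadol", "nausea")] == "medication_change"
        # the switch-source drug keeps its candidate pair
        assert reasons[("oxycodone", "nausea")] is None

    def test_negated_ae_flagged(self, bundle):
        flagged, _ = self._run(
            "He remained on oxycodone overnight. There was concern that this "
            "contributed to apnea. No further apneic events.",
            bundle,
        )
        by_surface = {p.ae.surface: p.filter_reason for p in flagged}
        assert by_surface["apneic events"] == "negated_ae"
        assert by_surface["apnea"] is None

    def test_filters_flag_but_never_delete(self, bundle):
        flagged, before = self._run(
            "She was given fentanyl for the back pain with subsequent hypotension.", bundle
        )
        assert len(flagged) == len(before)
        assert {(p.drug.start, p.ae.start) for p in flagged} == {
            (p.drug.start, p.ae.start) for p in before
        }
        assert set(unfiltered(flagged)) <= set(flagged)

    def test_clean_pair_unflagged(self, bundle):
        flagged, _ = self._run("Morphine likely contributed to his somnolence.", bundle)
        assert len(flagged) == 1 and not flagged[0].filtered

    def test_disabled_filters_are_skipped(self, bundle):
        mentions, sents = _prep(
            "She was given fentanyl for the back pain with subsequent hypotension.", bundle
        )
        pairs = apply_trigger_rule(mentions, sents)
        cfg = PairingConfig(filters_enabled=frozenset({"negated_ae"}))
        flagged = apply_filters(pairs, mentions, sents, cfg, bundle=bundle)
        assert all(not p.filtered for p in flagged)


class TestAggregate:
    def _pairs_for(self, texts_by_note, bundle):
        out = []
        for (note_id, text) in texts_by_note:
            mentions, sents = _prep(text, bundle, note_id=note_id)
            pairs = apply_trigger_rule(mentions, sents) + apply_antidote_rule(mentions, sents)
            out.extend(apply_filters(pairs, mentions, sents, bundle=bundle))
        return out

    def test_two_note_example_counts(self, bundle):
        notes = [
            NoteRecord("n1", "s1", text=""),
            NoteRecord("n2", "s2", text=""),
        ]
        pairs = self._pairs_for(
            [
                ("n1", "Morphine likely contributed to his nausea."),
                ("n2", "He was on fentanyl. Hypotension ensued. Narcan was given."),
            ],
            bundle,
        )
        table = aggregate_pairs(pairs, notes)
        assert list(table["total"]) == [2, 2, 2, 2, 2]
        assert list(table["trigger_phrase"]) == [1, 1, 1, 1, 1]
        assert list(table["antidote_only"]) == [1, 1, 1, 1, 1]
        assert list(table["both"]) == [0, 0, 0, 0, 0]

    def test_no_pairs_all_zero(self, bundle):
        table = aggregate_pairs([], [NoteRecord("n1", "s1")])
        assert (table.to_numpy() == 0).all()

    def test_same_pair_two_notes_one_patient(self, bundle):
        notes = [NoteRecord("n1", "s1", text=""), NoteRecord("n2", "s1", text="")]
        pairs = self._pairs_for(
            [
                ("n1", "Morphine likely contributed to his nausea."),
                ("n2", "Morphine likely contributed to his nausea."),
            ],
            bundle,
        )
        table = aggregate_pairs(pairs, notes)
        assert table.loc["unique_candidate_pairs", "total"] == 1
        assert table.loc["discharge_summaries", "total"] == 2
        assert table.loc["unique_patients", "total"] == 1
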