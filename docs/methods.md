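# Methods

## Problem and pipeline

`oradex` screens free-text hospital discharge summaries for candidate
opioid-related adverse drug events (ORADEs): hypothetical (drug, adverse
event) pairs documented in the narrative, produced for pharmacovigilance
triage, not causality assessment. The pipeline is deliberately rule-based
and fully inspectable:

1. **Section targeting.** Only three narrative sections are scanned —
   *brief hospital course*, *hospital course*, and *history of present
   illness* — the sections of a discharge summary that carry most
   adverse-event narrative. A section opens at a recognized header line
   (case-insensitive, optional colon, line-initial) and closes at the next
   header-like line (`Something:` with no sentence punctuation) or end of
   note. Notes lacking all three headers yield nothing unless
   `scan_whole_note` is set, which treats the whole note as one
   pseudo-section.
2. **Sentence segmentation** (below).
3. **Entity matching.** Opioid drugs (brand and generic surfaces mapped to
   generics with class labels), antidotes (naloxone/Narcan), trigger
   phrases, and adverse-event terms are matched per sentence:
   case-insensitive, word-boundary anchored, multi-word phrases as token
   sequences, longest match first, leftmost wins ties, non-overlapping
   within a type. Tokens are alphanumeric runs; hyphens split;
   de-identification placeholders `[** ... **]` are atomic tokens.
4. **Negation flagging** (below).
5. **Pairing rules** with a ±`window` sentence context (default 3).
6. **Audit filters** that flag, never delete, likely false positives.
7. **Scoring and report tables.**

## Sentence segmentation

A boundary falls after a run of `. ! ?` followed by whitespace, except:

- inside decimal numbers (`0.4 mg` — the period is not followed by
  whitespace);
- inside de-identification placeholders;
- after a token in the packaged abbreviation list (`q.`, `mg.`, `Dr.`,
  `e.g.`, …).

Blank lines and `#`-prefixed problem-list items force boundaries. Sentences
never cross section boundaries, and every non-whitespace character of a
section belongs to exactly one sentence (a tested invariant).

Time-of-day tokens (`am`, `pm`) are deliberately **not** in the suppression
list: in clinical narrative a dosing-schedule sentence very often ends at a
time expression ("… at 7:30 am, 9:30 am, 11:30 am. Code blue was called…"),
and suppressing that boundary would merge a dosing sentence into the
adverse-event sentence that follows, corrupting sentence distances. The
cost — a false join such as "7 a.m. Vitals were stable" being split — is
minor because the window spans several sentences anyway.

## Adverse-event recognition and normalization

The AE recognizer is a pluggable contract (sentence text → candidate
character spans). The shipped default is a dictionary matcher over a
packaged synonym table; any external model can be substituted via
`--ae-recognizer external:<command>` (spans on stdout, tab-separated)
without touching pipeline semantics.

Normalization (`normalize_ae`) maps a raw phrase to a MedDRA-style
preferred term (PT) and optional lower-level term (LLT): case fold → strip
punctuation → collapse whitespace → expand known abbreviations (e.g. `AMS`)
→ exact synonym lookup. Optional fuzzy matching (difflib ratio ≥ a
user-set threshold, deterministic tie-break on the lexicographically
smallest synonym) is off by default: determinism is preferred over recall.
Unmapped spans are kept and flagged, never silently guessed. The packaged
vocabulary is a small synthetic MedDRA-style table (~28 concepts covering
the opioid ADE domain: hypotension, somnolence, respiratory depression,
mental state abnormal, apnoea, …). Licensed MedDRA/UMLS resources cannot be
redistributed; a licensed mapper can be swapped in behind the same lookup.

## Negation

An adverse-event mention is negated when a negation cue ("no", "no
further", "denies", "without", "negative for", …) precedes it in the same
sentence with no termination cue ("but", "however", …) between cue and
mention — the standard ConText forward scope for these cue types. Scope is
intra-sentential only, and only adverse-event mentions are flagged. The
pass is a pure flag toggle (idempotent; spans untouched).

## Pairing rules

**Trigger-phrase rule.** Anchors are sentences containing a trigger phrase
with at least one opioid mention in the same sentence or within ±window
sentences of it (same section). For each anchor, every opioid mention and
every adverse-event mention within ±window are exhaustively paired. The
trigger sentence is the anchor from which both distances are measured; this
choice keeps both canonical narratives (same-sentence trigger, and
rescue-narrative follow-up) correct, and the distances are recorded per
pair for audit. The shipped trigger lexicon has 15 base phrases in the
style of the published trigger-tool lists plus 58 curated phrases shipped
as a distinct, replaceable file.

**Antidote rule.** Anchors are sentences mentioning a reversal agent.
Drugs and events within ±window are paired; the antidote itself is never
emitted as drug or event. A naloxone mention is strong indirect evidence
that an opioid adverse event is being described nearby even when no causal
phrase is present.

Duplicates by (drug mention, AE mention) collapse to the smallest
(sentence_distance, drug_distance). A pair found by both rules is retained
once per rule so rule-stratified counts remain possible. All-pairs
enumeration (rather than nearest-only) is used because the narratives of
interest routinely separate drug, event, and anchor; the distance audit
columns let a consumer re-restrict post hoc.

## Audit filters

Filters run in fixed order; the first match sets `filter_reason`; pairs are
flagged, never removed, so the audit trail is complete:

1. `pain_indication` — the AE surface or PT contains a pain token
   (token-wise). Pain terms paired with analgesics are overwhelmingly the
   *indication*, not the event.
2. `medication_change` — the AE's or the drug's sentence contains a
   change/switch construction (`change(d|ing)/switch(ed|ing) [from X] to Y`,
   matched by regular expression, target resolved against the drug
   lexicon) and the paired drug is the switch **target**: the reason for
   switching *to* a drug cannot have been caused by it. The switch-source
   drug's pairs are untouched — they remain legitimate candidates.
3. `negated_ae` — the AE mention is negated.

## Evaluation

Note-level scoring: a note is predicted positive when it carries ≥1
unfiltered pair; confusion counts over the gold labels give accuracy
(tp+tn)/N, precision tp/(tp+fp), recall tp/(tp+fn), F1 = 2PR/(P+R). Metrics
are exact `Fraction`s internally; a zero denominator yields an explicit
undefined marker (`None`), and rounding (2 decimals) happens only at
presentation. Pair-level scoring matches (note, generic drug, PT) tuples
after case folding; true negatives are undefined at pair level. Filtered
pairs are excluded from predictions by default, with a flag to include
them.

Aggregate counts are stratified by rule — found by the trigger rule,
found only by the antidote rule, found by both, and the union — with
uniqueness defined as: drug = generic name (brands collapse), AE = PT,
pair = (generic, PT), plus distinct note and patient counts.

## Synthetic corpus generator

The generator emulates the *lexical structure* that the extractor keys on:
three canonical sections with decoy headers, de-identification
placeholders, filler prose free of lexicon surfaces, and five plantable
event types realized from slot templates — true trigger-context ORADEs,
antidote rescue narratives, and the three confounders (pain-indication,
medication-switch, negated-event). Event blocks are separated by more
filler sentences than the context window so gold labels stay exact.

Defaults (chosen once as plausible study conditions; rates per note,
independent Bernoulli draws): `p_true_orade` 0.5, `p_antidote_event` 0.15,
`p_indication_confounder` 0.25, `p_switch_confounder` 0.15,
`p_negation_confounder` 0.10 — the confounder ordering mirrors the
qualitative most-common/moderate/rare frequencies seen in error analyses of
this kind of pipeline — and `max_distance` 2 (≤ the default window). With
`max_distance` above the pairing window, out-of-reach plants are recorded
in gold with an `out_of_window` flag so tests can assert the extractor
correctly misses them.

Determinism: each note draws from `default_rng([seed, note_index])`, so a
corpus is byte-identical across runs and a prefix is stable when `n_notes`
grows. Synthetic demographics (uniform age 18–94, gender, ethnicity) are
emitted only to exercise the report backends; no clinical realism is
claimed.

**What passing synthetic tests does and does not show.** The generator's
vocabulary is, by construction, fully covered by the lexicons, sentences
are well-formed, and events are isolated — so near-perfect recall/precision
on synthetic corpora demonstrates the *mechanics* (windows, anchors,
filters, normalization, determinism) are correct, and says nothing about
performance on real discharge summaries, whose misspellings, fragmented
concepts, list-heavy formatting, and out-of-vocabulary drug/event mentions
are exactly where rule-based recall degrades.

## Numerical and degenerate-input choices

- Offsets are 0-based half-open character positions throughout.
- Ties everywhere break deterministically (leftmost/longest matches;
  alphabetical PT in top-k lists after descending count; sorted synonym
  order in fuzzy lookup).
- Empty corpora, empty pair tables, and zero-denominator metrics all
  produce valid empty/undefined outputs rather than errors.
- UTF-8 strict everywhere; undecodable input bytes are a hard error.
- `window=0` is legal (same-sentence co-occurrence only).

## Problem sizes

Synthetic suites use 40–200 notes per corpus (200 for the oracle-
equivalence and recall/suppression checks, smaller for I/O and CLI round
trips); the full test suite and the acceptance script each complete in a
few seconds on one CPU.

## Known limitations

- Dictionary recognition cannot find out-of-vocabulary adverse events; the
  recognizer interface exists precisely so a learned model can replace it.
- Negation handles negation only — no hypothetical, historical, or
  family-history assertion classes.
- Concept fragmentation (drug and event linked only across paragraphs or
  problem-list items) is out of reach of the sentence-window design.
- The generic mention "narcotics" is excluded from the drug lexicon by
  default (it cannot be resolved to a specific opioid); an opt-in switch
  adds it with class `unspecified`.
- Multiple notes per admission are treated independently; no merging.
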