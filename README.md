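# oradex

Rule-based extraction of candidate **opioid-related adverse drug events
(ORADEs)** from free-text hospital discharge summaries, for
pharmacovigilance screening.

Opioids are among the drug classes most often implicated in inpatient
adverse drug reactions (confusion, respiratory depression, hypotension,
constipation, sedation, …), yet much of the evidence lives in unstructured
discharge narrative rather than coded fields. `oradex` screens that
narrative and emits auditable candidate (drug, event) pairs — hypothetical
signals for expert review, not causality claims.

## Method

For each note, the pipeline:

1. locates the three narrative sections that carry most adverse-event
   documentation (*brief hospital course*, *hospital course*, *history of
   present illness*) and segments them into sentences robust to clinical
   abbreviations, decimals, and de-identification placeholders;
2. matches opioid drugs (brand → generic, with natural/semisynthetic/
   synthetic class), antidotes (naloxone/Narcan), trigger phrases, and
   adverse-event terms against packaged lexicons; AE phrases are normalized
   to MedDRA-style preferred terms (PT/LLT) through a synonym table;
3. links drugs to events over a ±3-sentence context window by two rules:
   - **trigger-phrase rule** — anchored on causal cues such as
     "contributed to" or "secondary to" (15 base + 58 curated phrases);
   - **antidote rule** — anchored on naloxone mentions, indirect evidence
     of an opioid adverse event nearby;
4. flags (never deletes) the three classic false-positive patterns:
   pain-indication pairs, medication-switch events, and negated mentions
   (ConText-style cue/termination scope);
5. scores output against gold labels at note level
   (accuracy = (TP+TN)/N, precision = TP/(TP+FP), recall = TP/(TP+FN),
   F1 = 2PR/(P+R)) and pair level, and aggregates rule-stratified counts
   and report tables (per-class/per-drug patient counts, top-k AEs per
   drug, drug × AE chord matrix, demographics, line listings).

A deterministic synthetic note generator plants true ORADE narratives,
naloxone rescues, and each confounder with exact gold labels, so every
stage is testable without access to restricted EHR data. See
[docs/methods.md](docs/methods.md) for the full model description and
its limitations.

## Worked example

```python
from oradex import NoteRecord, load_lexicons, process_note
from oradex.corpus_io import pairs_to_frame

bundle = load_lexicons()
note = NoteRecord(
    note_id="demo-1",
    subject_id="patient-1",
    text="""BRIEF HOSPITAL COURSE:
He received dilaudid q 2 hr at 7:30 am, 9:30 am, 11:30 am. Code blue was
called for respiratory arrest (unwitnessed). 0.4 mg of Narcan IV was
administered followed by 1 mg of IV Narcan. This resulted in improvement of
his respiratory status and regain of his consciousness. No further apneic
events.
""",
)
pairs = process_note(note, bundle)
print(pairs_to_frame(pairs)[["generic_drug", "ae_pt", "rule", "trigger_used",
                             "drug_distance", "sentence_distance", "filtered",
                             "filter_reason"]].to_string(index=False))
```

prints

```
 generic_drug              ae_pt           rule trigger_used  drug_distance  sentence_distance  filtered filter_reason
hydromorphone respiratory arrest trigger_phrase  resulted in              3                  2     False          None
hydromorphone             apnoea trigger_phrase  resulted in              3                  1      True    negated_ae
hydromorphone respiratory arrest       antidote         None              2                  1     False          None
hydromorphone             apnoea       antidote         None              2                  2      True    negated_ae
```

Reading the output: the brand surface *dilaudid* is normalized to
hydromorphone; the naloxone mention anchors the antidote rule two sentences
after the drug and one after *respiratory arrest*; the same pair is also
found via the trigger "resulted in" (rule provenance is kept per rule); and
the negated "no further apneic events" pairs are flagged `negated_ae`
rather than deleted, leaving a complete audit trail. Unfiltered pairs are
candidates for expert review.

## Command line

```bash
oradex simulate --n 200 --seed 7 --out-notes notes.jsonl --out-gold gold.csv
oradex extract  --notes notes.jsonl --out pairs.csv --log run_log.json
oradex evaluate --pairs pairs.csv --gold gold.csv --level note
oradex report   --pairs pairs.csv --notes notes.jsonl --out-dir report/
```

Notes travel as JSONL or as CSV in the MIMIC-III NOTEEVENTS dialect
(`--format mimic_csv`); an optional ICD-9 prescreen (`--icd9 E935.2`)
restricts to notes coded for opioid adverse effects in therapeutic use.
All lexicons are plain CSV/text resources and can be replaced wholesale.

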