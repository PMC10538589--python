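# Sentence templates for the synthetic discharge-summary generator.
# Lines starting with '#' are comments; a line like [name] opens a template
# group; every following non-blank line is one template in that group.
# Slots: {DRUG} {TRIGGER} {AE} {ANTIDOTE}. Filler templates must not contain
# any surface form from the packaged lexicons.

[filler]
Vital signs remained stable throughout the day.
The remainder of the examination was unremarkable.
Laboratory values were within normal limits.
Physical therapy was consulted and worked with the patient.
The patient tolerated a regular diet.
Social work was involved in discharge planning.
Serial electrolytes were monitored and repleted as needed.
The family was updated at the bedside.
Home services were arranged prior to discharge.
The patient remained afebrile overnight.

[drug_intro]
He was started on {DRUG} for postoperative analgesia.
She received scheduled {DRUG} overnight.
The patient was continued on {DRUG} during the admission.
{DRUG} was administered every four hours as needed.

[trigger_anchor]
This was felt {TRIGGER} his {AE}.
Her course was notable for {AE}, {TRIGGER} the above regimen.
He went on to develop {AE}, {TRIGGER} the analgesic regimen.

[trigger_combined]
There was concern that the {DRUG} {TRIGGER} her {AE}.
He developed {AE} {TRIGGER} the {DRUG}.
Her {AE} was noted, {TRIGGER} the {DRUG}.

[ae_event]
He then went on to develop {AE}.
A code was called for {AE}.
Nursing noted {AE} overnight.

[antidote_rescue]
{ANTIDOTE} was administered with rapid improvement.
He required {ANTIDOTE} with good effect.
{ANTIDOTE} was given with prompt response.

[antidote_combined]
He developed {AE} on {DRUG}, requiring {ANTIDOTE}.

[indication]
She was given {DRUG} for her {AE} with subsequent improvement.
He received {DRUG} for {AE} control with subsequent relief.

[switch]
Her regimen was switched to {DRUG} due to {AE}, which resolved.
He was changed to {DRUG} due to {AE}.

[negation_concern]
There was initial concern that the {DRUG} {TRIGGER} her presentation.

[negation_denial]
No further {AE} were noted.
There were no episodes of {AE} overnight.
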