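concept_id,preferred_term,lower_level_term,synonym
C0001,hypotension,low blood pressure,hypotension
C0001,hypotension,low blood pressure,hypotensive
C0001,hypotension,low blood pressure,low blood pressure
C0002,somnolence,drowsiness,somnolence
C0002,somnolence,drowsiness,drowsiness
C0002,somnolence,drowsiness,drowsy
C0002,somnolence,drowsiness,sleepiness
C0003,nausea,,nausea
C0003,nausea,,nauseated
C0003,nausea,,nauseous
C0004,vomiting,emesis,vomiting
C0004,vomiting,emesis,emesis
C0004,vomiting,emesis,vomited
C0005,confusion,confusional state,confusion
C0005,confusion,confusional state,confused
C0005,confusion,confusional state,disorientation
C0005,confusion,confusional state,disoriented
C0006,agitation,,agitation
C0006,agitation,,agitated
C0007,respiratory arrest,,respiratory arrest
C0008,respiratory depression,hypoventilation,respiratory depression
C0008,respiratory depression,hypoventilation,respiratory suppression
C0008,respiratory depression,hypoventilation,hypoventilation
C0008,respiratory depression,hypoventilation,shallow breathing
C0009,constipation,,constipation
C0009,constipation,,constipated
C0009,constipation,,severe constipation
C0009,constipation,,severely constipated
C0010,mental state abnormal,altered mental status,mental state abnormal
C0010,mental state abnormal,altered mental status,altered mental status
C0010,mental state abnormal,altered mental status,altered mental state
C0010,mental state abnormal,altered mental status,mental status change
C0010,mental state abnormal,altered mental status,mental status changes
C0010,mental state abnormal,altered mental status,ams
C0011,pruritus,itching,pruritus
C0011,pruritus,itching,itching
C0011,pruritus,itching,itchiness
C0012,urinary retention,,urinary retention
C0012,urinary retention,,unable to void
C0013,ileus,,ileus
C0014,sedation,oversedation,sedation
C0014,sedation,oversedation,oversedation
C0014,sedation,oversedation,oversedated
C0015,apnoea,apneic events,apnoea
C0015,apnoea,apneic events,apnea
C0015,apnoea,apneic events,apneic events
C0015,apnoea,apneic events,apneic event
C0015,apnoea,apneic events,apneic episodes
C0016,hypersomnia,hypersomnolence,hypersomnia
C0016,hypersomnia,hypersomnolence,hypersomnolence
C0016,hypersomnia,hypersomnolence,daytime hypersomnolence
C0017,headache,,headache
C0017,headache,,headaches
C0017,headache,,morning headaches
C0018,delirium,,delirium
C0018,delirium,,delirious
C0019,dizziness,lightheadedness,dizziness
C0019,dizziness,lightheadedness,dizzy
C0019,dizziness,lightheadedness,lightheadedness
C0019,dizziness,lightheadedness,lightheaded
C0020,lethargy,,lethargy
C0020,lethargy,,lethargic
C0021,hallucination,,hallucination
C0021,hallucination,,hallucinations
C0021,hallucination,,hallucinating
C0022,bradycardia,,bradycardia
C0022,bradycardia,,bradycardic
C0023,back pain,low back pain,back pain
C0023,back pain,low back pain,low back pain
C0024,chest pain,,chest pain
C0025,abdominal pain,stomach pain,abdominal pain
C0025,abdominal pain,stomach pain,stomach pain
C0026,adverse reaction,,adverse reaction
C0027,hypoxia,oxygen desaturation,hypoxia
C0027,hypoxia,oxygen desaturation,hypoxic
C0027,hypoxia,oxygen desaturation,oxygen desaturation
C0027,hypoxia,oxygen desaturation,desaturation
C0028,urticaria,hives,urticaria
C0028,urticaria,hives,hives
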