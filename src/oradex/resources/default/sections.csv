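pattern,canonical
brief hospital course,brief_hospital_course
hospital course,hospital_course
hospital course by systems,hospital_course
hospital course by system,hospital_course
summary of hospital course,hospital_course
history of present illness,history_of_present_illness
history of the present illness,history_of_present_illness
hpi,history_of_present_illness
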