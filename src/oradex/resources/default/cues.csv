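cue,type
no,negation
not,negation
without,negation
denies,negation
denied,negation
denying,negation
no further,negation
no evidence of,negation
no signs of,negation
no episodes of,negation
negative for,negation
never,negation
free of,negation
but,termination
however,termination
although,termination
though,termination
except,termination
aside from,termination
apart from,termination
other than,termination
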