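short,expansion
ams,altered mental status
sob,shortness of breath
msc,mental status changes
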