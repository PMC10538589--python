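q
qd
qhs
qid
tid
bid
prn
po
iv
im
sc
sq
mg
mcg
gm
ml
cc
hr
hrs
min
dr
mr
mrs
ms
prof
st
vs
approx
e.g
i.e
pt
pts
wk
wks
mo
mos
yr
yrs
tab
tabs
cap
caps
resp
neuro
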