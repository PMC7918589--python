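term,value
mo2,0.051
mo3,0.095
mo4,0.197
mo5,0.274
sc2,0.046
sc3,0.084
sc4,0.163
sc5,0.212
ua2,0.041
ua3,0.074
ua4,0.140
ua5,0.186
pd2,0.061
pd3,0.113
pd4,0.229
pd5,0.327
ad2,0.054
ad3,0.101
ad4,0.205
ad5,0.286
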