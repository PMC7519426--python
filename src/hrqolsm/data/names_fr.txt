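# Proper-name dictionary used by the deidentifier (and, for synthetic corpora,
# by the generator when planting name PII).  Matched capitalized only.
Dupont
Durand
Moreau
Lefebvre
Garnier
Rousseau
Fontaine
Chevalier
Lambert
Roux
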