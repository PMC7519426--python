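# Global-health polarity phrasebook for the poor/stable/good classification.
# Matched as accent/case-folded substrings of the raw evidence texts.
poor: ["sa sante se degrade", "va de plus en plus mal"]
stable: ["son etat reste stable", "rien n a change"]
good: ["va beaucoup mieux", "nette amelioration"]
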