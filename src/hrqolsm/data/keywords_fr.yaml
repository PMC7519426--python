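# Immune-checkpoint-inhibitor keyword lexicon: drug -> synonyms.
# Matching is accent- and case-insensitive; the supplementary keyword list of
# the source corpus is not public, so this is a documented reconstruction
# covering the seven ICI compounds, their brand names and the class terms.
ipilimumab: [ipilimumab, yervoy]
nivolumab: [nivolumab, opdivo]
pembrolizumab: [pembrolizumab, keytruda]
atezolizumab: [atezolizumab, tecentriq]
durvalumab: [durvalumab, imfinzi]
tremelimumab: [tremelimumab]
avelumab: [avelumab, bavencio]
immunotherapy: [immunothérapie, immunotherapie, immunotherapy, immuno-oncologie]
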