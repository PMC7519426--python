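variable,level,count,percent
reporter,patient,89,59.3
reporter,relative,61,40.7
gender,woman,82,54.7
gender,man,60,40.0
gender,undetermined,8,5.3
cancer,lung,46,30.7
cancer,melanoma,41,27.3
cancer,other,36,24.0
cancer,undetermined,27,18.0
drug,nivolumab,31,20.7
drug,ipilimumab,20,13.3
drug,pembrolizumab,16,10.7
drug,other,11,7.3
drug,undetermined,72,48.0
global_health,poor,63,54.8
global_health,stable,32,27.8
global_health,good,20,17.4
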