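subdomain_id,label,domain,occurrences,qlq_c30_items,fact_g_items
global-health-state,Deteriorated/stable/better,Global health,115,Q29,GF7
fatigue-tiredness,Fatigue/Tiredness,Symptoms,34,Q10;Q12;Q18,GP1
unspecified-adverse-events,None/Unspecified adverse events,Symptoms,23,,GP5
fever,Fever,Symptoms,8,,
pain,Pain/Joint pain/Leg pain/Liver pain,Symptoms,15,Q9;Q19,GP4
cough,Cough,Symptoms,7,,
appetite-weight-loss,Loss of appetite/Weight loss,Symptoms,11,Q13,
rash-itch,Rash/itch,Symptoms,6,,
breathlessness,Respiratory trouble/Breathlessness,Symptoms,6,Q18,
headache,Headache,Symptoms,3,,
thyroid-disorders,Thyroid disorders,Symptoms,4,,
heavy-legs,Heavy legs,Symptoms,2,,
hair-loss,Hair loss,Symptoms,2,,
diarrhea,Diarrhea,Symptoms,2,Q17,
optimism-hope,Optimism/Hope,Emotional state,15,,GE3
exhaustion,Exhaustion,Emotional state,7,,
distress,Distress,Emotional state,6,,
good-morale,Good mental health/Morale,Emotional state,5,,GE1;GE2
fear,Fear,Emotional state,4,Q22,GE5;GE6
depression,Depression,Emotional state,3,Q24,
psychological-disorders,Psychological disorders,Emotional state,3,,
stable-health,Stable health,Emotional state,3,,
isolate-oneself,Isolate oneself,Emotional state,2,,
emotional-exhaustion,Emotional exhaustion due to side effects,Emotional state,1,,
normal-life,Normal life/Reduced activities and pace of life,Role,12,Q6;Q7,GF6;GF3
medical-time-constraints,Time constraints regarding medical care,Role,3,,
financial-problems,Financial problems,Role,2,Q28,
maintained-activities,Maintained activities,Role,2,Q6;Q7,GF6
home-care-constraints,Home care constraints,Role,1,,
improved-hrqol,Improved HRQoL,Role,1,Q30,GF7
driving-again,Ability to drive again,Role,1,,
minimal-physical-activity,Minimal or no physical activity/maintained activity,Physical activity,6,Q1;Q2;Q3;Q4,GP1;GP7
difficulty-walking-eating,Difficulty walking/eating,Physical activity,5,Q2;Q3;Q5,
difficulty-climbing-stairs,Difficulty climbing stairs,Physical activity,1,Q2;Q3;Q5,
difficulty-getting-into-bed,Difficulty getting into bed alone,Physical activity,1,Q2;Q3;Q5,
sick-leave,Sick leave,Professional situation,6,Q6,GF1;GF2
maintained-work,Maintained work activity,Professional situation,2,Q6,GF1;GF2
reduced-working-time,Reduction in working time,Professional situation,1,Q6,GF1;GF2
concentration-problems,Concentration problems,Cognitive state,1,Q20,
memory-problems,Memory problems,Cognitive state,1,Q25,
family-assistance,Requiring family assistance for medical care,Social state,1,Q26,
family-celebrations,Inability to participate in family celebrations,Social state,1,Q26,
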