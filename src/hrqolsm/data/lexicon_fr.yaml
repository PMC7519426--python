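# Default French trigger-phrase lexicon: subdomain id -> phrases.
# Phrases are matched after running the same cleaning pipeline as the posts
# (accent fold, lowercase, punctuation strip, stop words, stemming) as a
# contiguous stem sequence.  Seeded from the verbatim patient quotes that
# illustrate each taxonomy domain; curated so that no processed phrase is
# contained in another (closed-world precision).
global-health-state: ["etat general"]
fatigue-tiredness: ["fatigue", "fatiguee"]
unspecified-adverse-events: ["effets secondaires"]
fever: ["fievre"]
pain: ["douleur", "douleurs"]
cough: ["toux"]
appetite-weight-loss: ["perte de poids"]
rash-itch: ["demangeaisons"]
breathlessness: ["essouffle", "essoufflement"]
headache: ["migraine", "migraines"]
thyroid-disorders: ["thyroide"]
heavy-legs: ["jambes lourdes"]
hair-loss: ["cheveux"]
diarrhea: ["diarrhee"]
optimism-hope: ["espoir"]
exhaustion: ["epuise", "epuisee"]
distress: ["detresse"]
good-morale: ["bon moral"]
fear: ["peur"]
depression: ["depression"]
psychological-disorders: ["troubles psychologiques"]
stable-health: ["situation stationnaire"]
isolate-oneself: ["je m isole", "isolee"]
emotional-exhaustion: ["a bout de nerfs"]
normal-life: ["vie normale"]
medical-time-constraints: ["contraintes de temps"]
financial-problems: ["problemes d argent"]
maintained-activities: ["activites maintenues"]
home-care-constraints: ["soins a domicile"]
improved-hrqol: ["qualite de vie amelioree"]
driving-again: ["reprendre le volant"]
minimal-physical-activity: ["activite physique minimale"]
difficulty-walking-eating: ["difficulte a marcher"]
difficulty-climbing-stairs: ["monter les escaliers"]
difficulty-getting-into-bed: ["se coucher seul"]
sick-leave: ["arret maladie"]
maintained-work: ["activite professionnelle conservee"]
reduced-working-time: ["temps partiel"]
concentration-problems: ["me concentrer"]
memory-problems: ["memoire"]
family-assistance: ["aide de ma famille"]
family-celebrations: ["fetes de famille"]
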