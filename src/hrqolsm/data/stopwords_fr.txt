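# Packaged French stop-word list (function words, clitics, auxiliaries).
# Entries are matched after accent folding and lowercasing.
a
au
aux
avec
c
ca
ce
ceci
cela
ces
cet
cette
chez
comme
d
dans
de
des
donc
du
elle
elles
en
entre
et
eux
il
ils
j
je
l
la
le
les
leur
leurs
lui
m
ma
mais
me
meme
memes
mes
moi
mon
n
ne
ni
nos
notre
nous
on
ont
ou
par
pas
pour
qu
que
quel
quelle
quels
quelles
qui
quoi
s
sa
sans
se
ses
si
son
sont
sous
sur
t
ta
te
tes
toi
ton
tu
un
une
vos
votre
vous
y
# auxiliaries and very frequent verb forms
ai
aie
as
avais
avait
avaient
avez
avons
avoir
est
es
etaient
etais
etait
ete
etes
etre
eu
fut
sera
serai
serait
seront
soit
suis
# frequent adverbs/quantifiers (deliberately excludes "tres")
alors
aussi
autre
autres
beaucoup
bien
car
cependant
deja
donc
encore
enfin
ici
la-bas
lors
or
ouais
oui
non
peu
plus
plupart
pourtant
puis
quand
surtout
toujours
tout
toute
toutes
tous
trop
voici
voila
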