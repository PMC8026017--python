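# Portuguese stop-words (function words / liaison terms)
a
à
às
ao
aos
aquela
aquelas
aquele
aqueles
aquilo
as
até
com
como
da
daquela
daquele
das
de
dela
delas
dele
deles
depois
desta
deste
disso
disto
do
dos
e
é
ela
elas
ele
eles
em
então
entre
era
eram
essa
essas
esse
esses
esta
estas
está
estão
estava
estavam
este
estes
eu
foi
for
foram
há
isso
isto
já
la
lá
lhe
lhes
lo
mas
me
mesmo
meu
minha
muito
na
não
nas
nem
no
nos
nós
num
numa
o
os
ou
para
pela
pelas
pelo
pelos
por
pra
que
quem
se
sem
ser
seu
seus
só
sua
suas
também
te
tem
têm
tinha
tinham
um
uma
umas
uns
você
vocês
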