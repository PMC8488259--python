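word	pos	syllables
the	det	1
a	det	1
an	det	1
this	det	1
that	det	1
these	det	1
some	det	1
his	det	1
her	det	1
their	det	1
he	pron	1
she	pron	1
it	pron	1
they	pron	1
we	pron	1
i	pron	1
you	pron	1
him	pron	1
them	pron	1
there	pron	1
in	prep	1
on	prep	1
at	prep	1
of	prep	1
to	prep	1
from	prep	1
with	prep	1
by	prep	1
near	prep	1
under	prep	2
over	prep	2
beside	prep	2
into	prep	2
and	conj	1
but	conj	1
or	conj	1
because	conj	2
while	conj	1
when	conj	1
as	conj	1
so	conj	1
one	num	1
two	num	1
three	num	1
uh	filler	1
um	filler	1
er	filler	1
ah	filler	1
very	adv	2
quite	adv	1
almost	adv	2
often	adv	2
really	adv	3
slowly	adv	2
quickly	adv	2
again	adv	2
away	adv	2
down	adv	1
up	adv	1
outside	noun	2
cookie	noun	2
cookies	noun	2
biscuit	noun	2
jar	noun	1
boy	noun	1
girl	noun	1
woman	noun	2
mother	noun	2
lady	noun	2
mom	noun	1
son	noun	1
daughter	noun	2
sister	noun	2
brother	noun	2
stool	noun	1
chair	noun	1
plate	noun	1
dish	noun	1
dishes	noun	2
dishcloth	noun	2
towel	noun	2
cloth	noun	1
water	noun	2
window	noun	2
windows	noun	2
curtain	noun	2
curtains	noun	2
sink	noun	1
kitchen	noun	2
counter	noun	2
floor	noun	1
cupboard	noun	2
shelf	noun	1
lid	noun	1
hand	noun	1
apron	noun	2
yard	noun	1
garden	noun	2
exterior	noun	4
faucet	noun	2
is	verb	1
are	verb	1
was	verb	1
were	verb	1
stands	verb	1
standing	verb	2
falling	verb	2
reaching	verb	2
taking	verb	2
stealing	verb	2
washing	verb	2
drying	verb	2
wiping	verb	2
overflowing	verb	4
running	verb	2
spilling	verb	2
looking	verb	2
laughing	verb	2
asking	verb	2
tipping	verb	2
wobbling	verb	3
sees	verb	1
goes	verb	1
getting	verb	2
trying	verb	2
little	adj	2
young	adj	1
old	adj	1
small	adj	1
tall	adj	1
wet	adj	1
dry	adj	1
open	adj	2
full	adj	1
happy	adj	2
quiet	adj	2
warm	adj	1
wooden	adj	2
pleasant	adj	2
nice	adj	1
good	adj	1
first	adj	1
favorite	adj	3
friend	noun	1
trip	noun	1
job	noun	1
school	noun	1
teacher	noun	2
summer	noun	2
family	noun	3
child	noun	1
children	noun	2
beach	noun	1
mountain	noun	2
dog	noun	1
pet	noun	1
day	noun	1
year	noun	1
time	noun	1
home	noun	1
town	noun	1
place	noun	1
event	noun	2
birthday	noun	2
wedding	noun	2
vacation	noun	3
memory	noun	3
remember	verb	3
met	verb	1
went	verb	1
visited	verb	3
played	verb	1
worked	verb	1
traveled	verb	2
moved	verb	1
loved	verb	1
enjoyed	verb	2
lived	verb	1
walked	verb	1
house	noun	1
stood	verb	1
end	noun	1
street	noun	1
grew	verb	1
door	noun	1
every	det	2
morning	noun	2
birds	noun	1
sang	verb	1
trees	noun	1
people	noun	2
stopped	verb	1
watch	verb	1
flowers	noun	2
sun	noun	1
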