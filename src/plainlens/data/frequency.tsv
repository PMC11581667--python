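# Synthetic fixture frequency lexicon: word<TAB>zipf_score.
# Hand-curated common-English list; scores follow a Zipf-law decay by rank.
the	7.10
be	6.68
to	6.43
of	6.26
and	6.12
a	6.01
in	5.92
that	5.84
have	5.76
i	5.70
it	5.64
for	5.59
not	5.54
on	5.50
with	5.45
he	5.41
as	5.38
you	5.34
do	5.31
at	5.28
this	5.25
but	5.22
his	5.19
by	5.17
from	5.14
they	5.12
we	5.10
say	5.07
her	5.05
she	5.03
or	5.01
an	4.99
will	4.97
my	4.96
one	4.94
all	4.92
would	4.90
there	4.89
their	4.87
what	4.86
so	4.84
up	4.83
out	4.81
if	4.80
about	4.79
who	4.77
get	4.76
which	4.75
go	4.73
me	4.72
when	4.71
make	4.70
can	4.69
like	4.67
time	4.66
no	4.65
just	4.64
him	4.63
know	4.62
take	4.61
people	4.60
into	4.59
year	4.58
your	4.57
good	4.56
some	4.55
could	4.54
them	4.53
see	4.53
other	4.52
than	4.51
then	4.50
now	4.49
look	4.48
only	4.47
come	4.47
its	4.46
over	4.45
think	4.44
also	4.44
back	4.43
after	4.42
use	4.41
two	4.41
how	4.40
our	4.39
work	4.38
first	4.38
well	4.37
way	4.36
even	4.36
new	4.35
want	4.34
because	4.34
any	4.33
these	4.32
give	4.32
day	4.31
most	4.31
us	4.30
is	4.29
are	4.29
was	4.28
were	4.28
been	4.27
being	4.26
has	4.26
had	4.25
did	4.25
does	4.24
done	4.24
should	4.23
may	4.23
might	4.22
must	4.22
shall	4.21
am	4.20
man	4.20
woman	4.19
child	4.19
children	4.18
family	4.18
friend	4.17
home	4.17
house	4.16
water	4.16
food	4.15
drink	4.15
eat	4.15
sleep	4.14
rest	4.14
care	4.13
health	4.13
doctor	4.12
nurse	4.12
patient	4.11
hospital	4.11
clinic	4.10
medicine	4.10
team	4.10
plan	4.09
test	4.09
pain	4.08
help	4.08
visit	4.07
call	4.07
letter	4.07
morning	4.06
night	4.06
week	4.05
month	4.05
today	4.05
tomorrow	4.04
yesterday	4.04
holiday	4.03
school	4.03
office	4.03
staff	4.02
member	4.02
group	4.01
meeting	4.01
room	4.01
door	4.00
window	4.00
garden	4.00
market	3.99
ticket	3.99
dinner	3.98
lunch	3.98
breakfast	3.98
coffee	3.97
tea	3.97
milk	3.97
bread	3.96
fruit	3.96
apple	3.96
banana	3.95
energy	3.95
exercise	3.95
walk	3.94
run	3.94
play	3.94
read	3.93
write	3.93
learn	3.93
teach	3.92
talk	3.92
listen	3.92
speak	3.91
ask	3.91
answer	3.91
question	3.90
problem	3.90
idea	3.90
story	3.89
book	3.89
paper	3.89
page	3.88
word	3.88
sentence	3.88
name	3.88
number	3.87
money	3.87
price	3.87
cost	3.86
free	3.86
open	3.86
close	3.85
start	3.85
stop	3.85
begin	3.85
end	3.84
turn	3.84
move	3.84
keep	3.83
hold	3.83
carry	3.83
bring	3.83
send	3.82
find	3.82
found	3.82
lose	3.82
change	3.81
happen	3.81
live	3.81
stay	3.80
leave	3.80
left	3.80
arrive	3.80
early	3.79
late	3.79
soon	3.79
often	3.79
always	3.78
never	3.78
sometimes	3.78
again	3.78
once	3.77
twice	3.77
here	3.77
where	3.77
very	3.76
too	3.76
much	3.76
many	3.76
more	3.75
less	3.75
few	3.75
little	3.75
big	3.74
small	3.74
long	3.74
short	3.74
high	3.73
low	3.73
old	3.73
young	3.73
bad	3.72
easy	3.72
hard	3.72
simple	3.72
clear	3.71
safe	3.71
slow	3.71
fast	3.71
warm	3.71
cold	3.70
hot	3.70
happy	3.70
sad	3.70
tired	3.69
sick	3.69
ill	3.69
better	3.69
worse	3.68
best	3.68
worst	3.68
right	3.68
wrong	3.68
true	3.67
important	3.67
different	3.67
same	3.67
next	3.67
last	3.66
near	3.66
far	3.66
local	3.66
public	3.65
private	3.65
common	3.65
special	3.65
whole	3.65
full	3.64
empty	3.64
strong	3.64
weak	3.64
heavy	3.64
light	3.63
dark	3.63
bright	3.63
quiet	3.63
loud	3.63
clean	3.62
dirty	3.62
fresh	3.62
body	3.62
head	3.62
eye	3.61
ear	3.61
nose	3.61
mouth	3.61
hand	3.61
arm	3.60
leg	3.60
foot	3.60
heart	3.60
blood	3.60
skin	3.59
bone	3.59
brain	3.59
tooth	3.59
hair	3.59
face	3.59
neck	3.58
chest	3.58
stomach	3.58
muscle	3.58
breath	3.58
weight	3.57
mother	3.57
father	3.57
sister	3.57
brother	3.57
baby	3.56
parent	3.56
wife	3.56
husband	3.56
son	3.56
daughter	3.56
city	3.55
town	3.55
street	3.55
road	3.55
park	3.55
shop	3.55
store	3.54
bank	3.54
church	3.54
station	3.54
bridge	3.54
river	3.53
hill	3.53
tree	3.53
flower	3.53
grass	3.53
field	3.53
farm	3.52
animal	3.52
dog	3.52
cat	3.52
bird	3.52
fish	3.52
horse	3.51
cow	3.51
sheep	3.51
country	3.51
world	3.51
land	3.51
sea	3.50
sky	3.50
sun	3.50
moon	3.50
star	3.50
rain	3.50
snow	3.49
wind	3.49
cloud	3.49
weather	3.49
season	3.49
spring	3.49
summer	3.49
autumn	3.48
winter	3.48
fire	3.48
earth	3.48
air	3.48
ice	3.48
stone	3.47
sand	3.47
car	3.47
bus	3.47
train	3.47
plane	3.47
boat	3.46
bike	3.46
phone	3.46
computer	3.46
radio	3.46
television	3.46
music	3.46
film	3.45
game	3.45
sport	3.45
ball	3.45
club	3.45
party	3.45
gift	3.45
card	3.44
photo	3.44
picture	3.44
colour	3.44
red	3.44
blue	3.44
green	3.43
white	3.43
black	3.43
yellow	3.43
brown	3.43
grey	3.43
government	3.43
law	3.42
rule	3.42
report	3.42
news	3.42
list	3.42
note	3.42
sign	3.42
form	3.41
check	3.41
service	3.41
job	3.41
role	3.41
worker	3.41
manager	3.41
leader	3.40
teacher	3.40
student	3.40
driver	3.40
farmer	3.40
minute	3.40
hour	3.40
second	3.40
moment	3.39
period	3.39
age	3.39
life	3.39
death	3.39
birth	3.39
history	3.39
future	3.38
past	3.38
reason	3.38
result	3.38
effect	3.38
cause	3.38
chance	3.38
choice	3.37
voice	3.37
sound	3.37
smell	3.37
taste	3.37
touch	3.37
feeling	3.37
thought	3.37
memory	3.36
dream	3.36
hope	3.36
fear	3.36
love	3.36
hate	3.36
joy	3.36
worry	3.36
stress	3.35
given	3.35
taken	3.35
tested	3.35
planned	3.35
reviewed	3.35
checked	3.35
shown	3.34
written	3.34
made	3.34
helped	3.34
showed	3.34
took	3.34
kept	3.34
needs	3.34
needed	3.33
uses	3.33
used	3.33
asked	3.33
told	3.33
said	3.33
went	3.33
came	3.33
got	3.33
saw	3.32
wanted	3.32
vitamin	3.32
together	3.32
remember	3.32
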