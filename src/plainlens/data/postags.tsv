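# Coarse tag lexicon: word<TAB>tag. Consulted after the closed-class sets,
# before the suffix fallback. Open-class words absent here default by suffix.
need	VERB
needs	VERB
take	VERB
takes	VERB
took	VERB
make	VERB
makes	VERB
made	VERB
help	VERB
helps	VERB
helped	VERB
show	VERB
shows	VERB
showed	VERB
shown	VERB
give	VERB
gives	VERB
gave	VERB
given	VERB
keep	VERB
keeps	VERB
kept	VERB
find	VERB
finds	VERB
found	VERB
use	VERB
uses	VERB
eat	VERB
eats	VERB
drink	VERB
drinks	VERB
ask	VERB
asks	VERB
tell	VERB
tells	VERB
told	VERB
know	VERB
knows	VERB
think	VERB
thinks	VERB
go	VERB
goes	VERB
went	VERB
come	VERB
comes	VERB
came	VERB
get	VERB
gets	VERB
got	VERB
see	VERB
sees	VERB
saw	VERB
say	VERB
says	VERB
said	VERB
call	VERB
calls	VERB
recover	VERB
recovers	VERB
learn	VERB
learns	VERB
teach	VERB
talk	VERB
talks	VERB
listen	VERB
speak	VERB
speaks	VERB
answer	VERB
start	VERB
starts	VERB
stop	VERB
stops	VERB
begin	VERB
begins	VERB
end	VERB
ends	VERB
turn	VERB
turns	VERB
move	VERB
moves	VERB
hold	VERB
holds	VERB
carry	VERB
carries	VERB
bring	VERB
brings	VERB
send	VERB
sends	VERB
lose	VERB
loses	VERB
change	VERB
happen	VERB
happens	VERB
live	VERB
lives	VERB
stay	VERB
stays	VERB
leave	VERB
leaves	VERB
left	VERB
arrive	VERB
arrives	VERB
walk	VERB
walks	VERB
run	VERB
runs	VERB
play	VERB
plays	VERB
read	VERB
reads	VERB
write	VERB
writes	VERB
wrote	VERB
written	VERB
want	VERB
wants	VERB
wanted	VERB
clear	ADJ
good	ADJ
bad	ADJ
easy	ADJ
hard	ADJ
simple	ADJ
new	ADJ
old	ADJ
young	ADJ
high	ADJ
low	ADJ
big	ADJ
small	ADJ
long	ADJ
short	ADJ
safe	ADJ
slow	ADJ
fast	ADJ
warm	ADJ
cold	ADJ
hot	ADJ
happy	ADJ
sad	ADJ
tired	ADJ
sick	ADJ
ill	ADJ
better	ADJ
worse	ADJ
best	ADJ
worst	ADJ
right	ADJ
wrong	ADJ
true	ADJ
important	ADJ
same	ADJ
next	ADJ
last	ADJ
local	ADJ
healthy	ADJ
common	ADJ
whole	ADJ
full	ADJ
empty	ADJ
strong	ADJ
weak	ADJ
heavy	ADJ
light	ADJ
dark	ADJ
bright	ADJ
loud	ADJ
clean	ADJ
dirty	ADJ
fresh	ADJ
free	ADJ
often	ADV
always	ADV
sometimes	ADV
soon	ADV
now	ADV
today	ADV
tomorrow	ADV
yesterday	ADV
here	ADV
there	ADV
well	ADV
very	ADV
too	ADV
also	ADV
again	ADV
twice	ADV
early	ADV
late	ADV
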