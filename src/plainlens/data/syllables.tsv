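# Syllable-count exceptions: word<TAB>syllables. Checked before the heuristic.
idea	3
area	3
being	2
beyond	2
create	2
science	2
quiet	2
diet	2
iatrogenic	5
approximately	5
every	2
everyone	3
everything	3
really	2
business	2
interesting	4
different	3
evening	2
family	3
chocolate	3
camera	3
average	3
beautiful	3
usually	4
actually	4
especially	4
immediately	5
experience	4
society	4
period	3
radio	3
union	2
fuel	2
poem	2
cruel	2
influence	3
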