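# Synthetic fixture thesaurus: complex word<TAB>simpler alternatives (| separated).
utilize	use
utilise	use
commence	start|begin
terminate	end|stop
facilitate	help
administer	give
physician	doctor
medication	medicine
purchase	buy
obtain	get
assist	help
demonstrate	show
approximately	about
additional	more|extra
sufficient	enough
immediately	right away
ascertain	find out
endeavour	try
endeavor	try
subsequently	later
prior	before
regarding	about
numerous	many
frequently	often
initial	first
remainder	rest
component	part
requirement	need
assistance	help
discontinue	stop
modify	change
monitor	watch|check
notify	tell
participate	take part
possess	have
require	need
select	choose
transmit	send|pass on
verify	check
advise	tell
consult	talk to
indicate	show
implement	carry out
objective	goal
optimal	best
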