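# Acronym whitelist: surfaces listed here are never flagged as acronyms.
OK
TV
ID
AM
PM
FAQ
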