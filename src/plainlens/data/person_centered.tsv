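# Synthetic person-centered wordlist: flagged phrase<TAB>preferred person-first phrase.
diabetic	person with diabetes
diabetics	people with diabetes
asthmatic	person with asthma
asthmatics	people with asthma
epileptic	person with epilepsy
schizophrenic	person with schizophrenia
the disabled	people with disability
the elderly	older people
the handicapped	people with disability
handicapped	person with disability
suffers from	has
suffering from	living with
afflicted with	has
wheelchair-bound	uses a wheelchair
confined to a wheelchair	uses a wheelchair
addict	person with a substance use disorder
victim of	person affected by
committed suicide	died by suicide
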