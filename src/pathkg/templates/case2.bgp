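# Drug-action triples: pharmacological action and its target.
# ?drug is pre-bound by the caller.
?drug ?action ?target
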