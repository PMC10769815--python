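# Directed relation edges of a database pathway graph: a relation node
# connecting two entries.
?r kegg:entry1 ?e1
?r kegg:entry2 ?e2
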