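# Sentences in the annotation layer that mention the drug of interest.
# ?drug is pre-bound by the caller; ?s/?doc/?text are returned.
?s rdf:type ketcept:Sentence
?s ketcept:mentions ?drug
?s ketcept:doc ?doc
?s ketcept:text ?text
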