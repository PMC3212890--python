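# corpus manifest: service <TAB> role <TAB> file <TAB> media type
hello	request	hello-input.rdf	application/rdf+xml
hello	response	hello-output.rdf	application/rdf+xml
hello	description	hello-description.rdf	application/rdf+xml
hello	ontology	hello.owl.n3	text/rdf+n3
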