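<?xml version="1.0" encoding="utf-8"?>
<rdf:RDF
   xmlns:ns1="http://sadiframework.org/examples/hello.owl#"
   xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
>
  <rdf:Description rdf:about="http://sadiframework.org/examples/hello-input.rdf#1">
    <ns1:greeting>Hello, Guy Incognito!</ns1:greeting>
    <rdf:type rdf:resource="http://sadiframework.org/examples/hello.owl#GreetedIndividual"/>
  </rdf:Description>
</rdf:RDF>
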