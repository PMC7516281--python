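{
  "@context": {
    "sbol": "http://sbols.org/v3#",
    "prov": "http://www.w3.org/ns/prov#",
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "xsd": "http://www.w3.org/2001/XMLSchema#",
    "sbolkit": "https://sbolkit.dev/ns#"
  }
}
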