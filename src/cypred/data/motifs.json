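{
  "version": 1,
  "motifs": {
    "benzodioxole": {"smarts": "c1ccc2OCOc2c1", "exemplar": "c1ccc2c(c1)OCO2"},
    "imidazole": {"smarts": "c1c[nH]cn1", "exemplar": "c1c[nH]cn1"},
    "pyridine": {"smarts": "c1ccncc1", "exemplar": "c1ccncc1"},
    "indole": {"smarts": "c1ccc2c(c1)cc[nH]2", "exemplar": "c1ccc2[nH]ccc2c1"},
    "piperidine": {"smarts": "C1CCNCC1", "exemplar": "C1CCNCC1"},
    "pyrazine": {"smarts": "c1cnccn1", "exemplar": "c1cnccn1"},
    "triazole": {"smarts": "c1nc[nH]n1", "exemplar": "c1nc[nH]n1"},
    "heterocyclic_nitrogen": {"smarts": "[nR,NR]", "exemplar": "c1ccncc1"},
    "coordinating_heteroatom": {"smarts": "[#7,#8,#16]", "exemplar": "CCO"}
  }
}
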