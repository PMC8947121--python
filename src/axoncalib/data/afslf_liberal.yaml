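# AF/SLF with liberally expanded termination fields: 47l and p47r added to
# the anterior (Broca) field, PF, PFm and PGi to the posterior (Wernicke)
# field. Cross-sections and density as in the conservative spec.
name: "AF/SLF (liberal termination fields)"
components:
  arcuate: {left: 160.6, right: 51.5}
  slf: {left: 213.8, right: 174.4}
density: 350000.0
anterior_field: ["44", "45", "6r", "IFSa", "IFSp", "FOP4", "47l", "p47r"]
posterior_field: ["PSL", "RI", "STV", "PFcm", "PF", "PFm", "PGi"]
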