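# Arcuate + superior longitudinal fasciculus system, conservative
# termination fields centered on Broca's (anterior) and Wernicke's
# (posterior) areas, in multimodal-atlas parcel names.
# Cross-sections (mm^2) are published mid-tract measurements:
# arcuate 160.6 (L) / 51.5 (R); SLF 213.8 (L) / 174.4 (R).
name: "AF/SLF (conservative termination fields)"
components:
  arcuate: {left: 160.6, right: 51.5}
  slf: {left: 213.8, right: 174.4}
density: 350000.0   # shrinkage-corrected ipsilateral axons/mm^2
anterior_field: ["44", "45", "6r", "IFSa", "IFSp", "FOP4"]
posterior_field: ["PSL", "RI", "STV", "PFcm"]
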