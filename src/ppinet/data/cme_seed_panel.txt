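# Literature-curated cystoid macular edema seed panel (18 human proteins)
# angiogenesis
VEGFA
ANGPT2
KDR
FLT1
PDGFB
# inflammation and cytokine signaling
IL6
TNF
CXCL8
CXCL10
CCL2
# vascular permeability
ICAM1
EDN1
# oxidative stress and hypoxia
HIF1A
NOS2
# matrix remodeling
MMP2
MMP9
# additional regulators
TGFB1
PTGS2
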