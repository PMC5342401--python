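# Illustrative 20-gene seed list for demonstration runs.
# A plausible apoptosis / hypoxia / metformin-response panel for oral
# squamous cell carcinoma; NOT the original study's (unpublished) list.
TP53
CASP3
HIF1A
PDHA1
AKT1
MTOR
PRKAA1
PRKAA2
CDKN1A
BAX
BCL2
MYC
VEGFA
SLC2A1
LDHA
MDM2
EP300
EGFR
CCND1
HSP90AA1
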