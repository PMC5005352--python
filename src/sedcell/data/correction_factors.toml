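# Default volume-correction factors per (morphotype x treatment) and the
# treatments each imaging modality is corrected for. Factors multiply volumes.
# Values are the canonical tabled set; see sedcell.corrections for provenance
# (fixation 1/(1-0.225); dehydration+CPD 1/(1-0.58); halo 1/2.1 tabled as
# 0.475; filtration from mean filtered/non-filtered E. coli volumes).

[fixation]
coccoid = 1.29
elongated = 1.29
filamentous = 1.29

[filtration]
coccoid = 1.0
elongated = 1.13
filamentous = 1.13

[halo]
coccoid = 0.475
elongated = 0.475
filamentous = 0.475

[dehydration_cpd]
coccoid = 2.38
elongated = 2.38
filamentous = 2.38

[applicability]
FM = ["fixation", "filtration", "halo"]
SEM = ["fixation", "filtration", "dehydration_cpd"]
AFM = ["fixation", "filtration"]
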