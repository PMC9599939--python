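# Conserved miRNAs predicted to bind the CSMD1 3' UTR (TargetScan / miRBase
# families), as assayed on the TaqMan low-density miRNA cards.
# Reconstructed list: 18 members are the miRs named in the study's results;
# the remaining 4 (miR-135a, miR-183, miR-301b, miR-3666) are same-seed-family
# members completing the stated set of 22.
hsa-miR-10a
hsa-miR-10b
hsa-miR-19a
hsa-miR-19b
hsa-miR-33a
hsa-miR-33a*
hsa-miR-130a
hsa-miR-130b
hsa-miR-130b*
hsa-miR-135a
hsa-miR-135a*
hsa-miR-135b
hsa-miR-183
hsa-miR-183*
hsa-miR-190
hsa-miR-190b
hsa-miR-301a
hsa-miR-301b
hsa-miR-449a
hsa-miR-449b
hsa-miR-454
hsa-miR-3666
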