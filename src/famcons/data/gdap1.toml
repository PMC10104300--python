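# Curator-supplied annotation of human GDAP1 (reference NP_061845.2,
# numbering as in the crystal structures, e.g. PDB 7ALM chain A).
#
# Helix boundaries are not machine-derived: they were curated to be
# consistent with the residues assigned to each element in the structural
# literature (Arg120/His123 on helix a3; the a6 C-terminal stretch
# 218-227; Cys240 in the a6-a7 loop; 247-262 spanning a7; Arg282 on a8).
# Adjust for other constructs or numbering schemes.

[[helices]]
name = "a3"
chain = "A"
start = 116
end = 131

[[helices]]
name = "a6"
chain = "A"
start = 195
end = 227

[[helices]]
name = "a7"
chain = "A"
start = 247
end = 262

[[helices]]
name = "a8"
chain = "A"
start = 275
end = 290

[loop_a6_a7]
# the loop between helices a6 and a7 that folds back into the core;
# residues 238-240 at its tip are all disease-mutation targets
chain = "A"
start = 236
end = 241

[cmt]
# missense-mutation target residues in the GST-like domain, curated from
# the clinical-variant literature
sites = [120, 123, 161, 218, 219, 222, 226, 227, 238, 239, 240, 247, 256, 282, 310]

[thresholds]
s_conserved = 0.2
s_highly = 0.1
frac_min = 0.7
pseudocount = 0.5

[contacts]
hbond_max = 3.5
ionic_max = 4.0
angle_min = 90.0
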