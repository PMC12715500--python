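# Subnuclear compartment / protein-family keyword map used to classify
# candidate phase-separation scaffold proteins by their description,
# subcellular-localization and GO text.  Matching is case-insensitive
# plain substring (several terms are multiword phrases or fragments).
# Edit freely; the classifier takes any mapping of label -> list of terms.
pericentric_heterochromatin:
  - heterochromatin
  - methylated chromatin
  - methylated DNA
  - pericentromeric
  - pericentric
  - chromocenter
  - condensed
euchromatin:
  - euchromatin
  - transcriptionally active
  - active transcription
  - transcriptional enhancer
nucleus_speckle:
  - nuclear speckle
  - nucleus speckle
nucleolus:
  - nucleolus
nuclear_pore:
  - nuclear pore
dna_damage:
  - DNA damage
inactive_x_chromosome:
  - inactive X
paraspeckle:
  - paraspeckle
germ_granule:
  - germ granule
cajal:
  - cajal
pml:
  - PML
mbd_cbx:
  - MBD
  - MeCP
  - cbx5
histone_deacetylase:
  - histone deacetylase
histone_acetylase:
  - histone acetyltransferase
  - histone deacetylase corepressor
nurd:
  - NuRD
  - Gatad
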