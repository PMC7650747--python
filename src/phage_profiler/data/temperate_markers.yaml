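# Domain accessions taken as genomic evidence of a temperate lifestyle:
# site-specific recombinases (tyrosine and serine families) and phage
# immunity repressors.  Matching is case-insensitive on the accession.
marker_accessions:
  - PF00589   # Phage_integrase (tyrosine recombinase catalytic domain)
  - PF02899   # Phage_int_SAM_1 (integrase N-terminal SAM-like domain)
  - PF13495   # Phage_int_SAM_4
  - PF00239   # Resolvase (serine recombinase catalytic domain)
  - PF07508   # Recombinase (serine recombinase, large C-terminal domain)
  - PF07022   # Phage_CI_repr (phage CI-like immunity repressor)
  - PF01381   # HTH_3 (Cro/CI-type helix-turn-helix; classic lysogeny-module HTH)
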