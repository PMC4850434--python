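# End-to-end configuration reproducing the published MTHFR C677T /
# multiple-myeloma analysis from the packaged nine-study table.
input: table1                 # "table1" = packaged fixture, or a CSV path
genetic_models: [allele, homozygous, heterozygous, dominant, recessive]
tsa:
  alpha: 0.05
  power: 0.80
  # control event proportion is computed from the control allele counts
  # (38.02%) when omitted
  rri: 0.1681                 # anticipated relative risk increase (+16.81%)
  diversity: 0.67             # D^2 used for the published information size
  information_unit: subjects
  ris_variant: per-group
instrument:
  beta_per_allele: 0.158      # SD ln-Hcy per T allele (external GWAS)
  se: null
power:
  r2: 0.01
  alpha: 0.05
seed: 0
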