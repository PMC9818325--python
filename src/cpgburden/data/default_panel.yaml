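# Default cancer-predisposition gene panel shipped with cpgburden.
# Classes: "established" = high-to-moderate penetrance genes with
# prognostic/predictive potential; "candidate" = genes with uncertain
# clinical effect. Extend with your own YAML for a full screening panel.
genes:
  APC: established
  ATM: established
  BAP1: established
  BARD1: established
  BRCA1: established
  BRCA2: established
  BRIP1: established
  CDKN2A: established
  CHEK2: established
  DICER1: established
  FH: established
  HNF1A: established
  MET: established
  MLH1: established
  MSH2: established
  MSH6: established
  NBN: established
  NF1: established
  PALB2: established
  PMS2: established
  RAD51D: established
  RET: established
  TERT: established
  TP53: established
  VHL: established
  ATRIP: candidate
  AXIN1: candidate
  BLM: candidate
  DMBT1: candidate
  ERCC2: candidate
  ERCC5: candidate
  ERCC6: candidate
  EXO1: candidate
  FANCA: candidate
  FANCD2: candidate
  FANCG: candidate
  FANCM: candidate
  HOXB13: candidate
  LIG3: candidate
  MCPH1: candidate
  MDC1: candidate
  MITF: candidate
  MLH3: candidate
  MMP8: candidate
  MRE11: candidate
  MSH3: candidate
  MUTYH: candidate
  NHEJ1: candidate
  NTHL1: candidate
  PIK3CG: candidate
  PMS1: candidate
  RAD1: candidate
  RAD50: candidate
  RECQL5: candidate
  SBDS: candidate
  SETX: candidate
  SLX4: candidate
  SMARCA4: candidate
  TLR2: candidate
  TLR4: candidate
  TMEM127: candidate
  XRCC1: candidate
gene_sets:
  MRN:
  - MRE11
  - RAD50
  - NBN
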