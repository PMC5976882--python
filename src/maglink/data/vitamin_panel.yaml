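# Default metabolite panel: placeholder gene-family identifiers named
# after canonical bacterial biosynthesis genes.  Each step lists the
# alternative families that can perform it (OR semantics).  Curate real
# KO/ortholog-level definitions for production analyses.
pathways:
  pyridoxine:
    steps:
      - [pdxS]
      - [pdxT]
      - [pdxH]
  lysine:
    steps:
      - [lysC]
      - [asd]
      - [dapA]
      - [dapB]
      - [lysA]
  thiamine:
    steps:
      - [thiC]
      - [thiD]
      - [thiE]
      - [thiL]
  biotin:
    steps:
      - [bioF]
      - [bioA]
      - [bioD]
      - [bioB]
  riboflavin:
    steps:
      - [ribA]
      - [ribD]
      - [ribH]
      - [ribE]
  vitamin-b12:
    steps:
      - [cobA]
      - [cbiL]
      - [cbiF]
      - [cobQ]
      - [cobS]
  reduced-sulfur:
    steps:
      - [sat]
      - [cysC]
      - [cysH]
      - [cysJ, cysI]
markers:
  catalase-peroxidase: [katG]
  sulfate-reduction: [sat]
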