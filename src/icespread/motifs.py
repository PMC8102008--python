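"""Integrase recognition sequences of gut Bacteroidales ICEs.

These are the published target-site motifs duplicated on integration:

* ``GA1_PATTERN`` — the 7-bp degenerate consensus of the CTnBST-family
  tyrosine recombinase carried by GA1 ICEs (sequence-selective, hence
  widely scattered insertion sites). 'n' is any base; the two
  lowercase positions jointly tolerate a single mismatch.
* ``GA2ABC_REPEAT`` — the 22-bp sequence flanking GA2a/b/c ICEs at
  tRNA-Phe genes.
* ``INTGA2D_REPEAT`` — the 20-bp repeat generated by IntGA2d at
  tRNA-Lys genes.
* ``BPLEBEIUS_RECOGNITION`` — the 18-bp recognition sequence reported
  for the near-identical B. plebeius integrase; overlaps but does not
  equal the 20-bp repeat, motivating the merged 24-bp consensus.
* ``INTGA2CH_REPEAT`` — the 19-bp repeat of the IntGA2ch-bearing ICE
  variant at tRNA-Pro genes.
"""

from .sequence_core import DegeneratePattern

GA1_PATTERN = DegeneratePattern("tTnCcAA", max_soft_mismatches=1)

GA2ABC_REPEAT = "GTTCGATTCCTGGTGGCACCAC"  # 22 bp, tRNA-Phe
INTGA2D_REPEAT = "TTCGAGCCCCAGGCGGATCA"  # 20 bp, tRNA-Lys
BPLEBEIUS_RECOGNITION = "CCCCAGGCGGATCACTCA"  # 18 bp
INTGA2CH_REPEAT = "CTGGGGGGCGTGTGGTCGC"  # 19 bp, tRNA-Pro
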