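"""Constant adapter sequences flanking every tile in the synthesized oligo pool.

The amplicon layout on the sequencing read (R1) is

    UMI - ADAPTER5 - tile - ADAPTER3

so ``ADAPTER5`` is the anchor used for UMI extraction and ``ADAPTER3``
delimits the downstream end of the insert.
"""

ADAPTER5 = "TTCGATATCCGCATGCTAGC"
ADAPTER3 = "GATCGGAAGAGCACACGTCT"
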