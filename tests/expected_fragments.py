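"""The 29 published diagnosis fragments, frozen verbatim for the
format-fidelity checks (15 species; one species has no LSU barcode)."""

PRINTED_FRAGMENTS = (
    "ITS2 positions 127–146 gaaccgcaaattacgcatta, one mismatch allowed",
    "positions 486–515 gaacaggtcaacatcaattcttattgccat, one mismatch allowed",
    "ITS2 positions 108–127 ggratcycccgaggtgtgaaac; one mismatch allowed",
    "positions 546–565 ctcctggtgctctcacccgt; no mismatch allowed",
    "ITS2 positions 200–218 cattcgcaggaatagccag; one mismatch allowed",
    "positions 653–683 acgcaagctccagatcgaatctccgggctaa; one mismatch allowed",
    "positions 212–239 taatgtgagtgcaggaaatattatgact; one mismatch allowed",
    "positions 600–619 ctttggggtggcggtcgctg; one mismatch allowed",
    "ITS2 positions 25–44 tgggaacccatttcgtcgga; one mismatch allowed",
    "positions 665–694 cgttggggctgggacgcccgtcgctcgcac; one mismatch allowed",
    "positions 87–106 actgagccttgcagcaacaatctccccttt; no mismatch allowed",
    "positions 617–636 ccctctcggggggctgggga; no mismatch allowed",
    "positions 219–248 ttataatcttacgaagtactgaggtgatta; one mismatch allowed",
    "positions 515–546 aactaaaggratgtggctcctcggagtgttta; one mismatch allowed",
    "positions 159–178 taacttaattttttcccgag; one mismatch allowed",
    "positions 68–97 gcagatgatcgtgagggagttctcttcttc; one mismatch allowed",
    "positions 436–455 tgggcttctgctccggcgta; one mismatch allowed",
    "positions 97–116 cctgggcaaatttttttttc; one mismatch allowed",
    "positions 687–717 cttggatataagaagtggaatctacacaaat; one mismatch allowed",
    "positions 51–80 actgagccttgcagcaacaatctccccttt; no mismatch allowed",
    "positions 444–463 ggcgggaaatcagcccccct; no mismatch allowed",
    "ITS2 positions 186–215 gctttggacggcatgcgaatctgcatcaca; one mismatch allowed",
    "positions 656–685 tcaccaatcgacgtcaatcggcatgcgtct; one mismatch allowed",
    "positions 217–243 gaaaaaaaaagaaaggaaagaaaaggt; one mismatch allowed",
    "positions 470–489 tagtgcacttgctttcgcac; no mismatch allowed",
    "positions 228–257 ggaccgagaaggcgcaatagttgaacaatt; one mismatch allowed",
    "positions 585–604 ataactatcggacaaagttt; one mismatch allowed",
    "5.8S positions 122–151 gtcagtgtttgccacggagtatgccggctt; no mismatch allowed",
    "positions 694–723 gggcttgtcatggcagagggacacgtcgta; no mismatch allowed",
)
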