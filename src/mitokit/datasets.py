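"""Published reference tables for the decaploid *Camellia hainanica*
mitochondrial genome (GenBank PV110147) and its plastid comparison.

These small tables are the worked-example inputs for the summary operations:
the codon-transition census of predicted C-to-U RNA-editing sites, the SSR
motif-class counts, the tandem-repeat report, and the plastid-vs-mito
homologous-fragment table.  They let the hydropathy classifier, the repeat
summarizer and the fragment summarizer be exercised against real published
numbers without downloading the genome.
"""

from __future__ import annotations

# (reference codon, edited codon, number of sites) for the 539 predicted
# C-to-U editing sites across the annotated protein-coding genes.
RNA_EDITING_TRANSITIONS: list[tuple[str, str, int]] = [
    ("CAC", "TAC", 9),
    ("CAT", "TAT", 19),
    ("CGC", "TGC", 12),
    ("CGT", "TGT", 30),
    ("ACA", "ATA", 4),
    ("ACC", "ATC", 2),
    ("ACG", "ATG", 7),
    ("ACT", "ATT", 4),
    ("CGG", "TGG", 32),
    ("TCA", "TTA", 77),
    ("TCC", "TTC", 34),
    ("TCG", "TTG", 52),
    ("TCT", "TTT", 48),
    ("CAG", "TAG", 1),
    ("CGA", "TGA", 3),
    ("CCA", "TCA", 8),
    ("CCC", "TCC", 10),
    ("CCG", "TCG", 3),
    ("CCT", "TCT", 20),
    ("CCA", "CTA", 49),
    ("CCC", "CTC", 8),
    ("CCC", "TTC", 8),
    ("CCG", "CTG", 36),
    ("CCT", "CTT", 22),
    ("CCT", "TTT", 14),
    ("CTC", "TTC", 5),
    ("CTT", "TTT", 12),
    ("GCC", "GTC", 1),
    ("GCG", "GTG", 7),
    ("GCT", "GTT", 2),
]

# SSR counts per motif class (unit length 1..6) — 254 SSRs in total.
SSR_CLASS_COUNTS: dict[int, int] = {1: 29, 2: 70, 3: 37, 4: 98, 5: 16, 6: 4}

# Tandem-repeat report: (period, copy number, consensus unit, percent match,
# start, end) on the 902,617 bp mitogenome.
TANDEM_REPEATS: list[tuple[int, float, str, int, int, int]] = [
    (24, 3.0, "CCGGCGCAGGCTCAGCAGGAGGGG", 97, 21887, 21958),
    (22, 2.0, "AGGTTCGGCTAGCTTAGCTATT", 86, 39259, 39302),
    (29, 1.9, "CTTGCATGGACTGAAAGGCTTCCCCTTTA", 88, 71394, 71449),
    (26, 2.0, "CTTAGGACATACCCAGGCTAATATGA", 92, 89408, 89459),
    (61, 2.0, "GGTTTTTCAACGTACGATAGCACGGGTTAGCTTGCTTATTTAGAACTAGTGTTCTTAGTTCT", 93, 117884, 118009),
    (16, 1.9, "AGGGTTGTAGAAGTAC", 93, 140972, 141002),
    (29, 2.2, "AACTACCTAGCTACAGGAGGAGAACTACAA", 83, 157244, 157307),
    (13, 2.3, "CTTTCCTTTCTATAG", 89, 184967, 184998),
    (24, 3.0, "CCGGCGCAGGCTCAGCAGGAGGGG", 97, 206826, 206897),
    (18, 2.1, "TCATATTGATTCTATTTT", 90, 247687, 247723),
    (18, 2.3, "TTGAACTGATTCGAATCC", 82, 262819, 262859),
    (20, 2.0, "GAAGGGAAGATACCATCCTA", 90, 277599, 277638),
    (15, 2.1, "TCATAGCCGCGAGAGC", 88, 285307, 285339),
    (14, 2.7, "TTCTATTATACTTC", 82, 331031, 331069),
    (39, 2.0, "AATATCATGATCGGGTCGACCAGGCCAGATCATGAGTGA", 97, 341180, 341258),
    (5, 12.0, "TATAA", 100, 386055, 386114),
    (17, 2.1, "GAACCCGGCCAGTAAGC", 88, 397284, 397317),
    (27, 2.4, "CCCTTTGAGTAATCTTTAGAATAAAAT", 97, 401709, 401772),
    (73, 2.0, "GCTTGAACCGTGTCATCGTACGTTGAAAACCCGTGCCATCGTACGTTGGTTCAAGTCTGGTAATGGCGGAAGA", 97, 402502, 402649),
    (18, 2.1, "TTCGATTGGCCTTTCACC", 90, 410843, 410880),
    (12, 2.1, "ATAGGTTCGAAG", 100, 421825, 421849),
    (22, 2.0, "CGAAGCCTAGAACCAGTGATGA", 95, 423272, 423315),
    (12, 5.5, "TTCTTCGTCCCT", 79, 425930, 425992),
    (21, 3.7, "CTTCTGCTTCTTCGGCCCTTT", 80, 425923, 426003),
    (33, 2.7, "TCATATTCTTTCAATATCTTGTCAATCCTCTCC", 84, 426116, 426205),
    (21, 2.0, "CGTTTTCTTTTAGAATTGTCT", 95, 428130, 428172),
    (26, 2.0, "CTTAGGACATACCCAGGCTAATATGA", 92, 435838, 435889),
    (16, 2.4, "GATTCCCTTCCGCTAT", 91, 485472, 485509),
    (17, 2.6, "GGAGTACGAGCTTCGAA", 96, 504996, 505039),
    (5, 6.0, "ATTAA", 100, 518373, 518402),
    (26, 2.0, "CAATAGAGAAAGAGGTGTCTGGTGAT", 88, 519478, 519529),
    (17, 2.0, "AGCGGATCAAAATCGTTG", 94, 519793, 519827),
    (15, 2.4, "AAGTTGCAGAGAGC", 90, 542376, 542408),
    (16, 2.4, "GATTCCCTTCCGCTAT", 91, 553627, 553664),
    (6, 7.7, "TTGCGC", 85, 580075, 580120),
    (17, 2.2, "CTTCTCCTTACTTGGCAG", 85, 630186, 630223),
    (20, 2.0, "AACCCATTATAATACTAAAG", 84, 736003, 736041),
    (5, 6.0, "ATTAG", 100, 741402, 741431),
    (16, 1.9, "GTTTGATAGTCTATTCTG", 88, 753255, 753287),
    (15, 2.5, "TAAGAAGAGTAACAG", 100, 757039, 757075),
    (19, 3.2, "ATTCGTTCCTAGAAGAATG", 97, 770740, 770799),
    (14, 2.1, "TCAGCCCTACAAAG", 93, 778607, 778635),
    (33, 1.9, "GCAACTCCAAATCATGGGGACGAATCCCCCCGA", 90, 783617, 783679),
    (18, 2.1, "TCTTTTCTATTAGATTAG", 89, 788660, 788696),
]

# Plastid-vs-mito homologous fragments: (identity %, aligned length,
# mismatches, gap opens, cp start, cp end, mt start, mt end,
# genes on the plastid side, genes on the mito side).
HOMOLOG_FRAGMENTS: list[tuple] = [
    (99.342, 9572, 8, 7, 133762, 143315, 796675, 787141,
     "rps12;rrn4.5;rrn23;trnA-UGC;orf42;trnI-GAU;rrn16;trnV-GAC", "trnV-GAC;trnI-GAT;trnA-TGC"),
    (99.342, 9572, 8, 7, 100337, 109890, 787141, 796675,
     "rps12;trnV-GAC;rrn16;trnI-GAU;trnA-UGC;orf42;rrn23;rrn4.5", "trnV-GAC;trnI-GAT;trnA-TGC"),
    (99.467, 1689, 1, 1, 155251, 156939, 249545, 247865, "rpl23;rpl2", ""),
    (99.467, 1689, 1, 1, 86713, 88401, 247865, 249545, "rpl2;rpl23", ""),
    (87.169, 982, 82, 19, 66276, 67217, 866044, 865067, "psbJ;psbL;psbF;psbE", ""),
    (85.504, 1021, 85, 32, 68281, 69295, 864681, 863718,
     "petL;petG;trnW-CCA;trnP-UGG", "trnW-CCA;trnW-CCA"),
    (81.926, 758, 99, 19, 51363, 52105, 779260, 779994, "ndhJ;ndhK", ""),
    (86.337, 505, 38, 9, 54541, 55027, 368120, 368611, "atpE;atpB", ""),
    (81.971, 416, 41, 18, 25898, 26287, 871628, 871221, "rpoB", ""),
    (74.045, 890, 174, 42, 139520, 140383, 245971, 245113, "rrn16", "rrn18"),
    (74.045, 890, 174, 42, 103269, 104132, 245113, 245971, "rrn16", "rrn18"),
    (95.918, 147, 6, 0, 36637, 36783, 340240, 340386, "psbC", ""),
    (91.275, 149, 13, 0, 31883, 32031, 709660, 709808, "trnD-GUC", "trnD-GTC"),
    (92.913, 127, 9, 0, 154860, 154986, 660602, 660476, "trnI-CAU", "trnM-CAT"),
    (92.913, 127, 9, 0, 88666, 88792, 660476, 660602, "trnI-CAU", "trnM-CAT"),
    (88.889, 126, 8, 2, 149246, 149371, 517689, 517570, "ycf2", ""),
    (88.889, 126, 8, 2, 94281, 94406, 517570, 517689, "ycf2", ""),
    (90.517, 116, 4, 1, 108480, 108595, 654611, 654503, "rrn23", ""),
    (90.517, 116, 4, 1, 135057, 135172, 654503, 654611, "rrn23", ""),
    (96.429, 84, 2, 1, 132349, 132431, 327451, 327368, "trnN-GUU", "trnN-GTT"),
    (96.429, 84, 2, 1, 111221, 111303, 327368, 327451, "trnN-GUU", "trnN-GTT"),
    (97.368, 76, 2, 0, 88717, 88792, 750548, 750473, "trnI-CAU", "ccmC;trnM-CAT"),
    (97.368, 76, 2, 0, 154860, 154935, 750473, 750548, "trnI-CAU", "ccmC;trnM-CAT"),
    (93.506, 77, 5, 0, 54227, 54303, 337154, 337230, "trnM-CAU", "trnM-CAT"),
    (100.0, 42, 0, 0, 122881, 122922, 787772, 787813, "ndhA", ""),
    (90.566, 53, 5, 0, 150673, 150725, 590443, 590391, "ycf2", ""),
    (90.566, 53, 5, 0, 92927, 92979, 590391, 590443, "ycf2", ""),
    (90.385, 52, 1, 3, 155041, 155092, 80066, 80019, "", ""),
    (90.385, 52, 1, 3, 88560, 88611, 80019, 80066, "", ""),
    (97.297, 37, 0, 1, 144192, 144228, 100452, 100417, "", ""),
    (97.297, 37, 0, 1, 99424, 99460, 100417, 100452, "", ""),
    (97.059, 34, 1, 0, 76213, 76246, 84470, 84437, "psbB", ""),
    (97.059, 34, 1, 0, 76213, 76246, 430900, 430867, "psbB", ""),
    (96.875, 32, 1, 0, 31989, 32020, 598206, 598175, "trnD-GUC", ""),
]


def homolog_fragment_objects():
    """The published fragment table as :class:`~mitokit.transfer.HomologFragment`."""
    from mitokit.transfer import HomologFragment

    out = []
    for ident, length, mism, gap, qs, qe, ss, se, gcp, gmt in HOMOLOG_FRAGMENTS:
        strand = "+" if ss <= se else "-"
        out.append(
            HomologFragment(
                identity=ident,
                length=length,
                mismatches=mism,
                gap_opens=gap,
                q_span=(min(qs, qe), max(qs, qe)),
                s_span=(min(ss, se), max(ss, se)),
                strand=strand,
                evalue=0.0,
                genes_cp=tuple(g for g in gcp.split(";") if g),
                genes_mt=tuple(g for g in gmt.split(";") if g),
            )
        )
    return out
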