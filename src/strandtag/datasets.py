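"""Printed summary tables from a published comparative RNA-seq study.

A study of the malaria vector *Anopheles funestus* compared poly(A)
selection with Ribo-Zero rRNA depletion on split total-RNA samples
(FANG-1 cleaned/uncleaned, FANG-2, FANG-3; eight libraries) aligned to the
1,392-scaffold draft assembly plus the mitochondrial genome.  Its published
alignment metrics, rRNA accounting, sense-tag-count summaries and
chromosome-arm assignment totals are bundled here as worked-example inputs
for the summarization operations in this package.

The per-gene 5.8S rRNA rows of the published rRNA table are typographically
garbled in print (and near zero); only the cleanly printed per-sample rRNA
totals are carried here.
"""

from __future__ import annotations

import pandas as pd

SAMPLES = (
    "F1_XP_RZ", "F1_XP_PA", "F1_RZ", "F1_PA", "F2_RZ", "F2_PA", "F3_RZ", "F3_PA",
)

#: sample -> (library method, biological pair)
DESIGN = {
    "F1_XP_RZ": ("ribozero", "F1_XP"),
    "F1_XP_PA": ("polyA", "F1_XP"),
    "F1_RZ": ("ribozero", "F1"),
    "F1_PA": ("polyA", "F1"),
    "F2_RZ": ("ribozero", "F2"),
    "F2_PA": ("polyA", "F2"),
    "F3_RZ": ("ribozero", "F3"),
    "F3_PA": ("polyA", "F3"),
}

#: alignment metrics: sample -> (reads to align (R1+R2), aligned reads)
ALIGNMENT_METRICS = {
    "F1_XP_RZ": (67_895_442, 37_480_868),
    "F1_XP_PA": (65_605_318, 38_878_773),
    "F1_RZ": (60_479_632, 21_002_025),
    "F1_PA": (63_555_450, 37_671_216),
    "F2_RZ": (43_733_908, 24_067_157),
    "F2_PA": (60_656_692, 35_610_912),
    "F3_RZ": (54_693_906, 25_673_135),
    "F3_PA": (60_211_066, 35_007_336),
}

#: sense tag counts for the six cleanly printed putative rRNA genes
RRNA_GENE_COUNTS = pd.DataFrame(
    {
        "F1_XP_RZ": [20_426, 47_771, 3_064, 768_823, 51_260],
        "F1_XP_PA": [10_311, 21_402, 4_289, 2_673_376, 6_613],
        "F1_RZ": [120_345, 154_805, 24_027, 402_555, 20_543],
        "F1_PA": [16_664, 31_516, 4_787, 2_351_745, 7_110],
        "F2_RZ": [19_706, 48_525, 6_759, 272_148, 10_995],
        "F2_PA": [28_057, 54_305, 8_400, 1_927_215, 3_066],
        "F3_RZ": [95_593, 145_807, 17_239, 491_163, 21_513],
        "F3_PA": [20_651, 41_643, 6_504, 2_382_882, 3_032],
    },
    index=["AFUN015486_28S", "AFUN015548_28S", "AFUN015372_18S",
           "16S_rRNA_mito", "12S_rRNA_mito"],
)

#: per-sample totals over all ten putative rRNA features, as printed
RRNA_TOTALS = {
    "F1_XP_RZ": 891_358,
    "F1_XP_PA": 2_715_997,
    "F1_RZ": 722_281,
    "F1_PA": 2_411_823,
    "F2_RZ": 358_134,
    "F2_PA": 2_021_046,
    "F3_RZ": 771_319,
    "F3_PA": 2_454_717,
}

#: sense tag counting summary: sample -> (total tags, sense-assigned,
#: antisense-assigned)
TAG_COUNT_SUMMARY = {
    "F1_XP_RZ": (23_097_597, 13_325_951, 1_293_286),
    "F1_XP_PA": (24_317_689, 16_120_214, 1_234_142),
    "F1_RZ": (13_163_225, 7_379_904, 836_937),
    "F1_PA": (23_325_917, 14_816_364, 1_355_508),
    "F2_RZ": (14_787_076, 8_421_844, 1_006_847),
    "F2_PA": (21_970_208, 14_411_931, 1_237_662),
    "F3_RZ": (16_130_058, 8_495_428, 997_369),
    "F3_PA": (21_753_683, 13_447_922, 1_126_921),
}

#: published non-rRNA sense-assigned counts and percentages (for cross-checks)
NON_RRNA_SENSE_PRINTED = {
    "F1_XP_RZ": (12_434_593, 53.84),
    "F1_XP_PA": (13_404_217, 55.12),
    "F1_RZ": (6_657_623, 50.58),
    "F1_PA": (12_404_541, 53.18),
    "F2_RZ": (8_063_710, 54.53),
    "F2_PA": (12_390_885, 56.40),
    "F3_RZ": (7_724_109, 47.89),
    "F3_PA": (10_993_205, 50.53),
}

#: chromosome-arm assignment: arm -> (scaffold count, summed length in bp)
ARM_ASSIGNMENT_ROWS = {
    "X": (27, 16_915_574),
    "2R": (78, 52_607_791),
    "2L": (57, 42_990_663),
    "3R": (72, 41_849_609),
    "3L": (52, 29_153_900),
}

GENOME_LENGTH_BP = 225_223_604
TOTAL_SCAFFOLDS = 1_392
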