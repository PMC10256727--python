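"""Published values from the termite miRNA reference-gene study.

Eight candidate reference miRNAs (plus the *let-7-3p* validation target)
were assayed by stem-loop RT-qPCR in *Coptotermes formosanus* workers
during methoprene-induced soldier differentiation, in two body-part
strata (head; thorax + abdomen).  The study published, for each stratum,
the per-gene stability values under four algorithms (comparative
delta-Ct, NormFinder, geNorm, BestKeeper) together with the consensus
geometric-mean-of-ranks (GM) column, and, for each assay, the sequences
and amplification efficiencies.

The raw Ct measurements were not deposited, so the per-method stability
values below are the inputs from which the consensus ranking can be
recomputed; they also serve as a worked example for
:mod:`refstab.consensus`.
"""

from __future__ import annotations

from .ct_io import AssayDesign

__all__ = [
    "CANDIDATE_GENES",
    "TARGET_GENE",
    "EFFICIENCY_PERCENT",
    "ASSAY_DESIGNS",
    "STABILITY_VALUES",
    "PUBLISHED_GM",
    "GENORM_FINAL_PAIR",
]

CANDIDATE_GENES = [
    "miR-193-3p",
    "miR-971-5p",
    "miR-3049-5p",
    "miR-216-5p",
    "miR-7-3p",
    "novel-m0649-3p",
    "miR-2788-3p",
    "U6",
]

TARGET_GENE = "let-7-3p"

#: Standard-curve amplification efficiency, percent (100 = perfect doubling).
EFFICIENCY_PERCENT = {
    "miR-193-3p": 113.3,
    "miR-971-5p": 118.0,
    "miR-3049-5p": 100.5,
    "miR-216-5p": 114.5,
    "miR-7-3p": 106.4,
    "novel-m0649-3p": 110.2,
    "miR-2788-3p": 112.2,
    "U6": 104.0,
    "let-7-3p": 105.6,
}

#: Published assay sequences: miRNA (RNA), stem-loop RT primer, probe
#: (5'-FAM / 3'-MGB), forward primer.
ASSAY_DESIGNS = {
    "miR-193-3p": AssayDesign(
        gene="miR-193-3p",
        mirna_seq="UACUGGCCUGCUAAGUCCCAAG",
        stemloop_primer="GTCGTATCCAGTGCAGGGTCCGAGGTATTCGCACTGGATACGACCTTGGG",
        probe="(FAM)ATACGACCTTGGGACT(MGB)",
        forward_primer="CGTGTACTGGCCTGCTAAGT",
    ),
    "miR-971-5p": AssayDesign(
        gene="miR-971-5p",
        mirna_seq="CACUCUAAGCUCGAACACCAAGC",
        stemloop_primer="GTCGTATCCAGTGCAGGGTCCGAGGTATTCGCACTGGATACGACGCTTGG",
        probe="(FAM)ATACGACGCTTGGTG(MGB)",
        forward_primer="GCGTCACTCTAAGCTCGAACA",
    ),
    "miR-3049-5p": AssayDesign(
        gene="miR-3049-5p",
        mirna_seq="UCGGGAAGGCAGUUGCGGCGGACU",
        stemloop_primer="GTCGTATCCAGTGCAGGGTCCGAGGTATTCGCACTGGATACGACAGTCCG",
        probe="(FAM)ATACGACAGTCCGCC(MGB)",
        forward_primer="TCGGGAAGGCAGTTGCG",
    ),
    "miR-216-5p": AssayDesign(
        gene="miR-216-5p",
        mirna_seq="AAAUAUCAGCUGGUAAUUCUGA",
        stemloop_primer="GTCGTATCCAGTGCAGGGTCCGAGGTATTCGCACTGGATACGACTCAGAA",
        probe="(FAM)TGGATACGACTCAGAAT(MGB)",
        forward_primer="CCGAGCGAAATATCAGCTGGTAA",
    ),
    "miR-7-3p": AssayDesign(
        gene="miR-7-3p",
        mirna_seq="CAAGAAAUCACUCAUCUUCCUG",
        stemloop_primer="GTCGTATCCAGTGCAGGGTCCGAGGTATTCGCACTGGATACGACAGGAAG",
        probe="(FAM)TGGATACGACAGGAAG(MGB)",
        forward_primer="CGACGCCAAGAAATCACTCAT",
    ),
    "novel-m0649-3p": AssayDesign(
        gene="novel-m0649-3p",
        mirna_seq="CCUGUAUAUGGUCACUCUCCUG",
        stemloop_primer="GTCGTATCCAGTGCAGGGTCCGAGGTATTCGCACTGGATACGACAGGAGA",
        probe="(FAM)TGGATACGACAGGAGAG(MGB)",
        forward_primer="CGTGGAGCCTGTATATGGTCAC",
    ),
    "miR-2788-3p": AssayDesign(
        gene="miR-2788-3p",
        mirna_seq="CAAUGCCCUUGGAAAUCCCAG",
        stemloop_primer="GTCGTATCCAGTGCAGGGTCCGAGGTATTCGCACTGGATACGACTGGGAT",
        probe="(FAM)TGGATACGACTGGGATT(MGB)",
        forward_primer="CGAGGTCAATGCCCTTGGAA",
    ),
    "U6": AssayDesign(
        gene="U6",
        mirna_seq=(
            "ACUAAAAUUGGAACGAUACAGAGAAGAUUAGCAUGGCCCCUGCGCAAGGAUGACACG"
            "CAAAAUCGUGAAGCGUUCCACAUUUUU"
        ),
        stemloop_primer="GTCGTATCCAGTGCAGGGTCCGAGGTATTCGCACTGGATACGACAAAAAT",
        probe="(FAM)CTGGATACGACAAAAATG(MGB)",
        forward_primer="GCAAAATCGTGAAGCGTTCCA",
    ),
    "let-7-3p": AssayDesign(
        gene="let-7-3p",
        mirna_seq="CUGUACAACUUGCUAACUUUCC",
        stemloop_primer="GTCGTATCCAGTGCAGGGTCCGAGGTATTCGCACTGGATACGACGGAAAG",
        probe="(FAM)TGGATACGACGGAAAGT(MGB)",
        forward_primer="TGCGACCTGTACAACTTGCTAA",
    ),
}

#: Per-method stability values as published, per stratum.  Each method maps
#: to a list of (gene, value) in the published order (most stable first).
#: Lower is more stable for every method except ``bestkeeper_r``, where a
#: larger correlation with the BestKeeper index indicates more stability.
STABILITY_VALUES = {
    "head": {
        "delta_ct": [
            ("novel-m0649-3p", 0.68),
            ("miR-193-3p", 0.74),
            ("miR-971-5p", 0.78),
            ("miR-7-3p", 0.82),
            ("miR-2788-3p", 0.84),
            ("miR-3049-5p", 0.85),
            ("miR-216-5p", 0.97),
            ("U6", 1.39),
        ],
        "normfinder": [
            ("novel-m0649-3p", 0.178),
            ("miR-193-3p", 0.429),
            ("miR-7-3p", 0.443),
            ("miR-971-5p", 0.550),
            ("miR-2788-3p", 0.642),
            ("miR-3049-5p", 0.645),
            ("miR-216-5p", 0.719),
            ("U6", 1.328),
        ],
        "genorm": [
            ("novel-m0649-3p", 0.374),
            ("miR-193-3p", 0.374),
            ("miR-971-5p", 0.420),
            ("miR-2788-3p", 0.447),
            ("miR-3049-5p", 0.479),
            ("miR-7-3p", 0.596),
            ("miR-216-5p", 0.714),
            ("U6", 0.883),
        ],
        "bestkeeper_sd": [
            ("novel-m0649-3p", 0.40),
            ("miR-971-5p", 0.41),
            ("miR-3049-5p", 0.42),
            ("miR-2788-3p", 0.43),
            ("miR-193-3p", 0.44),
            ("miR-7-3p", 0.68),
            ("miR-216-5p", 1.01),
            ("U6", 1.46),
        ],
        "bestkeeper_r": [
            ("miR-216-5p", 0.922),
            ("U6", 0.918),
            ("novel-m0649-3p", 0.913),
            ("miR-7-3p", 0.857),
            ("miR-193-3p", 0.762),
            ("miR-971-5p", 0.633),
            ("miR-2788-3p", 0.523),
            ("miR-3049-5p", 0.512),
        ],
    },
    "thorax_abdomen": {
        "delta_ct": [
            ("novel-m0649-3p", 0.95),
            ("miR-7-3p", 1.04),
            ("miR-971-5p", 1.12),
            ("miR-2788-3p", 1.14),
            ("miR-193-3p", 1.18),
            ("miR-3049-5p", 1.29),
            ("miR-216-5p", 1.41),
            ("U6", 1.75),
        ],
        "normfinder": [
            ("novel-m0649-3p", 0.111),
            ("miR-7-3p", 0.446),
            ("miR-971-5p", 0.765),
            ("miR-2788-3p", 0.767),
            ("miR-193-3p", 0.792),
            ("miR-3049-5p", 1.003),
            ("miR-216-5p", 1.118),
            ("U6", 1.597),
        ],
        "genorm": [
            ("novel-m0649-3p", 0.675),
            ("miR-971-5p", 0.675),
            ("miR-2788-3p", 0.722),
            ("miR-7-3p", 0.791),
            ("miR-193-3p", 0.853),
            ("miR-3049-5p", 0.915),
            ("miR-216-5p", 1.063),
            ("U6", 1.236),
        ],
        # The two printed 1.33 values are a rounding collision; the published
        # row order resolves it (see consensus module tie policy).
        "bestkeeper_sd": [
            ("novel-m0649-3p", 1.16),
            ("miR-2788-3p", 1.28),
            ("miR-3049-5p", 1.31),
            ("miR-971-5p", 1.33),
            ("miR-193-3p", 1.33),
            ("miR-7-3p", 1.50),
            ("U6", 1.66),
            ("miR-216-5p", 1.79),
        ],
        "bestkeeper_r": [
            ("novel-m0649-3p", 0.977),
            ("miR-7-3p", 0.972),
            ("miR-971-5p", 0.916),
            ("miR-216-5p", 0.898),
            ("miR-2788-3p", 0.892),
            ("miR-193-3p", 0.888),
            ("miR-3049-5p", 0.846),
            ("U6", 0.697),
        ],
    },
}

#: The geNorm stepwise exclusion cannot separate the last two genes; the
#: published final pair per stratum (identical stability values) shares
#: rank 1 in the consensus.
GENORM_FINAL_PAIR = {
    "head": ("novel-m0649-3p", "miR-193-3p"),
    "thorax_abdomen": ("novel-m0649-3p", "miR-971-5p"),
}

#: Published consensus GM values (geometric mean of the four method ranks).
PUBLISHED_GM = {
    "head": {
        "novel-m0649-3p": 1.00,
        "miR-193-3p": 2.11,
        "miR-971-5p": 2.91,
        "miR-2788-3p": 4.47,
        "miR-7-3p": 4.56,
        "miR-3049-5p": 4.82,
        "miR-216-5p": 7.00,
        "U6": 8.00,
    },
    "thorax_abdomen": {
        "novel-m0649-3p": 1.00,
        "miR-971-5p": 2.45,
        "miR-7-3p": 3.13,
        "miR-2788-3p": 3.13,
        "miR-193-3p": 5.00,
        "miR-3049-5p": 5.05,
        "miR-216-5p": 7.24,
        "U6": 7.74,
    },
}
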