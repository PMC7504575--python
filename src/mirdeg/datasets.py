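"""Bundled worked-example tables.

``example_mirna_tf_pairs`` is a small published table of durum wheat
miRNA-transcription-factor pairs with antagonistic regulatory patterns in a
stress-tolerant genotype: each row carries the miRNA and target log2
fold-changes under one stress condition (water-deficit WS, heat HS, or
combined WH), the pairing type, and the TF family.  A miRNA fold-change of
-inf denotes the reporting convention for a miRNA whose expression under
stress was zero (a negative fold-change of infinite magnitude).  All rows
were reported significant at p < 0.05; the table ships a representative
p = 0.01 for both layers so the rows can be pushed through the classifier.

The id grammar in the miRNA column is the variant grammar this package
emits: ``_L-1`` (1 nt shorter at the 3' end), ``_1ss9CG`` (one substitution,
position 9, C -> G), ``-p5`` (5' precursor-arm-derived mature), etc.
"""

from __future__ import annotations

import pandas as pd

_INF = float("inf")

_ROWS = [
    # mirna, target transcript, target annotation, mirna_log2fc, target_log2fc, stress, pairing, tf_family
    ("osa-miR398a", "TRITD_1Bv1G135100-4", "DREB transcription factor 3A", -1.23, 2.95, "WS", "Newly discovered", "DREB"),
    ("osa-miR398a", "TRITD_1Bv1G135100-4", "DREB transcription factor 3A", -2.67, 1.75, "HS", "Newly discovered", "DREB"),
    ("osa-miR398a", "TRITD_1Bv1G135100-4", "DREB transcription factor 3A", -1.34, 1.75, "WH", "Newly discovered", "DREB"),
    ("mdm-miR397a_1ss21AT", "TRITD_2Bv1G034790", "NAC transcription factor (plastid)", -_INF, 3.74, "HS", "Newly discovered", "NAC"),
    ("osa-miR398a_L+1R-1", "TRITD_3Av1G235010-2", "NAC transcription factor 6A", -2.05, 4.13, "HS", "Newly discovered", "NAC"),
    ("osa-miR398a_L+1R-1", "TRITD_3Av1G235010-2", "NAC transcription factor 6A", -0.92, 2.58, "WH", "Newly discovered", "NAC"),
    ("osa-miR444b.1", "TRITD_2Av1G026820", "NAC transcription factor (plastid)", -1.77, 3.40, "HS", "Newly discovered", "NAC"),
    ("osa-miR444b.1", "TRITD_2Av1G026820", "NAC transcription factor (plastid)", -1.50, 1.94, "WH", "Newly discovered", "NAC"),
    ("osa-miR444b.1", "TRITD_5Av1G170450-2", "NAC domain-containing protein 41", -1.50, 2.90, "WH", "Newly discovered", "NAC"),
    ("osa-miR444b.1", "TRITD_5Bv1G161590", "NAC domain-containing protein 41", -1.50, 3.59, "WH", "Newly discovered", "NAC"),
    ("tae-MIR1128-p5_1ss13AG", "TRITD_4Bv1G108860", "NAC domain-containing protein 92-like", -_INF, 4.16, "HS", "Newly discovered", "NAC"),
    ("tae-MIR5384-p5", "TRITD_5Bv1G161590", "NAC domain-containing protein 41", -1.98, 3.59, "WH", "Newly discovered", "NAC"),
    ("ata-miR166d-5p", "TRITD_7Av1G051530-5", "auxin response factor 16", -2.37, 1.60, "WH", "Newly discovered", "ARF"),
    ("osa-miR167a-5p_R+1", "TRITD_6Av1G046710", "auxin response factor 6-like", -1.00, 1.59, "HS", "Conserved", "ARF"),
    ("tae-miR408_L-1", "TRITD_7Bv1G194180-3", "auxin response factor 17", -3.62, 2.21, "WH", "Newly discovered", "ARF"),
    ("ata-miR528-3p_1ss4GC", "TRITD_7Bv1G194180-3", "auxin response factor 17", -_INF, 1.81, "HS", "Newly discovered", "ARF"),
    ("ata-miR528-3p_1ss4GC", "TRITD_7Bv1G194180-3", "auxin response factor 17", -2.60, 2.21, "WH", "Newly discovered", "ARF"),
    ("ata-miR528-3p_1ss4GC", "TRITD_7Av1G245930-4", "auxin response factor 17", -2.60, 1.79, "WH", "Newly discovered", "ARF"),
    ("bdi-miR394", "TRITD_1Bv1G030900-5", "WRKY14 transcription factor", -0.76, 1.76, "WH", "Newly discovered", "WRKY"),
    ("osa-miR396e-5p_1ss19CT", "TRITD_5Bv1G146000-2", "probable WRKY transcription factor 2", -2.32, 2.04, "WH", "Newly discovered", "WRKY"),
    ("tae-miR398", "TRITD_7Av1G028020", "putative WRKY transcription factor 72", -_INF, 1.74, "HS", "Newly discovered", "WRKY"),
    ("osa-miR444b.1_1ss21CT", "TRITD_3Av1G213210", "putative WRKY transcription factor 33", -1.32, 2.58, "HS", "Newly discovered", "WRKY"),
    ("tae-MIR5048-p3_2ss18TG21GA", "TRITD_3Av1G074690-4", "WRKY transcription factor, partial", -0.66, 1.63, "HS", "Newly discovered", "WRKY"),
    ("ata-MIR9674b-p5", "TRITD_3Av1G213210", "putative WRKY transcription factor 33", -3.53, 2.58, "HS", "Newly discovered", "WRKY"),
    ("ata-MIR9674b-p5", "TRITD_3Bv1G195790", "WRKY27 transcription factor", -3.53, 1.88, "HS", "Newly discovered", "WRKY"),
    ("osa-miR530-5p_L+1_1ss21AT", "TRITD_5Av1G046770", "MYB transcription factor 79", -_INF, 4.00, "HS", "Newly discovered", "MYB"),
    ("ata-miR5168-5p", "TRITD_5Av1G118710", "transcription factor MYB44-like", -_INF, 4.57, "HS", "Newly discovered", "MYB"),
    ("ata-miR5168-5p", "TRITD_5Av1G118710", "transcription factor MYB44-like", -_INF, 2.67, "WH", "Newly discovered", "MYB"),
    ("tae-MIR9772-p5", "TRITD_5Av1G207760-4", "MYB-related protein", -0.66, 2.95, "HS", "Newly discovered", "MYB"),
    ("tae-miR408_L-1", "TRITD_6Av1G199570-2", "bZIP transcription factor", -3.55, 3.69, "HS", "Newly discovered", "bZIP"),
    ("tae-MIR5384-p5", "TRITD_3Bv1G212830", "bZIP domain containing protein", -1.93, 2.98, "HS", "Newly discovered", "bZIP"),
    ("tae-MIR5384-p5", "TRITD_3Bv1G212830", "bZIP domain containing protein", -1.98, 1.97, "WH", "Newly discovered", "bZIP"),
    ("bdi-MIR530b-p3_1ss14GC", "TRITD_3Av1G067970", "bHLH13-like", -_INF, 2.14, "HS", "Newly discovered", "bHLH"),
    ("tae-MIR9662b-p5_1ss9CG", "TRITD_2Av1G047140", "bHLH47", -1.66, 2.42, "HS", "Newly discovered", "bHLH"),
]


def example_mirna_tf_pairs() -> pd.DataFrame:
    """Worked-example miRNA-TF pairs with antagonistic patterns (see module docs)."""
    df = pd.DataFrame(
        _ROWS,
        columns=[
            "mirna", "transcript", "target_annotation", "mirna_log2fc",
            "target_log2fc", "stress", "pairing_type", "tf_family",
        ],
    )
    df["mirna_p"] = 0.01
    df["target_p"] = 0.01
    return df
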