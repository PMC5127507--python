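"""Published count tables from the triplicate-vs-single SEPT9 screening study.

Counts (positives, total) are the ground truth; the percentage column is
carried verbatim as printed. Two cells are internally inconsistent at
1-decimal rounding and are listed in :data:`PCT_MISMATCHES`:

* printed 82.4% for 303/369 = 82.1% (the CRC 1/3 figure, reprinted in
  tables 2, 3 and 4);
* table4 ("Other GI Diseases", "3/3"): printed 3.4% but 2/47 = 4.3%.

The published pairwise chi-square comparisons are encoded in
:data:`PRINTED_CHI2_COMPARISONS` with the 2x2 counts they derive from.
"""

from __future__ import annotations

from typing import NamedTuple


class FixtureCell(NamedTuple):
    positives: int
    total: int
    printed_pct: float


ALGORITHMS = ("1/3", "2/3", "1/1", "3/3")

# Sensitivity/specificity for CRC vs NED under each interpretation algorithm.
TABLE2 = {
    ("Sensitivity", "1/3"): FixtureCell(303, 369, 82.4),
    ("Sensitivity", "2/3"): FixtureCell(277, 369, 75.1),
    ("Sensitivity", "1/1"): FixtureCell(263, 369, 71.3),
    ("Sensitivity", "3/3"): FixtureCell(214, 369, 58.0),
    ("Specificity", "1/3"): FixtureCell(402, 490, 82.0),
    ("Specificity", "2/3"): FixtureCell(476, 490, 97.1),
    ("Specificity", "1/1"): FixtureCell(454, 490, 92.7),
    ("Specificity", "3/3"): FixtureCell(484, 490, 98.8),
}

# Positive detection rate per CRC stage.
TABLE3 = {
    ("Stage 0", "1/3"): FixtureCell(12, 21, 57.1),
    ("Stage 0", "2/3"): FixtureCell(11, 21, 52.4),
    ("Stage 0", "1/1"): FixtureCell(10, 21, 47.6),
    ("Stage 0", "3/3"): FixtureCell(7, 21, 33.3),
    ("Stage I", "1/3"): FixtureCell(27, 42, 64.3),
    ("Stage I", "2/3"): FixtureCell(23, 42, 54.8),
    ("Stage I", "1/1"): FixtureCell(21, 42, 50.0),
    ("Stage I", "3/3"): FixtureCell(14, 42, 33.3),
    ("Stage II", "1/3"): FixtureCell(92, 105, 87.6),
    ("Stage II", "2/3"): FixtureCell(87, 105, 82.9),
    ("Stage II", "1/1"): FixtureCell(82, 105, 78.1),
    ("Stage II", "3/3"): FixtureCell(69, 105, 65.7),
    ("Stage III", "1/3"): FixtureCell(115, 131, 87.8),
    ("Stage III", "2/3"): FixtureCell(103, 131, 78.6),
    ("Stage III", "1/1"): FixtureCell(100, 131, 76.3),
    ("Stage III", "3/3"): FixtureCell(84, 131, 64.1),
    ("Stage IV", "1/3"): FixtureCell(14, 15, 93.3),
    ("Stage IV", "2/3"): FixtureCell(13, 15, 86.7),
    ("Stage IV", "1/1"): FixtureCell(14, 15, 93.3),
    ("Stage IV", "3/3"): FixtureCell(12, 15, 80.0),
    ("Not specified", "1/3"): FixtureCell(43, 55, 78.2),
    ("Not specified", "2/3"): FixtureCell(40, 55, 72.7),
    ("Not specified", "1/1"): FixtureCell(36, 55, 65.5),
    ("Not specified", "3/3"): FixtureCell(28, 55, 50.9),
    ("Overall", "1/3"): FixtureCell(303, 369, 82.4),
    ("Overall", "2/3"): FixtureCell(277, 369, 75.1),
    ("Overall", "1/1"): FixtureCell(263, 369, 71.3),
    ("Overall", "3/3"): FixtureCell(214, 369, 58.0),
}

# Positive detection rate per diagnostic group.
TABLE4 = {
    ("CRC", "1/3"): FixtureCell(303, 369, 82.4),
    ("CRC", "2/3"): FixtureCell(277, 369, 75.1),
    ("CRC", "1/1"): FixtureCell(263, 369, 71.3),
    ("CRC", "3/3"): FixtureCell(214, 369, 58.0),
    ("Adenoma", "1/3"): FixtureCell(42, 113, 37.2),
    ("Adenoma", "2/3"): FixtureCell(30, 113, 26.5),
    ("Adenoma", "1/1"): FixtureCell(29, 113, 25.7),
    ("Adenoma", "3/3"): FixtureCell(17, 113, 15.0),
    ("Polyps", "1/3"): FixtureCell(23, 87, 26.4),
    ("Polyps", "2/3"): FixtureCell(8, 87, 9.2),
    ("Polyps", "1/1"): FixtureCell(11, 87, 12.6),
    ("Polyps", "3/3"): FixtureCell(3, 87, 3.4),
    ("IBD", "1/3"): FixtureCell(7, 27, 25.9),
    ("IBD", "2/3"): FixtureCell(5, 27, 18.5),
    ("IBD", "1/1"): FixtureCell(5, 27, 18.5),
    ("IBD", "3/3"): FixtureCell(2, 27, 7.4),
    ("Other GI Diseases", "1/3"): FixtureCell(11, 47, 23.4),
    ("Other GI Diseases", "2/3"): FixtureCell(4, 47, 8.5),
    ("Other GI Diseases", "1/1"): FixtureCell(6, 47, 12.8),
    ("Other GI Diseases", "3/3"): FixtureCell(2, 47, 3.4),
    ("NED", "1/3"): FixtureCell(88, 490, 18.0),
    ("NED", "2/3"): FixtureCell(14, 490, 2.9),
    ("NED", "1/1"): FixtureCell(36, 490, 7.3),
    ("NED", "3/3"): FixtureCell(6, 490, 1.2),
}

# Triplicate assay (2/3 rule) vs single-well assay, per group/stage.
TABLE5 = {
    ("CRC Overall", "epi_procolon_2_2/3"): FixtureCell(277, 369, 75.1),
    ("CRC Overall", "sensicolon_1/1"): FixtureCell(223, 291, 76.6),
    ("Stage I", "epi_procolon_2_2/3"): FixtureCell(23, 42, 54.8),
    ("Stage I", "sensicolon_1/1"): FixtureCell(24, 37, 64.9),
    ("Stage II", "epi_procolon_2_2/3"): FixtureCell(87, 105, 82.9),
    ("Stage II", "sensicolon_1/1"): FixtureCell(48, 66, 72.7),
    ("Stage III", "epi_procolon_2_2/3"): FixtureCell(103, 131, 78.6),
    ("Stage III", "sensicolon_1/1"): FixtureCell(65, 82, 79.3),
    ("Stage IV", "epi_procolon_2_2/3"): FixtureCell(13, 15, 86.7),
    ("Stage IV", "sensicolon_1/1"): FixtureCell(31, 33, 93.9),
    ("Adenoma", "epi_procolon_2_2/3"): FixtureCell(30, 113, 26.5),
    ("Adenoma", "sensicolon_1/1"): FixtureCell(21, 214, 9.8),
    ("Polyps", "epi_procolon_2_2/3"): FixtureCell(8, 87, 9.2),
    ("Polyps", "sensicolon_1/1"): FixtureCell(6, 116, 5.2),
    ("Other GI Diseases", "epi_procolon_2_2/3"): FixtureCell(4, 47, 8.5),
    ("Other GI Diseases", "sensicolon_1/1"): FixtureCell(4, 108, 3.7),
    ("NED", "epi_procolon_2_2/3"): FixtureCell(14, 490, 2.9),
    ("NED", "sensicolon_1/1"): FixtureCell(12, 295, 4.1),
}

#: Cells whose printed percentage disagrees with positives/total at
#: 1-decimal rounding; counts are authoritative. The 82.4%-for-303/369
#: cell is the same figure reprinted in three tables.
PCT_MISMATCHES = {
    ("table2", "Sensitivity", "1/3"),
    ("table3", "Overall", "1/3"),
    ("table4", "CRC", "1/3"),
    ("table4", "Other GI Diseases", "3/3"),
}


class Chi2Comparison(NamedTuple):
    """One published pairwise comparison with its 2x2 counts.

    ``a``/``b`` are positives/negatives under the first condition,
    ``c``/``d`` under the second; ``printed_stat`` is the chi-square value
    as published.
    """

    label: str
    a: int
    b: int
    c: int
    d: int
    printed_stat: float


def _from_cells(label, cell1: FixtureCell, cell2: FixtureCell, stat):
    return Chi2Comparison(label, cell1.positives,
                          cell1.total - cell1.positives, cell2.positives,
                          cell2.total - cell2.positives, stat)


PRINTED_CHI2_COMPARISONS = [
    # sensitivity of the 1/3 rule vs each alternative (positives = detected)
    _from_cells("sensitivity 1/3 vs 2/3",
                TABLE2[("Sensitivity", "1/3")],
                TABLE2[("Sensitivity", "2/3")], 5.44),
    _from_cells("sensitivity 1/3 vs 1/1",
                TABLE2[("Sensitivity", "1/3")],
                TABLE2[("Sensitivity", "1/1")], 12.13),
    _from_cells("sensitivity 1/3 vs 3/3",
                TABLE2[("Sensitivity", "1/3")],
                TABLE2[("Sensitivity", "3/3")], 51.16),
    # specificity of the 3/3 rule vs each alternative (positives = negative
    # test among NED)
    _from_cells("specificity 3/3 vs 1/3",
                TABLE2[("Specificity", "3/3")],
                TABLE2[("Specificity", "1/3")], 79.12),
    _from_cells("specificity 3/3 vs 1/1",
                TABLE2[("Specificity", "3/3")],
                TABLE2[("Specificity", "1/1")], 22.39),
    _from_cells("specificity 3/3 vs 2/3",
                TABLE2[("Specificity", "3/3")],
                TABLE2[("Specificity", "2/3")], 3.26),
    # disease-group detection rate vs NED under the same rule
    _from_cells("adenoma vs NED, 1/3",
                TABLE4[("Adenoma", "1/3")], TABLE4[("NED", "1/3")], 20.04),
    _from_cells("adenoma vs NED, 2/3",
                TABLE4[("Adenoma", "2/3")], TABLE4[("NED", "2/3")], 76.19),
    _from_cells("polyps vs NED, 2/3",
                TABLE4[("Polyps", "2/3")], TABLE4[("NED", "2/3")], 8.09),
    _from_cells("IBD vs NED, 2/3",
                TABLE4[("IBD", "2/3")], TABLE4[("NED", "2/3")], 17.73),
    # triplicate 2/3 rule vs single-well assay
    _from_cells("CRC: triplicate 2/3 vs single-well",
                TABLE5[("CRC Overall", "epi_procolon_2_2/3")],
                TABLE5[("CRC Overall", "sensicolon_1/1")], 0.22),
    _from_cells("adenoma: triplicate 2/3 vs single-well",
                TABLE5[("Adenoma", "epi_procolon_2_2/3")],
                TABLE5[("Adenoma", "sensicolon_1/1")], 15.73),
]

#: Enrolment by diagnostic group, and the CRC stage mix.
TABLE1_GROUP_SIZES = {
    "CRC": 369, "ADENOMA": 113, "POLYPS": 87, "IBD": 27,
    "OTHER_GI": 47, "NED": 490,
}
TABLE1_STAGE_MIX = {
    "0": 21, "I": 42, "II": 105, "III": 131, "IV": 15, "NOT_SPECIFIED": 55,
}

#: Plasma-equivalent operating points (volume mL, sensitivity, specificity).
#: 2.7 mL is the triplicate assay's three pooled wells under the 2/3 rule;
#: 1.8 mL the single-well assay; 1.0 mL the triplicate assay's single-well
#: average (the 1/1 column of TABLE2).
TABLE6_OPERATING_POINTS = [
    (2.7, 0.751, 0.971),
    (1.8, 0.766, 0.959),
    (1.0, 0.713, 0.927),
]
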