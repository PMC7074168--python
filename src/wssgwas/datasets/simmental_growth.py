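"""Published summary statistics for growth traits in a Chinese Simmental
beef-cattle population (weighted single-step GWAS study).

These are printed summary tables, not raw data: per-trait descriptive
statistics with REML variance components, and the per-trait genomic windows
that explained more than 1% of the additive genetic variance (window region,
gVar%, top SNP, nearest candidate gene and its distance). They serve as
worked inputs for the package's summary arithmetic (CV%, sigma_p2, h2,
window accounting, nonredundant-region counting).

Traits: BW birth weight, YW yearling weight, BYADG average daily gain from
birth to yearling, MW18 body weight at 18 months.
"""
from __future__ import annotations

import pandas as pd

#: Descriptive statistics and variance components, one row per trait.
TRAIT_TABLE = pd.DataFrame(
    [
        # trait, N, mean, sd, min, max, cv_pct, sigma_a2, sigma_e2, sigma_p2, h2, se_h2
        ("BW", 6022, 44.96, 5.38, 29.0, 61.0, 11.97, 10.165, 14.150, 24.315, 0.42, 0.03),
        ("YW", 3996, 418.21, 68.37, 264.94, 608.65, 16.36, 444.650, 1352.400, 1797.050, 0.24, 0.03),
        ("BYADG", 3996, 1.03, 0.19, 0.60, 1.54, 18.45, 0.003, 0.010, 0.013, 0.23, 0.02),
        ("MW18", 3137, 587.41, 109.36, 376.84, 905.24, 18.61, 1193.400, 1598.000, 2791.400, 0.43, 0.03),
    ],
    columns=[
        "trait", "n", "mean", "sd", "min", "max", "cv_percent",
        "sigma_a2", "sigma_e2", "sigma_p2", "h2", "se_h2",
    ],
)

_WINDOW_COLUMNS = ["chrom", "start_bp", "end_bp", "gvar_percent", "top_snp",
                   "candidate_gene", "distance"]

#: >1% windows for birth weight (18 regions).
BW_WINDOWS = pd.DataFrame(
    [
        (10, 64843548, 64888989, 7.89, "BovineHD1000018698", "SQOR", "195750"),
        (18, 46973033, 47054361, 6.52, "BovineHD1800013865", "TBCB", "971"),
        (13, 32898989, 32942587, 4.51, "BovineHD1300009582", "CACNB2", "106042"),
        (17, 59422381, 59533974, 4.23, "BovineHD1700016840", "WSB2", "634"),
        (21, 54246453, 54304950, 4.17, "BovineHD2100015513", "DYNLL1", "49145"),
        (1, 86864010, 87000954, 3.00, "BovineHD0100024730", "CCDC39", "89435"),
        (18, 43486335, 43539576, 2.83, "BovineHD1800012856", "CEP89", "within"),
        (7, 25274362, 25344621, 2.51, "BovineHD0700006961", "CHSY3", "within"),
        (10, 22200536, 22227480, 2.20, "BovineHD4100007964", "TRDC", "within"),
        (21, 18442926, 18507549, 2.06, "BovineHD4100015053", "/", "/"),
        (18, 9390632, 9440030, 1.78, "BovineHD4100013431", "CDH13", "122107"),
        (16, 55454686, 55576782, 1.57, "BovineHD1600015438", "BOVAGGRUS", "12062"),
        (2, 84272058, 84486086, 1.35, "BovineHD0200024049", "SLC39A10", "461944"),
        (27, 17515069, 17628482, 1.35, "BovineHD2700005087", "/", "/"),
        (1, 93966859, 94071139, 1.24, "BovineHD0100026650", "NLGN1", "334630"),
        (20, 58103188, 58151048, 1.14, "BovineHD2000016087", "ANKH", "274075"),
        (22, 21743429, 21782083, 1.14, "BovineHD2200006300", "ITPR1", "within"),
        (3, 83073814, 83124751, 1.07, "BovineHD0300023782", "ATG4C", "225105"),
    ],
    columns=_WINDOW_COLUMNS,
)

#: >1% windows for yearling weight (14 regions).
YW_WINDOWS = pd.DataFrame(
    [
        (19, 28728158, 28766002, 11.80, "BovineHD1900008433", "MYH10", "within"),
        (24, 30102158, 30164301, 10.30, "BovineHD2400008151", "CHST9", "within"),
        (3, 106567276, 106628358, 9.47, "BovineHD0300030609", "RLF", "within"),
        (3, 103471058, 103518431, 6.91, "BovineHD0300029636", "FAM183A", "27683"),
        (2, 98892271, 98968329, 4.95, "BovineHD0200028465", "CPS1", "within"),
        (3, 107082578, 107188510, 3.09, "BovineHD4100002437", "PABPC4", "1629"),
        (3, 105809585, 105893206, 1.92, "BovineHD0300030334", "CTPS", "within"),
        (3, 105103446, 105151204, 1.57, "BovineHD0300030104", "/", "/"),
        (2, 98767231, 98852487, 1.50, "BovineHD0200028425", "CPS1", "within"),
        (12, 37317791, 37375872, 1.36, "BovineHD1200010822", "ATP12A", "395299"),
        (23, 13141062, 13228547, 1.33, "BovineHD2300003307", "KCNK17", "19569"),
        (26, 28767232, 28870785, 1.33, "BovineHD2600007699", "SORCS1", "377841"),
        (20, 23511931, 23646033, 1.11, "BovineHD2000007095", "SLC38A9", "within"),
        (12, 37380083, 37454520, 1.08, "BovineHD1200010844", "/", "/"),
    ],
    columns=_WINDOW_COLUMNS,
)

#: >1% windows for birth-to-yearling average daily gain (15 regions).
BYADG_WINDOWS = pd.DataFrame(
    [
        (3, 106574782, 106644015, 20.15, "BTB-00148396", "RLF", "within"),
        (21, 5941998, 5968820, 10.77, "BovineHD2100001150", "ALDH1A3", "108659"),
        (5, 77160030, 77212501, 6.22, "BovineHD0500021921", "/", "/"),
        (28, 41315052, 41343055, 4.52, "BovineHD2800011614", "WAPAL", "178111"),
        (5, 77289332, 77341198, 2.90, "BovineHD0500021954", "/", "/"),
        (3, 103471058, 103518431, 2.79, "BovineHD0300029636", "FAM183A", "27683"),
        (21, 6031496, 6114704, 2.66, "BovineHD2100001184", "/", "/"),
        (11, 47195270, 47279484, 1.75, "BovineHD1100013811", "RPIA", "24890"),
        (22, 30689705, 30734004, 1.69, "BovineHD2200008831", "FOXP1", "within"),
        (3, 105080919, 105138584, 1.58, "BovineHD0300030098", "/", "/"),
        (19, 24496287, 24525423, 1.56, "BovineHD1900007093", "OR1G1", "9771"),
        (24, 36117632, 36240233, 1.50, "BovineHD2400009926", "ADCYAP1", "within"),
        (3, 79457216, 79552102, 1.31, "BovineHD0300022907", "PDE4B", "within"),
        (20, 23511931, 23646033, 1.26, "BovineHD2000007095", "SLC38A9", "within"),
        (20, 63943581, 63965954, 1.13, "BovineHD2000018191", "SEMA5A", "204352"),
    ],
    columns=_WINDOW_COLUMNS,
)

#: >1% windows for 18-month weight (21 regions).
MW18_WINDOWS = pd.DataFrame(
    [
        (1, 64788160, 64867718, 3.44, "BTB-00033090", "ARHGAP31", "within"),
        (20, 55978366, 56002160, 2.74, "BovineHD2000015364", "/", "/"),
        (22, 32826296, 32856787, 2.68, "BovineHD2200009375", "FAM19A4", "within"),
        (4, 18525619, 18550135, 2.62, "BovineHD0400005535", "C14H8orf59", "424568"),
        (26, 2272143, 2343667, 2.21, "BovineHD2600000342", "/", "/"),
        (1, 156048715, 156119788, 2.13, "BovineHD0100045578", "TBC1D5", "within"),
        (9, 86926509, 86984196, 2.06, "BovineHD0900024383", "SASH1", "within"),
        (10, 51554432, 51726000, 1.87, "BovineHD1000015443", "FAM63B", "within"),
        (10, 48374404, 48406759, 1.82, "BovineHD1000014557", "VPS13C", "105944"),
        (25, 25386519, 25442136, 1.77, "BovineHD2500007181", "KIAA0556", "29783"),
        (9, 93609823, 93684438, 1.72, "BovineHD0900026491", "/", "/"),
        (23, 19254288, 19290469, 1.64, "BovineHD2300004888", "CLIC5", "within"),
        (14, 49154187, 49217544, 1.54, "BovineHD1400013993", "MED30", "195164"),
        (14, 47765008, 47835714, 1.40, "BovineHD1400013511", "SAMD12", "14727"),
        (5, 18940413, 19018750, 1.39, "BovineHD0500005477", "DUSP6", "336392"),
        (9, 71346676, 71377254, 1.19, "BovineHD0900019755", "MOXD1", "4746"),
        (25, 30583072, 30676658, 1.16, "BovineHD2500008480", "/", "/"),
        (3, 60766989, 60828010, 1.15, "BovineHD0300018250", "TTLL7", "317902"),
        (1, 49845978, 49930370, 1.14, "BTB-01076879", "ALCAM", "486294"),
        (21, 38919896, 39060313, 1.13, "BTB-00818234", "/", "/"),
        (9, 88466483, 88498915, 1.01, "BovineHD0900024910", "PPP1R14C", "within"),
    ],
    columns=_WINDOW_COLUMNS,
)

WINDOW_TABLES = {
    "BW": BW_WINDOWS,
    "YW": YW_WINDOWS,
    "BYADG": BYADG_WINDOWS,
    "MW18": MW18_WINDOWS,
}
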