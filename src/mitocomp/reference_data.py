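"""Published per-species summary values for the study taxa.

Comparative inputs for 14 hymenopteran mitogenomes and the neuropteran
outgroup, keyed by GenBank accession: region lengths with A+T content,
and protein-coding-gene (PCG) sense-strand base percentages with the
AT-/GC-skews as printed in the comparative tables.  These are inputs to
consistency checks (recomputing skews from the percentages, cross-table
A+T agreement), not outputs of this package.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["ACCESSIONS", "REGION_TABLE", "PCG_SKEW_TABLE",
           "region_table", "pcg_skew_table"]

ACCESSIONS = (
    "KT921411", "KR703582", "KJ713152", "JX566509", "KR703581", "AY787816",
    "FJ478173", "KM377623", "KM377624", "FJ478174", "KP163643", "KJ735511",
    "EU871947", "DQ302100", "FJ171324",
)

# species, accession, whole length, whole AT%, PCG length, PCG AT%,
# rrnL length, rrnL AT%, rrnS length, rrnS AT%
REGION_TABLE = (
    ("Allantus luctifer",        "KJ713152", 15418, 81.13, 11212, 79.90, 1340, 84.10,  807, 83.52),
    ("Asiemphytus rufocephalus", "KR703582", 14864, 81.40, 11257, 80.30, 1339, 85.06,  803, 83.44),
    ("Monocellicampa pruni",     "JX566509", 15169, 77.22, 11176, 75.20, 1356, 82.67,  797, 81.18),
    ("Tenthredo tienmushana",    "KR703581", 14942, 80.14, 11278, 79.00, 1355, 83.17,  797, 83.69),
    ("Trichiosoma anthracinum",  "KT921411", 15392, 80.76, 11185, 79.30, 1351, 84.46,  800, 83.50),
    ("Perga condei",             "AY787816", 13413, 77.92, 10148, 76.50, 1357, 83.05,  728, 80.91),
    ("Cephus cinctus",           "FJ478173", 19337, 81.96, 11291, 79.10, 1386, 84.63, 1011, 80.51),
    ("Cephus pygmeus",           "KM377623", 16145, 79.82, 11293, 77.50, 1367, 84.56, 1008, 84.42),
    ("Cephus sareptanus",        "KM377624", 15212, 79.20, 11285, 77.30, 1379, 83.76, 1014, 85.21),
    ("Orussus occidentalis",     "FJ478174", 15947, 76.21, 11174, 74.20, 1336, 80.09,  787, 81.07),
    ("Apis mellifera",           "KP163643", 15427, 84.18, 11029, 83.20, 1366, 84.55,  781, 81.31),
    ("Vespa bicolor",            "KJ735511", 16937, 81.72, 11230, 79.30, 1451, 84.77,  838, 85.20),
    ("Diadegma semiclausum",     "EU871947", 18728, 87.41, 11122, 83.70, 1392, 88.00,  768, 88.54),
    ("Vanhornia eucnemidarum",   "DQ302100", 16567, 80.14, 11068, 78.20, 1327, 82.82,  395, 80.76),
)

# species, T%, C%, A%, G% of the PCG region, printed AT-skew, GC-skew
PCG_SKEW_TABLE = (
    ("Allantus luctifer",        45.0, 10.2, 34.9, 10.0, -0.126, -0.010),
    ("Asiemphytus rufocephalus", 45.1,  9.7, 35.2, 10.0, -0.123,  0.015),
    ("Monocellicampa pruni",     42.2, 12.9, 33.0, 11.9, -0.122, -0.040),
    ("Tenthredo tienmushana",    44.6, 10.6, 34.4, 10.4, -0.129, -0.010),
    ("Trichiosoma anthracinum",  44.1, 10.4, 35.2, 10.3, -0.112, -0.005),
    ("Perga condei",             43.2, 11.6, 33.3, 12.0, -0.129,  0.017),
    ("Cephus cinctus",           44.0, 10.7, 35.1, 10.2, -0.113, -0.024),
    ("Cephus pygmeus",           43.2, 11.1, 34.3, 11.3, -0.115,  0.009),
    ("Cephus sareptanus",        42.8, 11.6, 34.5, 11.1, -0.107, -0.022),
    ("Orussus occidentalis",     42.0, 13.7, 32.2, 12.1, -0.132, -0.062),
    ("Apis mellifera",           46.1,  8.6, 37.1,  8.3, -0.108, -0.018),
    ("Vespa bicolor",            44.3, 11.1, 35.0,  9.6, -0.117, -0.072),
    ("Diadegma semiclausum",     47.0,  8.2, 36.7,  8.1, -0.123, -0.006),
    ("Vanhornia eucnemidarum",   42.7, 11.7, 35.5, 10.0, -0.092, -0.078),
)


def region_table() -> pd.DataFrame:
    return pd.DataFrame(REGION_TABLE, columns=[
        "species", "accession", "whole_len", "whole_at", "pcg_len", "pcg_at",
        "rrnl_len", "rrnl_at", "rrns_len", "rrns_at"])


def pcg_skew_table() -> pd.DataFrame:
    return pd.DataFrame(PCG_SKEW_TABLE, columns=[
        "species", "t_pct", "c_pct", "a_pct", "g_pct",
        "at_skew_printed", "gc_skew_printed"])
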