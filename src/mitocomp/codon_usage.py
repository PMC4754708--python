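"""Codon counting, RSCU, start/stop classification and amino-acid usage.

All translation uses the invertebrate mitochondrial genetic code
(translation table 5: ATA=Met, AGA/AGG=Ser, TGA=Trp; stops TAA/TAG).
RSCU (relative synonymous codon usage) for a codon c in a synonymous
family of size k with counts n is RSCU(c) = k*n_c / sum_family(n), so a
uniformly used family has RSCU = 1 everywhere and the family sum is k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome_io import Mitogenome

__all__ = [
    "GENETIC_CODE", "STOP_CODONS", "SENSE_CODONS", "SYNONYMOUS_FAMILIES",
    "CodonCounts", "RSCUTable", "StartStopReport",
    "count_codons", "rscu", "classify_terminal_codons", "amino_acid_usage",
    "translate_codon",
]

_BASES = "TCAG"
_AA_ORDER = "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSSSVVVVAAAADDEEGGGG"
# table-5 overrides relative to the standard code
_TABLE5_OVERRIDES = {"ATA": "M", "AGA": "S", "AGG": "S", "TGA": "W"}

GENETIC_CODE: dict[str, str] = {}
for _i, (_b1, _b2, _b3) in enumerate(
        (a, b, c) for a in _BASES for b in _BASES for c in _BASES):
    GENETIC_CODE[_b1 + _b2 + _b3] = _AA_ORDER[_i]
GENETIC_CODE.update(_TABLE5_OVERRIDES)

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))

SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _aa in sorted({aa for aa in GENETIC_CODE.values() if aa != "*"}):
    SYNONYMOUS_FAMILIES[_aa] = tuple(
        c for c in SENSE_CODONS if GENETIC_CODE[c] == _aa)


def translate_codon(codon: str) -> str:
    """Amino acid (1-letter; '*' stop) of a codon under table 5."""
    return GENETIC_CODE[codon.upper().replace("U", "T")]


@dataclass
class CodonCounts:
    """Sense-codon counts with stop codons tallied separately."""

    counts: dict[str, int]
    stop_counts: dict[str, int] = field(default_factory=dict)
    n_ambiguous: int = 0

    @property
    def n_codons_total(self) -> int:
        return sum(self.counts.values())


@dataclass
class RSCUTable:
    """RSCU per sense codon; families with zero usage are undefined (None)."""

    rscu: dict[str, float | None]
    missing: list[str]


@dataclass
class StartStopReport:
    """Per-PCG start/stop codon classification.

    ``rows`` columns: gene, start_codon, start_class (ATN / abnormal /
    other), stop (TAA / TAG / TA / T / nonstandard).
    """

    rows: pd.DataFrame


def count_codons(cds_list: list[str], drop_trailing_partial: bool = True) -> CodonCounts:
    """Count in-frame codons over a list of coding sequences.

    Codons are read in frame 0.  A trailing 1-2 nt remainder (an
    incomplete stop completed by polyadenylation in vivo) is dropped when
    ``drop_trailing_partial``.  Complete stop codons go to the separate
    stop tally; codons containing ambiguity codes or gaps are skipped and
    counted as ambiguous.
    """
    counts: dict[str, int] = {}
    stops: dict[str, int] = {}
    n_ambiguous = 0
    for cds in cds_list:
        cds = cds.upper().replace("U", "T")
        if len(cds) < 3:
            raise ValueError("CDS shorter than one codon")
        n_full = len(cds) // 3
        if len(cds) % 3 and not drop_trailing_partial:
            raise ValueError(f"CDS length {len(cds)} not a multiple of 3")
        for k in range(n_full):
            codon = cds[3 * k: 3 * k + 3]
            if any(b not in "ACGT" for b in codon):
                n_ambiguous += 1
            elif codon in STOP_CODONS:
                stops[codon] = stops.get(codon, 0) + 1
            else:
                counts[codon] = counts.get(codon, 0) + 1
    return CodonCounts(counts=counts, stop_counts=stops, n_ambiguous=n_ambiguous)


def rscu(counts: CodonCounts) -> RSCUTable:
    """Relative synonymous codon usage of a codon-count table."""
    table: dict[str, float | None] = {}
    missing: list[str] = []
    for family in SYNONYMOUS_FAMILIES.values():
        total = sum(counts.counts.get(c, 0) for c in family)
        k = len(family)
        for c in family:
            n_c = counts.counts.get(c, 0)
            table[c] = None if total == 0 else k * n_c / total
            if n_c == 0:
                missing.append(c)
    return RSCUTable(rscu=table, missing=sorted(missing))


def amino_acid_usage(counts: CodonCounts) -> pd.DataFrame:
    """Amino-acid counts and frequencies, ranked by usage (table 5)."""
    aa_counts: dict[str, int] = {}
    for codon, n in counts.counts.items():
        aa = GENETIC_CODE[codon]
        aa_counts[aa] = aa_counts.get(aa, 0) + n
    total = sum(aa_counts.values())
    rows = [{"amino_acid": aa, "count": n,
             "frequency": n / total if total else 0.0}
            for aa, n in sorted(aa_counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    return pd.DataFrame(rows, columns=["amino_acid", "count", "frequency"])


_ABNORMAL_STARTS = frozenset({"GTG", "TTG", "AAA"})


def _three_prime_gap(genome: Mitogenome, feat) -> int | None:
    """Offset from a PCG's 3' end (gene orientation) to the next feature.

    <=0 means the downstream feature abuts or overlaps the CDS tail, the
    geometry required for an incomplete stop completed by polyadenylation.
    """
    feats = sorted(genome.features, key=lambda x: (x.start, -x.length))
    if len(feats) < 2:
        return None
    pos = next(i for i, x in enumerate(feats) if x is feat)
    f = feat
    n = len(feats)
    if f.strand == "J":
        nxt = feats[(pos + 1) % n]
        gap = nxt.start - f.end
        if pos == n - 1 and genome.topology == "circular":
            gap = nxt.start + genome.length - f.end
    else:
        prv = feats[(pos - 1) % n]
        gap = f.start - prv.end
        if pos == 0 and genome.topology == "circular":
            gap = f.start + genome.length - prv.end
    return gap


def classify_terminal_codons(genome: Mitogenome) -> StartStopReport:
    """Classify start and stop codons of every annotated PCG.

    Starts: ATN, abnormal (GTG/TTG/AAA), or other.  Stops: complete
    TAA/TAG when the CDS length is a codon multiple and ends in a stop;
    incomplete T/TA when the length remainder matches and the next
    feature in gene orientation abuts or overlaps; anything else is
    flagged nonstandard.
    """
    rows = []
    for feat in genome.features:
        if feat.feature_class != "PCG":
            continue
        cds = feat.extract(genome.sequence)
        start = cds[:3]
        if start.startswith("AT"):
            start_class = "ATN"
        elif start in _ABNORMAL_STARTS:
            start_class = "abnormal"
        else:
            start_class = "other"
        rem = len(cds) % 3
        stop = "nonstandard"
        if rem == 0 and cds[-3:] in STOP_CODONS:
            stop = cds[-3:]
        elif rem in (1, 2):
            tail = cds[-rem:]
            expected = "T" if rem == 1 else "TA"
            gap = _three_prime_gap(genome, feat)
            if tail == expected and gap is not None and gap <= 0:
                stop = tail
        rows.append({"gene": feat.name, "start_codon": start,
                     "start_class": start_class, "stop": stop})
    return StartStopReport(rows=pd.DataFrame(
        rows, columns=["gene", "start_codon", "start_class", "stop"]))
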