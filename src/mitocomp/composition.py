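"""Nucleotide composition, A+T content, and AT/GC strand skews.

Strand compositional asymmetry is summarised by AT-skew = (A − T)/(A + T)
and GC-skew = (G − C)/(G + C), computed on percentages (equivalently on
counts).  Protein-coding-gene statistics are computed on each gene's
sense strand, concatenated, which reproduces the characteristic excess
of T and C reported for sawfly mitogenomes; a flag switches to the
deposited J-strand instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .genome_io import Mitogenome, MitocompError

__all__ = ["CompositionStats", "base_composition", "skew",
           "region_composition", "scatter3d_table", "AbsentRegionError"]

_AMBIGUOUS = set("RYSWKMBDHVN")


class AbsentRegionError(MitocompError):
    """Requested region is not annotated in the genome."""


@dataclass
class CompositionStats:
    """Base counts and derived skews for one genome region.

    Percentages are computed on the unambiguous (ACGT) total; ambiguity
    codes are tallied separately.  A skew whose denominator is zero is
    ``None`` (undefined), never 0.
    """

    region_label: str
    length: int
    count_a: int
    count_c: int
    count_g: int
    count_t: int
    n_ambiguous: int

    @property
    def _total(self) -> int:
        return self.count_a + self.count_c + self.count_g + self.count_t

    def pct(self, base: str) -> float:
        count = getattr(self, f"count_{base.lower()}")
        return 100.0 * count / self._total

    @property
    def at_content(self) -> float:
        return self.pct("A") + self.pct("T")

    @property
    def at_skew(self) -> float | None:
        return skew(self.pct("A"), self.pct("T"))

    @property
    def gc_skew(self) -> float | None:
        return skew(self.pct("G"), self.pct("C"))


def base_composition(seq: str, region_label: str = "") -> CompositionStats:
    """Count bases of a DNA string and derive composition statistics."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    a, c, g, t = seq.count("A"), seq.count("C"), seq.count("G"), seq.count("T")
    ambiguous = sum(1 for ch in seq if ch in _AMBIGUOUS)
    if a + c + g + t == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return CompositionStats(region_label=region_label, length=len(seq),
                            count_a=a, count_c=c, count_g=g, count_t=t,
                            n_ambiguous=ambiguous)


def skew(x_pct: float, y_pct: float) -> float | None:
    """(x − y)/(x + y); ``None`` when x + y = 0.

    AT-skew uses x = A%, y = T%; GC-skew uses x = G%, y = C%.
    """
    total = x_pct + y_pct
    if total == 0:
        return None
    return (x_pct - y_pct) / total


_REGIONS = ("whole", "PCGs", "rrnL", "rrnS", "tRNAs",
            "codon_pos1", "codon_pos2", "codon_pos3")


def region_composition(genome: Mitogenome, region: str) -> CompositionStats:
    """Composition of one annotated region of a mitogenome.

    ``PCGs`` and ``tRNAs`` concatenate each gene's coding-orientation
    sequence; ``codon_pos1/2/3`` pick every third base of the PCG
    concatenation; ``whole`` is the deposited sequence as-is.
    """
    if region not in _REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {_REGIONS}")
    if region == "whole":
        return base_composition(genome.sequence, "whole")
    if region in ("rrnL", "rrnS"):
        feat = genome.get(region)
        if feat is None:
            raise AbsentRegionError(f"{genome.accession}: no {region} annotated")
        return base_composition(feat.extract(genome.sequence), region)
    if region == "tRNAs":
        feats = genome.features_of_class("tRNA")
        if not feats:
            raise AbsentRegionError(f"{genome.accession}: no tRNAs annotated")
        return base_composition(
            "".join(f.extract(genome.sequence) for f in feats), "tRNAs")
    pcgs = genome.features_of_class("PCG")
    if not pcgs:
        raise AbsentRegionError(f"{genome.accession}: no PCGs annotated")
    concat = "".join(f.extract(genome.sequence) for f in pcgs)
    if region == "PCGs":
        return base_composition(concat, "PCGs")
    pos = int(region[-1]) - 1
    return base_composition(concat[pos::3], region)


def scatter3d_table(genomes: list[Mitogenome]) -> pd.DataFrame:
    """Per-species (A+T%, AT-skew, GC-skew) of the PCG region.

    The rows are the data behind a 3-D scatter comparison of strand
    asymmetry between lineages.  Genomes with no annotated PCGs are
    flagged and carry NaN values rather than being dropped.
    """
    rows = []
    for g in genomes:
        try:
            stats = region_composition(g, "PCGs")
            rows.append({"accession": g.accession, "organism": g.organism,
                         "at_content": stats.at_content,
                         "at_skew": stats.at_skew, "gc_skew": stats.gc_skew,
                         "flag": ""})
        except AbsentRegionError:
            rows.append({"accession": g.accession, "organism": g.organism,
                         "at_content": math.nan, "at_skew": math.nan,
                         "gc_skew": math.nan, "flag": "no_pcgs"})
    return pd.DataFrame(rows)


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding used for report tables."""
    factor = 10 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)
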