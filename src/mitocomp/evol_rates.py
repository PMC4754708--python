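"""Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction.

The NG86 counting method under the invertebrate mitochondrial code
(table 5):

* each codon contributes fractional synonymous sites
  s = sum over its 3 positions of (#synonymous single-base changes)/3,
  with changes to stop codons counted as nonsynonymous alternatives;
  S is the average of the two sequences' totals and N = 3*codons - S;
* differences within a codon pair are averaged with equal weight over
  all substitution pathways (orderings of the differing positions);
  pathways passing through a stop codon are excluded, and if every
  pathway is blocked the codon's differences are split in proportion to
  its site counts;
* the proportions pS = Sd/S and pN = Nd/N are corrected for multiple
  hits with the Jukes-Cantor map d = -(3/4) ln(1 - (4/3) p).

The Ka/Ks ratio is undefined (None, flagged) when Ks = 0 or when a log
argument is non-positive (saturation); it is never reported as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import pandas as pd

from .codon_usage import GENETIC_CODE, STOP_CODONS
from .genome_io import Mitogenome, extract_gene_sequence, PCG_NAMES

__all__ = ["KaKsResult", "ng86", "synonymous_site_fraction",
           "pathway_differences", "jukes_cantor", "rates_vs_reference"]

_BASES = "ACGT"


@lru_cache(maxsize=None)
def synonymous_site_fraction(codon: str) -> float:
    """Fractional synonymous sites of one sense codon (0..3)."""
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = sum(
            1 for b in _BASES
            if b != codon[pos]
            and GENETIC_CODE[codon[:pos] + b + codon[pos + 1:]] == aa
        )
        s += syn / 3.0
    return s


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) contribution of one codon pair under pathway averaging."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return (0.0, 0.0)
    valid = []
    for path in permutations(diff_pos):
        cur = codon_a
        steps = []
        blocked = False
        for pos in path:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            steps.append(GENETIC_CODE[nxt] == GENETIC_CODE[cur])
            cur = nxt
        if not blocked:
            valid.append(steps)
    if not valid:
        # every pathway crosses a stop: split differences by site counts
        s_frac = (synonymous_site_fraction(codon_a)
                  + synonymous_site_fraction(codon_b)) / 2.0 / 3.0
        d = float(len(diff_pos))
        return (d * s_frac, d * (1.0 - s_frac))
    sd = sum(sum(steps) for steps in valid) / len(valid)
    nd = len(diff_pos) - sd
    return (sd, nd)


def jukes_cantor(p: float) -> float | None:
    """JC-corrected distance; None when saturated (1 - 4p/3 <= 0)."""
    arg = 1.0 - (4.0 / 3.0) * p
    if arg <= 0.0:
        return None
    return -0.75 * math.log(arg) + 0.0   # +0.0 normalises -0.0


@dataclass
class KaKsResult:
    """NG86 site/difference counts and JC-corrected rates for one pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    n_codons_compared: int

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S > 0 else 0.0

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N > 0 else 0.0

    @property
    def Ks(self) -> float | None:
        return jukes_cantor(self.pS)

    @property
    def Ka(self) -> float | None:
        return jukes_cantor(self.pN)

    @property
    def ratio(self) -> float | None:
        """Ka/Ks; None (undefined) when Ks=0 or either rate is saturated."""
        ka, ks = self.Ka, self.Ks
        if ka is None or ks is None or ks == 0.0:
            return None
        return ka / ks

    @property
    def saturated(self) -> bool:
        return self.Ka is None or self.Ks is None


def ng86(cds_a: str, cds_b: str) -> KaKsResult:
    """NG86 comparison of two equal-length in-frame coding sequences.

    Codons containing gaps, ambiguity codes, or a stop in either sequence
    are excluded pairwise.
    """
    cds_a = cds_a.upper().replace("U", "T")
    cds_b = cds_b.upper().replace("U", "T")
    if len(cds_a) != len(cds_b):
        raise ValueError(f"length mismatch: {len(cds_a)} vs {len(cds_b)}")
    if len(cds_a) % 3:
        raise ValueError(f"length {len(cds_a)} is not a multiple of 3")
    S = N = Sd = Nd = 0.0
    n_used = 0
    for k in range(len(cds_a) // 3):
        ca = cds_a[3 * k: 3 * k + 3]
        cb = cds_b[3 * k: 3 * k + 3]
        if any(b not in _BASES for b in ca + cb):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        n_used += 1
        s_pair = (synonymous_site_fraction(ca) + synonymous_site_fraction(cb)) / 2.0
        S += s_pair
        N += 3.0 - s_pair
        sd, nd = pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    return KaKsResult(S=S, N=N, Sd=Sd, Nd=Nd, n_codons_compared=n_used)


def _pairwise_frame(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Trim two sequences to a shared in-frame length (floor to codons)."""
    n = min(len(seq_a), len(seq_b))
    n -= n % 3
    return seq_a[:n], seq_b[:n]


def rates_vs_reference(
    genomes: list[Mitogenome],
    reference: Mitogenome,
    genes: tuple[str, ...] = PCG_NAMES,
    alignments: dict[str, dict[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-genome Ka, Ks and Ka/Ks against a designated reference taxon.

    ``alignments`` may supply pre-aligned CDS per gene (gene -> accession
    -> aligned sequence, reference included); otherwise annotated gene
    sequences are compared directly, trimmed to a common codon length
    (appropriate for unaligned input only when indels are absent).
    Returns one row per (genome, gene) plus a ``concatenated`` row per
    genome; undefined ratios stay as missing values, never 0.
    """
    rows = []
    for g in genomes:
        concat_a: list[str] = []
        concat_b: list[str] = []
        for gene in genes:
            if alignments and gene in alignments:
                aln = alignments[gene]
                seq_g = aln.get(g.accession)
                seq_r = aln.get(reference.accession)
            else:
                seq_g = extract_gene_sequence(g, gene)
                seq_r = extract_gene_sequence(reference, gene)
            if not seq_g or not seq_r:
                rows.append({"accession": g.accession, "gene": gene,
                             "Ka": None, "Ks": None, "ratio": None,
                             "flag": "absent"})
                continue
            a, b = _pairwise_frame(seq_g, seq_r)
            res = ng86(a, b)
            concat_a.append(a)
            concat_b.append(b)
            rows.append({"accession": g.accession, "gene": gene,
                         "Ka": res.Ka, "Ks": res.Ks, "ratio": res.ratio,
                         "flag": "saturated" if res.saturated else ""})
        if concat_a:
            res = ng86("".join(concat_a), "".join(concat_b))
            rows.append({"accession": g.accession, "gene": "concatenated",
                         "Ka": res.Ka, "Ks": res.Ks, "ratio": res.ratio,
                         "flag": "saturated" if res.saturated else ""})
    return pd.DataFrame(rows, columns=["accession", "gene", "Ka", "Ks",
                                       "ratio", "flag"])
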