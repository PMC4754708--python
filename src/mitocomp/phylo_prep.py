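"""Partitioned supermatrix construction and saturation screening.

Pre-aligned per-gene matrices are split by codon position, translated,
concatenated into the four standard matrix variants

* ``P123``  — all three codon positions of the protein-coding genes,
* ``P123R`` — P123 plus the rRNA and tRNA partitions,
* ``P12T``  — P123R minus a named exclusion list (typically the
  saturated third-position and rRNA partitions),
* ``AA``    — the translated protein-coding genes,

and exported with charset definitions (NEXUS or RAxML style).  Sequence
alignment itself and substitution-model search are external; this module
consumes aligned FASTA and a partition-scheme configuration.

Saturation is screened per partition by regressing the observed
p-distance of every taxon pair on its K80-corrected distance: a slope
well below 1 (default threshold 0.6), or corrected distances undefined
for >10% of pairs, flags substitution saturation.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .codon_usage import GENETIC_CODE
from .genome_io import MitocompError

__all__ = ["AlignedPartition", "Supermatrix", "SaturationResult",
           "read_aligned_fasta", "split_codon_positions", "translate_alignment",
           "build_matrix", "export_matrix", "import_nexus", "saturation_scan"]


class MatrixError(MitocompError):
    """Invalid partition/matrix input."""


@dataclass
class AlignedPartition:
    """One aligned block: taxon -> row, all rows equal length."""

    name: str
    rows: dict[str, str]
    kind: str                      # codon_pos1/2/3, rRNA, tRNA, AA, nt
    source_gene: str = ""

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.rows.values()}
        if len(lengths) > 1:
            raise MatrixError(f"partition {self.name}: ragged rows {lengths}")

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


@dataclass
class Supermatrix:
    """Concatenated partitions with charset column ranges (half-open)."""

    variant: str
    rows: dict[str, str]
    charsets: list[tuple[str, tuple[int, int]]]

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


@dataclass
class SaturationResult:
    """Pairwise distance table and the p-on-corrected regression."""

    partition: str
    pairs: pd.DataFrame            # taxon_a, taxon_b, p, s, v, corrected
    slope: float | None
    r_squared: float | None
    undefined_fraction: float
    saturated_flag: bool


def read_aligned_fasta(path, name: str = "", kind: str = "nt") -> AlignedPartition:
    """Load one aligned FASTA file as a partition."""
    rows: dict[str, str] = {}
    current = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if current is not None:
                    rows[current] = "".join(chunks)
                current = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if current is not None:
        rows[current] = "".join(chunks)
    return AlignedPartition(name=name or str(path), rows=rows, kind=kind)


def split_codon_positions(part: AlignedPartition) -> tuple[AlignedPartition,
                                                           AlignedPartition,
                                                           AlignedPartition]:
    """Split a frame-0 codon alignment into the three position partitions."""
    if part.n_sites % 3:
        raise MatrixError(
            f"{part.name}: alignment length {part.n_sites} not a codon multiple")
    out = []
    for pos in range(3):
        rows = {t: s[pos::3] for t, s in part.rows.items()}
        out.append(AlignedPartition(name=f"{part.name}_p{pos + 1}", rows=rows,
                                    kind=f"codon_pos{pos + 1}",
                                    source_gene=part.source_gene or part.name))
    return tuple(out)


def translate_alignment(part: AlignedPartition) -> AlignedPartition:
    """Translate a frame-0 nt alignment under table 5.

    Codons containing a gap translate to '-'; ambiguity to 'X'; internal
    stops are kept as '*' (flaggable downstream).
    """
    if part.n_sites % 3:
        raise MatrixError(
            f"{part.name}: alignment length {part.n_sites} not a codon multiple")
    rows = {}
    for taxon, seq in part.rows.items():
        aas = []
        for k in range(len(seq) // 3):
            codon = seq[3 * k: 3 * k + 3].upper().replace("U", "T")
            if "-" in codon:
                aas.append("-")
            elif any(b not in "ACGT" for b in codon):
                aas.append("X")
            else:
                aas.append(GENETIC_CODE[codon])
        rows[taxon] = "".join(aas)
    return AlignedPartition(name=f"{part.name}_aa", rows=rows, kind="AA",
                            source_gene=part.source_gene or part.name)


_VARIANT_KINDS = {
    "P123": ("codon_pos1", "codon_pos2", "codon_pos3"),
    "P123R": ("codon_pos1", "codon_pos2", "codon_pos3", "rRNA", "tRNA"),
    "P12T": ("codon_pos1", "codon_pos2", "codon_pos3", "rRNA", "tRNA"),
    "AA": ("AA",),
}


def build_matrix(partitions: list[AlignedPartition], variant: str,
                 exclusions: tuple[str, ...] = ()) -> Supermatrix:
    """Concatenate partitions into one of the four matrix variants.

    Taxa missing from a partition are gap-filled; for ``P12T`` the
    ``exclusions`` name the partitions to drop from P123R (typically the
    ones carrying all third codon positions and the rRNAs).
    """
    if variant not in _VARIANT_KINDS:
        raise MatrixError(f"unknown matrix variant {variant!r}")
    kinds = _VARIANT_KINDS[variant]
    chosen = [p for p in partitions if p.kind in kinds]
    if variant == "P12T":
        chosen = [p for p in chosen if p.name not in set(exclusions)]
    if not chosen:
        raise MatrixError(f"no partitions left for variant {variant}")
    taxa = sorted({t for p in chosen for t in p.taxa})
    gap = "-"
    rows = {t: [] for t in taxa}
    charsets: list[tuple[str, tuple[int, int]]] = []
    cursor = 0
    for p in chosen:
        for t in taxa:
            rows[t].append(p.rows.get(t, gap * p.n_sites))
        charsets.append((p.name, (cursor, cursor + p.n_sites)))
        cursor += p.n_sites
    return Supermatrix(variant=variant,
                       rows={t: "".join(v) for t, v in rows.items()},
                       charsets=charsets)


def _sanitize_taxa(taxa: list[str]) -> dict[str, str]:
    mapping = {}
    seen = set()
    for t in taxa:
        clean = re.sub(r"[^A-Za-z0-9_.]", "_", t)
        base = clean
        k = 1
        while clean in seen:
            k += 1
            clean = f"{base}_{k}"
        seen.add(clean)
        mapping[t] = clean
    return mapping


def export_matrix(matrix: Supermatrix, path, fmt: str = "NEXUS",
                  partition_style: str = "NEXUS charset") -> dict[str, str]:
    """Write a supermatrix; returns the taxon-name sanitisation map.

    ``fmt``: NEXUS (data + sets block), PHYLIP-relaxed, or FASTA.
    ``partition_style`` "RAxML partition file" additionally writes
    ``<path>.partitions`` with ``DNA, name = start-end\\3`` lines for
    codon partitions.
    """
    mapping = _sanitize_taxa(matrix.taxa)
    datatype = "protein" if matrix.variant == "AA" else "dna"
    if fmt == "NEXUS":
        with open(path, "w") as fh:
            fh.write("#NEXUS\n")
            fh.write("begin data;\n")
            fh.write(f"  dimensions ntax={len(matrix.taxa)} "
                     f"nchar={matrix.n_sites};\n")
            fh.write(f"  format datatype={datatype} missing=? gap=-;\n")
            fh.write("  matrix\n")
            for t in matrix.taxa:
                fh.write(f"  {mapping[t]}  {matrix.rows[t]}\n")
            fh.write("  ;\nend;\n")
            fh.write("begin sets;\n")
            for name, (a, b) in matrix.charsets:
                fh.write(f"  charset {name} = {a + 1}-{b};\n")
            fh.write("end;\n")
    elif fmt == "PHYLIP-relaxed":
        with open(path, "w") as fh:
            fh.write(f"{len(matrix.taxa)} {matrix.n_sites}\n")
            for t in matrix.taxa:
                fh.write(f"{mapping[t]}  {matrix.rows[t]}\n")
    elif fmt == "FASTA":
        with open(path, "w") as fh:
            for t in matrix.taxa:
                fh.write(f">{mapping[t]}\n{matrix.rows[t]}\n")
    else:
        raise MatrixError(f"unknown export format {fmt!r}")
    if partition_style == "RAxML partition file":
        model = "MTART" if matrix.variant == "AA" else "DNA"
        with open(f"{path}.partitions", "w") as fh:
            for name, (a, b) in matrix.charsets:
                m = re.search(r"codon_pos(\d)$|_p(\d)$", name)
                if m and matrix.variant != "AA":
                    fh.write(f"{model}, {name} = {a + 1}-{b}\\3\n")
                else:
                    fh.write(f"{model}, {name} = {a + 1}-{b}\n")
    return mapping


def import_nexus(path) -> Supermatrix:
    """Read back a NEXUS file written by :func:`export_matrix`."""
    rows: dict[str, str] = {}
    charsets: list[tuple[str, tuple[int, int]]] = []
    in_matrix = False
    datatype = "dna"
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.lower().startswith("format"):
                m = re.search(r"datatype=(\w+)", line, re.IGNORECASE)
                if m:
                    datatype = m.group(1).lower()
            if line.lower() == "matrix":
                in_matrix = True
                continue
            if in_matrix:
                if line == ";":
                    in_matrix = False
                    continue
                if line:
                    taxon, seq = line.split(None, 1)
                    rows[taxon] = rows.get(taxon, "") + seq.replace(" ", "")
            m = re.match(r"charset\s+(\S+)\s*=\s*(\d+)-(\d+);", line)
            if m:
                charsets.append((m.group(1),
                                 (int(m.group(2)) - 1, int(m.group(3)))))
    variant = "AA" if datatype == "protein" else "imported"
    return Supermatrix(variant=variant, rows=rows, charsets=charsets)


# ---------------------------------------------------------------------------
# saturation screening
# ---------------------------------------------------------------------------

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def _pair_distances(sa: str, sb: str) -> tuple[float, float, float, float | None] | None:
    """(p, s_prop, v_prop, K80 distance) with pairwise deletion."""
    n = s = v = 0
    for a, b in zip(sa, sb):
        if a not in "ACGT" or b not in "ACGT":
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            s += 1
        else:
            v += 1
    if n == 0:
        return None
    P, Q = s / n, v / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        d = None
    else:
        d = 0.5 * math.log(1.0 / w1) + 0.25 * math.log(1.0 / w2)
    return ((s + v) / n, P, Q, d)


def saturation_scan(part: AlignedPartition,
                    slope_threshold: float = 0.6) -> SaturationResult:
    """Screen one nt partition for substitution saturation.

    For every taxon pair the observed proportion of differences
    (p-distance), transition and transversion proportions, and the
    K80-corrected distance are computed with pairwise deletion of
    gaps/ambiguity.  A least-squares regression of p on the corrected
    distance summarises the plateauing: an unsaturated partition has
    slope near 1.  ``saturated_flag`` is raised when the slope falls
    below ``slope_threshold`` or the corrected distance is undefined
    (log argument <= 0) for more than 10% of pairs.
    """
    taxa = part.taxa
    if len(taxa) < 3:
        raise MatrixError("saturation scan needs at least 3 taxa")
    recs = []
    n_undef = 0
    n_pairs = 0
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            res = _pair_distances(part.rows[taxa[i]], part.rows[taxa[j]])
            if res is None:
                continue    # all-gap pair: skipped
            n_pairs += 1
            p, P, Q, d = res
            if d is None:
                n_undef += 1
            recs.append({"taxon_a": taxa[i], "taxon_b": taxa[j],
                         "p_distance": p, "s_proportion": P,
                         "v_proportion": Q, "corrected_distance": d})
    df = pd.DataFrame(recs)
    defined = df.dropna(subset=["corrected_distance"]) if len(df) else df
    slope = r2 = None
    if len(defined) >= 2 and defined["corrected_distance"].nunique() > 1:
        fit = stats.linregress(defined["corrected_distance"],
                               defined["p_distance"])
        slope, r2 = float(fit.slope), float(fit.rvalue ** 2)
    undef_frac = n_undef / n_pairs if n_pairs else 0.0
    flag = (slope is not None and slope < slope_threshold) or undef_frac > 0.10
    return SaturationResult(partition=part.name, pairs=df, slope=slope,
                            r_squared=r2, undefined_fraction=undef_frac,
                            saturated_flag=flag)
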