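"""Read, write and normalise annotated mitochondrial genomes.

Insect mitochondrial genomes carry 37 genes (13 protein-coding genes, 2
rRNAs, 22 tRNAs) plus an A+T-rich control region.  Deposited GenBank
records label these genes inconsistently ("COI", "COX1", "cytochrome c
oxidase subunit I" ...), so everything entering the pipeline is mapped to
one canonical vocabulary and to 0-based half-open coordinates.  Strands
are reported as J (majority/'+') and N (minority/'-'), the convention
used for mitogenomes.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PCG_NAMES",
    "TRNA_NAMES",
    "RRNA_NAMES",
    "ALL_GENE_NAMES",
    "GeneFeature",
    "Mitogenome",
    "MitocompError",
    "GenomeParseError",
    "GenomeContentError",
    "canonicalize_gene_name",
    "read_genbank",
    "write_genbank",
    "write_gene_fasta",
    "write_feature_table",
    "extract_gene_sequence",
    "reverse_complement",
]


class MitocompError(Exception):
    """Base class for pipeline errors."""


class GenomeParseError(MitocompError):
    """A record could not be parsed as an annotated mitogenome."""


class GenomeContentError(MitocompError):
    """A parsed record contains no recognisable mitochondrial genes."""


# ---------------------------------------------------------------------------
# canonical gene vocabulary
# ---------------------------------------------------------------------------

PCG_NAMES = (
    "nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3",
    "nad5", "nad4", "nad4l", "nad6", "cob", "nad1",
)
RRNA_NAMES = ("rrnL", "rrnS")
TRNA_NAMES = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)
CONTROL_NAME = "AT_rich"
ALL_GENE_NAMES = PCG_NAMES + RRNA_NAMES + TRNA_NAMES

_CLASS_OF = {n: "PCG" for n in PCG_NAMES}
_CLASS_OF.update({n: "rRNA" for n in RRNA_NAMES})
_CLASS_OF.update({n: "tRNA" for n in TRNA_NAMES})
_CLASS_OF[CONTROL_NAME] = "control"

_AA3_TO_TRNA = {
    "ala": "trnA", "cys": "trnC", "asp": "trnD", "glu": "trnE",
    "phe": "trnF", "gly": "trnG", "his": "trnH", "ile": "trnI",
    "lys": "trnK", "met": "trnM", "asn": "trnN", "pro": "trnP",
    "gln": "trnQ", "arg": "trnR", "thr": "trnT", "val": "trnV",
    "trp": "trnW", "tyr": "trnY",
}

# Leu/Ser paralogs resolved by anticodon.  trnL1 decodes CUN codons
# (anticodon UAG), trnL2 decodes UUR (UAA); trnS1 decodes AGN (GCU/UCU),
# trnS2 decodes UCN (UGA).
_LEU_SER_BY_ANTICODON = {
    ("leu", "UAG"): "trnL1",
    ("leu", "UAA"): "trnL2",
    ("ser", "GCU"): "trnS1",
    ("ser", "UCU"): "trnS1",
    ("ser", "UGA"): "trnS2",
}

_PCG_SYNONYMS = {
    "cox1": ("cox1", "coi", "co1", "coxi", "cytochrome c oxidase subunit i",
             "cytochrome c oxidase subunit 1", "cytochrome oxidase subunit i",
             "cytochrome oxidase subunit 1"),
    "cox2": ("cox2", "coii", "co2", "coxii", "cytochrome c oxidase subunit ii",
             "cytochrome c oxidase subunit 2", "cytochrome oxidase subunit ii",
             "cytochrome oxidase subunit 2"),
    "cox3": ("cox3", "coiii", "co3", "coxiii", "cytochrome c oxidase subunit iii",
             "cytochrome c oxidase subunit 3", "cytochrome oxidase subunit iii",
             "cytochrome oxidase subunit 3"),
    "cob": ("cob", "cytb", "cyt b", "cytochrome b", "cyb"),
    "atp6": ("atp6", "atpase6", "atpase 6", "atp synthase f0 subunit 6",
             "atp synthase subunit 6"),
    "atp8": ("atp8", "atpase8", "atpase 8", "atp synthase f0 subunit 8",
             "atp synthase subunit 8"),
    "nad1": ("nad1", "nd1", "nadh1", "nadh dehydrogenase subunit 1"),
    "nad2": ("nad2", "nd2", "nadh2", "nadh dehydrogenase subunit 2"),
    "nad3": ("nad3", "nd3", "nadh3", "nadh dehydrogenase subunit 3"),
    "nad4": ("nad4", "nd4", "nadh4", "nadh dehydrogenase subunit 4"),
    "nad4l": ("nad4l", "nd4l", "nadh4l", "nadh dehydrogenase subunit 4l"),
    "nad5": ("nad5", "nd5", "nadh5", "nadh dehydrogenase subunit 5"),
    "nad6": ("nad6", "nd6", "nadh6", "nadh dehydrogenase subunit 6"),
    "rrnL": ("rrnl", "16s", "16s rrna", "16s ribosomal rna", "l-rrna", "lrrna",
             "large subunit ribosomal rna", "rrn l"),
    "rrnS": ("rrns", "12s", "12s rrna", "12s ribosomal rna", "s-rrna", "srrna",
             "small subunit ribosomal rna", "rrn s"),
    "AT_rich": ("at_rich", "at rich region", "a+t-rich region", "a+t rich region",
                "control region", "d-loop", "putative control region"),
}
_SYNONYM_TO_CANONICAL = {
    syn: canon for canon, syns in _PCG_SYNONYMS.items() for syn in syns
}
# direct canonical tRNA labels ("trnA", "trnl1", ...)
for _t in TRNA_NAMES:
    _SYNONYM_TO_CANONICAL[_t.lower()] = _t

_TRNA_RE = re.compile(
    r"^(?:trna[-_ ]?|trn[-_ ]?)"
    r"(ala|arg|asn|asp|cys|gln|glu|gly|his|ile|leu|lys|met|phe|pro|ser|thr|trp|tyr|val"
    r"|[acdefghiklmnpqrstvwy])"
    r"\s*\(?([12])?\)?$",
    re.IGNORECASE,
)

_AA1_TO_AA3 = {
    "a": "ala", "c": "cys", "d": "asp", "e": "glu", "f": "phe", "g": "gly",
    "h": "his", "i": "ile", "k": "lys", "l": "leu", "m": "met", "n": "asn",
    "p": "pro", "q": "gln", "r": "arg", "s": "ser", "t": "thr", "v": "val",
    "w": "trp", "y": "tyr",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

IUPAC_LETTERS = frozenset("ACGTRYSWKMBDHVN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonicalize_gene_name(raw_label: str, anticodon: str | None = None) -> str | None:
    """Map a raw feature label to the canonical gene vocabulary.

    ``anticodon`` (any of DNA/RNA, any case) disambiguates the Leu and Ser
    tRNA paralogs.  Returns ``None`` for labels that cannot be mapped;
    returns the ambiguous placeholders ``"trnL?"`` / ``"trnS?"`` when a
    Leu/Ser tRNA carries no usable anticodon (the caller resolves these
    positionally).
    """
    if not raw_label:
        raise ValueError("empty gene label")
    label = raw_label.strip().lower().replace("’", "'")
    if label in _SYNONYM_TO_CANONICAL:
        return _SYNONYM_TO_CANONICAL[label]
    m = _TRNA_RE.match(label)
    if m is None:
        return None
    aa = m.group(1).lower()
    if len(aa) == 1:
        aa = _AA1_TO_AA3[aa]
    numeral = m.group(2)
    if aa in ("leu", "ser"):
        if anticodon:
            key = (aa, anticodon.upper().replace("T", "U"))
            if key in _LEU_SER_BY_ANTICODON:
                return _LEU_SER_BY_ANTICODON[key]
        if numeral:
            return ("trnL" if aa == "leu" else "trnS") + numeral
        return "trnL?" if aa == "leu" else "trnS?"
    return _AA3_TO_TRNA[aa]


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class GeneFeature:
    """One annotated gene on a mitogenome.

    ``intervals`` are 0-based half-open genomic slices stored in 5'→3'
    reading order on the J-strand; a feature spanning the origin of a
    circular molecule is represented by two intervals (tail, head).
    Strand is ``"J"`` (annotated '+') or ``"N"`` ('-').
    """

    name: str
    feature_class: str
    strand: str
    intervals: list[tuple[int, int]]
    anticodon: str | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def extract(self, sequence: str) -> str:
        """Coding-orientation (sense strand) sequence of this feature."""
        raw = "".join(sequence[s:e] for s, e in self.intervals)
        return reverse_complement(raw) if self.strand == "N" else raw


@dataclass
class Mitogenome:
    """An annotated mitochondrial genome (sequence + normalised features)."""

    accession: str
    organism: str
    sequence: str
    topology: str = "circular"  # or "linear-sequenced-region"
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def sequenced_complete(self) -> bool:
        """True when all 37 canonical genes are annotated."""
        present = {f.name for f in self.features}
        return all(n in present for n in ALL_GENE_NAMES)

    def get(self, name: str) -> GeneFeature | None:
        for f in self.features:
            if f.name == name:
                return f
        return None

    def features_of_class(self, feature_class: str) -> list[GeneFeature]:
        return [f for f in self.features if f.feature_class == feature_class]

    def validate(self) -> None:
        bad = set(self.sequence) - IUPAC_LETTERS
        if bad:
            raise GenomeContentError(f"non-IUPAC letters in sequence: {sorted(bad)}")
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.intervals:
                if not (0 <= s < e <= n):
                    raise GenomeContentError(
                        f"feature {f.name} interval [{s},{e}) outside [0,{n})")


def extract_gene_sequence(genome: Mitogenome, name: str) -> str | None:
    """Sense-strand sequence of gene ``name``; ``None`` when absent."""
    feat = genome.get(name)
    if feat is None:
        return None
    return feat.extract(genome.sequence)


# ---------------------------------------------------------------------------
# GenBank reading
# ---------------------------------------------------------------------------

_ANTICODON_SEQ_RE = re.compile(r"seq\s*:\s*([acgtu]{3})", re.IGNORECASE)

# ancestral neighbours used to resolve Ser/Leu paralogs annotated without
# an anticodon: each paralog sits in a distinctive gene neighbourhood
_PARALOG_NEIGHBOURS = {
    "trnL1": {"rrnL", "nad1"},
    "trnL2": {"cox1", "cox2"},
    "trnS1": {"trnN", "trnE"},
    "trnS2": {"cob", "nad6"},
}


def _feature_label(feat: SeqFeature) -> str | None:
    for key in ("gene", "product", "note", "standard_name"):
        vals = feat.qualifiers.get(key)
        if vals:
            return str(vals[0])
    if feat.type in ("D-loop", "rep_origin"):
        return "control region"
    return None


def _feature_anticodon(feat: SeqFeature) -> str | None:
    for key in ("anticodon", "note"):
        for val in feat.qualifiers.get(key, []):
            m = _ANTICODON_SEQ_RE.search(str(val))
            if m:
                return m.group(1).upper().replace("T", "U")
            if key == "note" and re.fullmatch(r"[ACGTUacgtu]{3}", str(val).strip()):
                return str(val).strip().upper().replace("T", "U")
    return None


def _location_to_intervals(loc) -> list[tuple[int, int]]:
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    ivals = [(int(p.start), int(p.end)) for p in parts]
    if loc.strand == -1:
        # Biopython lists complement-join parts 5'->3' on the minus strand;
        # store them in J-strand genomic reading order instead
        ivals = ivals[::-1]
    return ivals


def read_genbank(path) -> Mitogenome:
    """Parse a GenBank flat file into a normalised :class:`Mitogenome`.

    Recognised features (CDS, tRNA, rRNA, D-loop/misc_feature control
    region) are canonicalised; unrecognised ones are kept with the flag
    ``"unknown"`` and excluded from comparative statistics downstream.
    Duplicate annotations of one gene keep the longest copy.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise GenomeParseError(f"cannot parse GenBank file {path}: {exc}") from exc

    topology = record.annotations.get("topology", "circular")
    genome = Mitogenome(
        accession=record.id,
        organism=record.annotations.get("organism", record.description or ""),
        sequence=str(record.seq).upper(),
        topology="circular" if topology == "circular" else "linear-sequenced-region",
    )

    feats: list[GeneFeature] = []
    for feat in record.features:
        if feat.type not in ("CDS", "tRNA", "rRNA", "misc_feature", "D-loop"):
            continue
        label = _feature_label(feat)
        if label is None:
            continue
        anticodon = _feature_anticodon(feat)
        name = canonicalize_gene_name(label, anticodon)
        flags: list[str] = []
        if name is None:
            warnings.warn(f"unrecognised gene label {label!r} kept as unknown",
                          stacklevel=2)
            name = label
            flags.append("unknown")
        strand = "N" if feat.location.strand == -1 else "J"
        fclass = _CLASS_OF.get(name, {"CDS": "PCG", "tRNA": "tRNA",
                                      "rRNA": "rRNA"}.get(feat.type, "unknown"))
        feats.append(GeneFeature(
            name=name, feature_class=fclass, strand=strand,
            intervals=_location_to_intervals(feat.location),
            anticodon=anticodon, flags=flags,
        ))

    feats = _resolve_paralogs(feats)
    feats = _drop_duplicates(feats)
    feats.sort(key=lambda f: (f.start, -f.length))
    genome.features = feats

    if not any(f.name in _CLASS_OF for f in feats):
        raise GenomeContentError(
            f"{path}: no recognisable mitochondrial genes in feature table")
    genome.validate()
    return genome


def _resolve_paralogs(feats: list[GeneFeature]) -> list[GeneFeature]:
    """Assign trnL?/trnS? placeholders to a paralog by gene neighbourhood."""
    ordered = sorted(feats, key=lambda f: f.start)
    used = {f.name for f in ordered}
    for i, f in enumerate(ordered):
        if f.name not in ("trnL?", "trnS?"):
            continue
        pair = ("trnL1", "trnL2") if f.name == "trnL?" else ("trnS1", "trnS2")
        neigh = set()
        if len(ordered) > 1:
            neigh.add(ordered[(i - 1) % len(ordered)].name)
            neigh.add(ordered[(i + 1) % len(ordered)].name)
        chosen = None
        for cand in pair:
            if neigh & _PARALOG_NEIGHBOURS[cand]:
                chosen = cand
                break
        if chosen is None:
            chosen = next((c for c in pair if c not in used), pair[0])
        f.name = chosen
        f.feature_class = "tRNA"
        f.flags.append("inferred")
        used.add(chosen)
    return feats


def _drop_duplicates(feats: list[GeneFeature]) -> list[GeneFeature]:
    best: dict[str, GeneFeature] = {}
    keep: list[GeneFeature] = []
    for f in feats:
        if f.name not in _CLASS_OF:
            keep.append(f)
            continue
        prev = best.get(f.name)
        if prev is None:
            best[f.name] = f
            keep.append(f)
        elif f.length > prev.length:
            prev.flags.append("duplicate")
            keep.remove(prev)
            best[f.name] = f
            keep.append(f)
        else:
            f.flags.append("duplicate")
    return keep


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _intervals_to_location(f: GeneFeature) -> SimpleLocation | CompoundLocation:
    strand = -1 if f.strand == "N" else 1
    parts = [SimpleLocation(s, e, strand) for s, e in f.intervals]
    if strand == -1:
        parts = parts[::-1]
    return parts[0] if len(parts) == 1 else CompoundLocation(parts)


def write_genbank(genome: Mitogenome, path) -> None:
    """Write a genome back to a GenBank flat file (read_genbank inverse)."""
    record = SeqRecord(Seq(genome.sequence), id=genome.accession,
                       name=genome.accession.split(".")[0][:16],
                       description=f"{genome.organism} mitochondrion")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = (
        "circular" if genome.topology == "circular" else "linear")
    record.annotations["organism"] = genome.organism
    for f in genome.features:
        ftype = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                 "control": "misc_feature"}.get(f.feature_class, "misc_feature")
        quals = {"gene": [f.name]}
        if f.feature_class == "PCG":
            quals["transl_table"] = ["5"]
        if f.anticodon:
            quals["note"] = [f"anticodon seq:{f.anticodon.lower()}"]
        if f.feature_class == "control":
            quals["note"] = ["A+T-rich region"]
        record.features.append(
            SeqFeature(_intervals_to_location(f), type=ftype, qualifiers=quals))
    SeqIO.write(record, str(path), "genbank")


def write_gene_fasta(genome: Mitogenome, path, feature_class: str | None = None) -> None:
    """Write per-gene sense-strand sequences as FASTA."""
    with open(path, "w") as fh:
        for f in genome.features:
            if feature_class and f.feature_class != feature_class:
                continue
            fh.write(f">{genome.accession}|{f.name}\n{f.extract(genome.sequence)}\n")


def write_feature_table(genome: Mitogenome, path) -> None:
    """TSV feature table: accession, gene, class, strand, start, end, length."""
    with open(path, "w") as fh:
        fh.write("accession\tgene\tclass\tstrand\tstart\tend\tlength\n")
        for f in genome.features:
            fh.write(f"{genome.accession}\t{f.name}\t{f.feature_class}\t"
                     f"{f.strand}\t{f.start}\t{f.end}\t{f.length}\n")
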