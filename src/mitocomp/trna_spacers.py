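"""tRNA cloverleaf structures, mismatched pairs, and spacer/overlap census.

A mitochondrial tRNA folds into a cloverleaf with four arms: the
amino-acid acceptor (AA) stem, the DHU arm, the anticodon (AC) arm and
the TΨC arm, plus a variable loop.  Metazoan mitochondrial tRNAs often
lose the DHU stem (a large loop replaces the arm).  Structures are
either parsed from dot-bracket strings (e.g. structure-prediction
output) or folded with a deterministic constrained heuristic.

The mismatch census counts stem pairs outside the canonical set
{A-U, U-A, G-C, C-G, G-U, U-G}; the G-U wobble is canonical by default
but the set is configurable.  T in DNA input pairs as U.

Intergenic spacers and overlaps are censused by walking consecutive
annotated features: signed junction length = next.start - current.end
(positive gap, negative overlap, zero abutting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import Mitogenome, MitocompError, CONTROL_NAME, reverse_complement

__all__ = ["CloverleafStructure", "MismatchRecord", "SpacerRecord",
           "StructureParseError", "CANONICAL_PAIRS",
           "parse_structure_string", "to_dot_bracket", "fold_cloverleaf",
           "count_mismatches", "spacer_overlap_scan", "find_motif"]

CANONICAL_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
                             ("G", "U"), ("U", "G")})

# stem size ranges (pairs); DHU 0 encodes a D-arm replaced by a loop
ARM_RANGES = {"AA": (6, 8), "DHU": (0, 4), "AC": (4, 6), "TPSIC": (3, 5)}


class StructureParseError(MitocompError):
    """A dot-bracket string could not be interpreted as a cloverleaf."""


@dataclass
class CloverleafStructure:
    """Paired positions (0-based, (5'i, 3'j)) of the four cloverleaf arms."""

    aa_stem: list[tuple[int, int]]
    dhu_stem: list[tuple[int, int]]
    ac_stem: list[tuple[int, int]]
    tpsic_stem: list[tuple[int, int]]
    dhu_loop: tuple[int, int] | None = None      # [start, end) ranges
    ac_loop: tuple[int, int] | None = None
    tpsic_loop: tuple[int, int] | None = None
    variable_loop: tuple[int, int] | None = None
    anticodon_positions: tuple[int, int, int] | None = None
    degenerate: bool = False                     # D-arm replaced by a loop

    def all_pairs(self) -> list[tuple[str, tuple[int, int]]]:
        out = []
        for arm, stem in (("AA", self.aa_stem), ("DHU", self.dhu_stem),
                          ("AC", self.ac_stem), ("TPSIC", self.tpsic_stem)):
            out.extend((arm, p) for p in stem)
        return out


@dataclass
class MismatchRecord:
    """One non-canonical stem pair of a tRNA."""

    trna: str
    pair: tuple[str, str]
    arm: str
    position: tuple[int, int]


@dataclass
class SpacerRecord:
    """One junction between consecutive annotated features."""

    upstream: str
    downstream: str
    signed_length: int           # >0 gap, <0 overlap, 0 abutting
    sequence: str = ""           # gap sequence (empty for overlaps)
    junction_seq: str = ""       # gap or overlap-local sequence for motif search
    motifs: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# dot-bracket parsing
# ---------------------------------------------------------------------------

def _pairs_from_dot_bracket(structure: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureParseError(f"unbalanced ')' at position {i}")
            pairs.append((stack.pop(), i))
        elif ch not in ".-:,_":
            raise StructureParseError(f"unexpected character {ch!r} at {i}")
    if stack:
        raise StructureParseError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


def to_dot_bracket(structure: CloverleafStructure, length: int) -> str:
    """Regenerate the dot-bracket string of a cloverleaf structure."""
    chars = ["."] * length
    for _, (i, j) in structure.all_pairs():
        chars[i], chars[j] = "(", ")"
    return "".join(chars)


def _group_stems(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Split nested pairs into ladders, breaking at multiloop branch points."""
    if not pairs:
        return []
    # children[k] = pairs directly nested inside pair k
    children: dict[int, list[int]] = {k: [] for k in range(len(pairs))}
    roots: list[int] = []
    stack: list[int] = []
    for k, (i, j) in enumerate(pairs):   # pairs sorted by i
        while stack and not (pairs[stack[-1]][0] < i and j < pairs[stack[-1]][1]):
            stack.pop()
        if stack:
            children[stack[-1]].append(k)
        else:
            roots.append(k)
        stack.append(k)
    stems: list[list[tuple[int, int]]] = []

    def walk(start: int) -> None:
        stem = [pairs[start]]
        node = start
        while len(children[node]) == 1:
            node = children[node][0]
            stem.append(pairs[node])
        stems.append(stem)
        for child in children[node]:
            walk(child)

    for r in roots:
        walk(r)
    return stems


def parse_structure_string(seq: str, structure: str) -> CloverleafStructure:
    """Interpret a dot-bracket string as a cloverleaf.

    Arms are assigned positionally: the closing stem is the AA stem and
    the hairpins in 5'→3' order are DHU, AC, TΨC.  With only two
    hairpins the D-arm is degenerate (a loop) and the hairpins are AC
    and TΨC.
    """
    if len(seq) != len(structure):
        raise StructureParseError("sequence/structure length mismatch")
    pairs = _pairs_from_dot_bracket(structure)
    if not pairs:
        raise StructureParseError("no base pairs in structure")
    stems = _group_stems(pairs)
    hairpins: list[list[tuple[int, int]]]
    if len(stems) >= 2:
        # the stem with the outermost (5'-most) pair closes the cloverleaf
        closing = min(stems, key=lambda st: st[0][0])
        hairpins = sorted((st for st in stems if st is not closing),
                          key=lambda st: st[0][0])
    else:
        closing = stems[0]
        hairpins = []

    dhu: list[tuple[int, int]] = []
    ac: list[tuple[int, int]] = []
    tpsic: list[tuple[int, int]] = []
    degenerate = False
    if len(hairpins) >= 3:
        dhu, ac, tpsic = hairpins[0], hairpins[1], hairpins[2]
    elif len(hairpins) == 2:
        ac, tpsic = hairpins
        degenerate = True
    elif len(hairpins) == 1:
        ac = hairpins[0]
        degenerate = True
    else:
        raise StructureParseError("structure has no hairpins")

    def hairpin_loop(stem):
        if not stem:
            return None
        i, j = stem[-1]
        return (i + 1, j)

    ac_loop = hairpin_loop(ac)
    anticodon = None
    if ac_loop:
        lo, hi = ac_loop
        mid = (lo + hi) // 2
        if hi - lo >= 3:
            anticodon = (mid - 1, mid, mid + 1)
    variable = None
    if ac and tpsic:
        variable = (ac[0][1] + 1, tpsic[0][0])
    return CloverleafStructure(
        aa_stem=closing, dhu_stem=dhu, ac_stem=ac, tpsic_stem=tpsic,
        dhu_loop=hairpin_loop(dhu), ac_loop=ac_loop,
        tpsic_loop=hairpin_loop(tpsic), variable_loop=variable,
        anticodon_positions=anticodon, degenerate=degenerate)


# ---------------------------------------------------------------------------
# heuristic folding
# ---------------------------------------------------------------------------

def _pair_score(a: str, b: str) -> int:
    """Canonical Watson-Crick +2, G-U wobble +1, anything else -1."""
    x = (a.replace("T", "U"), b.replace("T", "U"))
    if x in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
        return 2
    if x in (("G", "U"), ("U", "G")):
        return 1
    return -1


def _best_hairpin(seq: str, lo: int, hi: int, min_len: int, max_len: int,
                  min_loop: int = 3, max_loop: int = 9):
    """Highest-scoring hairpin stem inside region [lo, hi).

    Returns (score, stem_pairs) with stem_pairs [] when nothing fits.
    Deterministic tie-break: 5'-most start, then longest stem.
    """
    best_score, best = 0, []
    for s in range(lo, hi):
        for ln in range(max_len, min_len - 1, -1):
            for loop in range(min_loop, max_loop + 1):
                e = s + 2 * ln + loop - 1
                if e >= hi:
                    continue
                stem = [(s + k, e - k) for k in range(ln)]
                score = sum(_pair_score(seq[i], seq[j]) for i, j in stem)
                if score > best_score:
                    best_score, best = score, stem
    return best_score, best


def fold_cloverleaf(seq: str, anticodon: str) -> CloverleafStructure | None:
    """Fold a tRNA sequence into a cloverleaf anchored at its anticodon.

    The anticodon is centred in a 7-nt AC loop; the AC stem (4-6 pairs),
    AA stem (6-8 pairs, pairing the 5' and 3' termini), DHU stem (0-4
    pairs) and TΨC stem (3-5 pairs) are chosen to maximise the total
    pair score (+2 canonical, +1 G-U, -1 mismatch), subject to
    non-crossing and the arm-size ranges.  Deterministic; ties resolved
    toward the 5'-most anticodon anchor and the longest stems.  Returns
    ``None`` when no candidate satisfies the constraints (fold failure).
    """
    seq = seq.upper().replace("U", "T")
    if not (55 <= len(seq) <= 90):
        raise ValueError(f"tRNA length {len(seq)} outside 55-90 nt")
    anticodon = anticodon.upper().replace("U", "T")
    anchors = [p for p in range(len(seq) - 2) if seq[p:p + 3] == anticodon]
    if not anchors:
        raise ValueError("anticodon not found in sequence")

    n = len(seq)
    best_score = None
    best_struct = None
    for p in anchors:
        loop_lo, loop_hi = p - 2, p + 5        # 7-nt AC loop [loop_lo, loop_hi)
        if loop_lo < 1 or loop_hi > n - 1:
            continue
        for aa_len in range(ARM_RANGES["AA"][1], ARM_RANGES["AA"][0] - 1, -1):
            aa_stem = [(k, n - 1 - k) for k in range(aa_len)]
            for ac_len in range(ARM_RANGES["AC"][1], ARM_RANGES["AC"][0] - 1, -1):
                ac_stem = [(loop_lo - 1 - k, loop_hi + k) for k in range(ac_len)]
                five_lo, five_hi = aa_len, loop_lo - ac_len   # DHU region
                three_lo, three_hi = loop_hi + ac_len, n - aa_len
                if five_hi < five_lo or three_hi < three_lo:
                    continue
                score = sum(_pair_score(seq[i], seq[j]) for i, j in aa_stem)
                score += sum(_pair_score(seq[i], seq[j]) for i, j in ac_stem)
                d_score, dhu_stem = _best_hairpin(
                    seq, five_lo, five_hi, 1, ARM_RANGES["DHU"][1])
                t_score, tpsic_stem = _best_hairpin(
                    seq, three_lo, three_hi,
                    ARM_RANGES["TPSIC"][0], ARM_RANGES["TPSIC"][1])
                score += d_score + t_score
                if best_score is None or score > best_score:
                    best_score = score
                    best_struct = (p, aa_stem, dhu_stem, ac_stem, tpsic_stem)
    if best_struct is None:
        return None
    p, aa_stem, dhu_stem, ac_stem, tpsic_stem = best_struct
    ac_stem = sorted(ac_stem)
    struct = CloverleafStructure(
        aa_stem=aa_stem, dhu_stem=dhu_stem, ac_stem=ac_stem,
        tpsic_stem=tpsic_stem,
        dhu_loop=((dhu_stem[-1][0] + 1, dhu_stem[-1][1]) if dhu_stem else None),
        ac_loop=(p - 2, p + 5),
        tpsic_loop=((tpsic_stem[-1][0] + 1, tpsic_stem[-1][1])
                    if tpsic_stem else None),
        variable_loop=((ac_stem[0][1] + 1, tpsic_stem[0][0])
                       if tpsic_stem else None),
        anticodon_positions=(p, p + 1, p + 2),
        degenerate=not dhu_stem)
    return struct


def count_mismatches(structure: CloverleafStructure, seq: str,
                     trna: str = "",
                     canonical: frozenset = CANONICAL_PAIRS) -> list[MismatchRecord]:
    """Stem pairs whose bases fall outside the canonical pair set."""
    seq_u = seq.upper().replace("T", "U")
    records = []
    for arm, (i, j) in structure.all_pairs():
        pair = (seq_u[i], seq_u[j])
        if pair not in canonical:
            records.append(MismatchRecord(trna=trna, pair=pair, arm=arm,
                                          position=(i, j)))
    return records


# ---------------------------------------------------------------------------
# spacer / overlap census
# ---------------------------------------------------------------------------

def spacer_overlap_scan(genome: Mitogenome) -> tuple[list[SpacerRecord], dict]:
    """Census of gaps, overlaps and abutments between consecutive features.

    Nested features (fully inside another) are excluded from the walk.
    The control region is a feature (its flanks are junctions) but its
    own length never counts as intergenic sequence.  The wrap-around
    junction is included for circular genomes.
    """
    feats = sorted((f for f in genome.features if "unknown" not in f.flags),
                   key=lambda f: (f.start, -f.length))
    if len(feats) < 2:
        raise ValueError("need at least two features for a junction walk")
    # drop nested features
    kept = []
    for f in feats:
        nested = any(g is not f and g.start <= f.start and f.end <= g.end
                     and g.length > f.length for g in feats)
        if not nested:
            kept.append(f)
    records: list[SpacerRecord] = []
    n = len(kept)
    L = genome.length
    n_junctions = n if genome.topology == "circular" else n - 1
    for i in range(n_junctions):
        cur, nxt = kept[i], kept[(i + 1) % n]
        if i == n - 1:   # wrap junction
            signed = nxt.start + L - cur.end
            gap_seq = genome.sequence[cur.end:] + genome.sequence[:nxt.start] \
                if signed > 0 else ""
            junc = gap_seq if signed > 0 else genome.sequence[
                nxt.start: nxt.start - signed]
        else:
            signed = nxt.start - cur.end
            gap_seq = genome.sequence[cur.end:nxt.start] if signed > 0 else ""
            junc = gap_seq if signed > 0 else genome.sequence[nxt.start:cur.end]
        records.append(SpacerRecord(upstream=cur.name, downstream=nxt.name,
                                    signed_length=signed, sequence=gap_seq,
                                    junction_seq=junc))
    gaps = [r for r in records if r.signed_length > 0]
    overlaps = [r for r in records if r.signed_length < 0]
    longest = max(gaps, key=lambda r: r.signed_length, default=None)
    summary = {
        "total_intergenic_bp": sum(r.signed_length for r in gaps),
        "n_gap_locations": len(gaps),
        "longest_gap": longest.signed_length if longest else 0,
        "longest_gap_junction": ((longest.upstream, longest.downstream)
                                 if longest else None),
        "n_overlaps": len(overlaps),
        "overlap_length_range": ((min(-r.signed_length for r in overlaps),
                                  max(-r.signed_length for r in overlaps))
                                 if overlaps else (0, 0)),
        "n_abutting": sum(1 for r in records if r.signed_length == 0),
    }
    return records, summary


def find_motif(records: list[SpacerRecord], motif: str,
               where: str = "both") -> list[dict]:
    """Exact-match motif search on junction-local sequences.

    Both orientations are searched; each hit reports the junction, the
    offset and the orientation (J for as-given, N for the reverse
    complement).
    """
    if not motif:
        raise ValueError("empty motif")
    motif = motif.upper()
    rc = reverse_complement(motif)
    hits = []
    for r in records:
        if where == "gaps" and r.signed_length <= 0:
            continue
        if where == "overlaps" and r.signed_length >= 0:
            continue
        for needle, orient in ((motif, "J"), (rc, "N")):
            start = r.junction_seq.find(needle)
            if start != -1:
                hits.append({"upstream": r.upstream, "downstream": r.downstream,
                             "offset": start, "orientation": orient,
                             "motif": motif})
                if motif not in r.motifs:
                    r.motifs.append(motif)
                break
    return hits
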