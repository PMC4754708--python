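"""Circular signed gene orders and rearrangement analysis.

A mitogenome's gene arrangement is a circular signed permutation of the
37 canonical genes (+ control region); sign + means J-strand, - means
N-strand.  Arrangements are compared against the putative ancestral
insect arrangement: genes outside a maximum common circular signed
subsequence are classified as translocated (moved, same strand),
inverted in place (strand flip, same position) or remote-inverted
(moved + strand flip).  Breakpoints are signed circular adjacencies of
one order absent from the other, with (x -> y) considered shared with
(-y -> -x) (the standard signed-adjacency convention, under which a full
mirror reversal of a circle has distance 0).

Event classification is a heuristic: the narrative is a set of "at
least N" events, not a provably minimum scenario.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

from .genome_io import ALL_GENE_NAMES, CONTROL_NAME, Mitogenome, MitocompError

__all__ = ["GeneOrderPerm", "RearrangementReport", "RearrangementEvent",
           "ancestral_insect_order", "extract_gene_order",
           "compare_to_ancestor", "breakpoint_distance", "apply_rearrangement"]


class GeneOrderError(MitocompError):
    """Invalid gene-order input (unknown genes, mismatched gene sets)."""


@dataclass
class GeneOrderPerm:
    """A circular signed gene order: [(name, +1|-1), ...]."""

    order: list[tuple[str, int]]
    missing: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.order]
        if not names:
            raise GeneOrderError("empty gene order")
        if len(names) != len(set(names)):
            raise GeneOrderError("repeated gene names in order")

    @property
    def names(self) -> set[str]:
        return {n for n, _ in self.order}

    def sign_of(self, name: str) -> int:
        for n, s in self.order:
            if n == name:
                return s
        raise KeyError(name)

    def project(self, keep: set[str]) -> "GeneOrderPerm":
        """Delete genes outside ``keep`` (circular order preserved)."""
        return GeneOrderPerm(order=[(n, s) for n, s in self.order if n in keep],
                             missing=set(self.missing))

    def rotate_to(self, name: str) -> list[tuple[str, int]]:
        idx = [n for n, _ in self.order].index(name)
        return self.order[idx:] + self.order[:idx]

    def format(self) -> str:
        """Linear map string, '-' prefix marks N-strand genes."""
        return " ".join(("-" if s < 0 else "") + n for n, s in self.order)


@dataclass
class RearrangementEvent:
    """A rearrangement to inject: move ``gene`` to just before ``before``.

    kinds: ``translocation`` (move, sign kept), ``inversion`` (in-place
    sign flip, ``before`` ignored), ``remote_inversion`` (move + flip).
    """

    kind: str
    gene: str
    before: str | None = None


@dataclass
class RearrangementReport:
    """Comparison of an observed order against the ancestor."""

    status: dict[str, str]           # gene -> in_place / translocated / ...
    breakpoint_count: int
    conserved_blocks: list[list[tuple[str, int]]]
    narrative: list[str]


# Ancestral insect mitochondrial gene arrangement (circular; starts at
# trnI by convention).
_ANCESTRAL = [
    ("trnI", +1), ("trnQ", -1), ("trnM", +1), ("nad2", +1), ("trnW", +1),
    ("trnC", -1), ("trnY", -1), ("cox1", +1), ("trnL2", +1), ("cox2", +1),
    ("trnK", +1), ("trnD", +1), ("atp8", +1), ("atp6", +1), ("cox3", +1),
    ("trnG", +1), ("nad3", +1), ("trnA", +1), ("trnR", +1), ("trnN", +1),
    ("trnS1", +1), ("trnE", +1), ("trnF", -1), ("nad5", -1), ("trnH", -1),
    ("nad4", -1), ("nad4l", -1), ("trnT", +1), ("trnP", -1), ("nad6", +1),
    ("cob", +1), ("trnS2", +1), ("nad1", -1), ("trnL1", -1), ("rrnL", -1),
    ("trnV", -1), ("rrnS", -1), (CONTROL_NAME, +1),
]


def ancestral_insect_order() -> GeneOrderPerm:
    """The putative ancestral insect arrangement (37 genes + control)."""
    return GeneOrderPerm(order=list(_ANCESTRAL))


def extract_gene_order(genome: Mitogenome) -> GeneOrderPerm:
    """Observed circular signed gene order of an annotated genome.

    Genes sorted by start coordinate; ties broken longest-first (and
    logged via the feature's flags upstream).  Canonically unrecognised
    features are skipped; unsequenced canonical genes are listed in
    ``missing``.
    """
    known = set(ALL_GENE_NAMES) | {CONTROL_NAME}
    feats = [f for f in genome.features if f.name in known]
    if len(feats) < 1:
        raise GeneOrderError(f"{genome.accession}: no canonical genes")
    feats.sort(key=lambda f: (f.start, -f.length))
    order = [(f.name, -1 if f.strand == "N" else +1) for f in feats]
    missing = known - {f.name for f in feats}
    return GeneOrderPerm(order=order, missing=missing)


def apply_rearrangement(order: GeneOrderPerm,
                        events: list[RearrangementEvent]) -> GeneOrderPerm:
    """Apply rearrangement events to a gene order (used to build cases
    with known ground truth)."""
    cur = list(order.order)
    names = [n for n, _ in cur]
    for ev in events:
        if ev.gene not in names:
            raise GeneOrderError(f"event gene {ev.gene!r} not in order")
        i = names.index(ev.gene)
        if ev.kind == "inversion":
            cur[i] = (cur[i][0], -cur[i][1])
            continue
        if ev.kind not in ("translocation", "remote_inversion"):
            raise GeneOrderError(f"unknown event kind {ev.kind!r}")
        if ev.before is None or ev.before == ev.gene:
            raise GeneOrderError(f"bad destination for {ev.gene}: {ev.before!r}")
        if ev.before not in names:
            raise GeneOrderError(f"destination gene {ev.before!r} not in order")
        item = cur.pop(i)
        if ev.kind == "remote_inversion":
            item = (item[0], -item[1])
        names = [n for n, _ in cur]
        j = names.index(ev.before)
        cur.insert(j, item)
        names = [n for n, _ in cur]
    return GeneOrderPerm(order=cur, missing=set(order.missing))


# ---------------------------------------------------------------------------
# circular LCS machinery
# ---------------------------------------------------------------------------

def _lis_indices(seq: list[int]) -> list[int]:
    """Indices of one longest strictly increasing subsequence of seq."""
    tails: list[int] = []          # values
    tails_idx: list[int] = []      # index in seq of each tail
    parent = [-1] * len(seq)
    for i, v in enumerate(seq):
        j = bisect_left(tails, v)
        if j == len(tails):
            tails.append(v)
            tails_idx.append(i)
        else:
            tails[j] = v
            tails_idx[j] = i
        parent[i] = tails_idx[j - 1] if j > 0 else -1
    out: list[int] = []
    k = tails_idx[-1] if tails_idx else -1
    while k != -1:
        out.append(k)
        k = parent[k]
    return out[::-1]


def _cyclic_common_subsequence(a: list, b: list) -> list:
    """Maximum-length common circular subsequence of two circular lists
    of unique hashable items (returns the items, in a's order)."""
    set_b = set(b)
    common_items = [x for x in a if x in set_b]
    if not common_items:
        return []
    best: list = []
    names_a = a
    names_b = b
    for anchor in common_items:
        ia = names_a.index(anchor)
        ib = names_b.index(anchor)
        rot_a = names_a[ia:] + names_a[:ia]
        rot_b = names_b[ib:] + names_b[:ib]
        pos_b = {x: k for k, x in enumerate(rot_b)}
        filt = [x for x in rot_a if x in pos_b]
        seq = [pos_b[x] for x in filt]
        lis = _lis_indices(seq)
        cand = [filt[k] for k in lis]
        if len(cand) > len(best):
            best = cand
    return best


def _adjacency_set(order: list[tuple[str, int]],
                   exclude: frozenset[str] = frozenset()) -> set[frozenset]:
    """Canonical signed circular adjacencies of an order.

    Each adjacency (x,sx)->(y,sy) is stored in a flip-invariant canonical
    form so that (x->y) and (-y->-x) compare equal.
    """
    items = [(n, s) for n, s in order if n not in exclude]
    out: set = set()
    m = len(items)
    for i in range(m):
        (x, sx), (y, sy) = items[i], items[(i + 1) % m]
        fwd = (x, sx, y, sy)
        rev = (y, -sy, x, -sx)
        out.add(min(fwd, rev))
    return out


def breakpoint_distance(a: GeneOrderPerm, b: GeneOrderPerm) -> int:
    """Signed circular adjacencies of ``a`` absent from ``b``."""
    if a.names != b.names:
        raise GeneOrderError(
            f"gene sets differ: {sorted(a.names ^ b.names)}")
    return len(_adjacency_set(a.order) - _adjacency_set(b.order))


def compare_to_ancestor(observed: GeneOrderPerm,
                        ancestor: GeneOrderPerm | None = None) -> RearrangementReport:
    """Classify each observed gene against the ancestral arrangement.

    The ancestor is first projected onto the observed gene set, so genes
    missing from a partially sequenced genome are never reported as
    rearranged.  The control region takes part in ordering but is
    excluded from breakpoint counting.
    """
    if ancestor is None:
        ancestor = ancestral_insect_order()
    unknown = observed.names - ancestor.names
    if unknown:
        raise GeneOrderError(f"genes unknown to ancestor: {sorted(unknown)}")
    anc = ancestor.project(observed.names)

    signed_obs = list(observed.order)
    signed_anc = list(anc.order)
    in_place_items = set(_cyclic_common_subsequence(signed_obs, signed_anc))
    unsigned_common = set(_cyclic_common_subsequence(
        [n for n, _ in signed_obs], [n for n, _ in signed_anc]))

    status: dict[str, str] = {}
    narrative: list[str] = []
    anc_sign = {n: s for n, s in anc.order}
    for name, sign in observed.order:
        if (name, sign) in in_place_items:
            status[name] = "in_place"
        elif sign != anc_sign[name] and name in unsigned_common:
            status[name] = "inverted_in_place"
            narrative.append(f"inversion of {name} in place")
        elif sign == anc_sign[name]:
            status[name] = "translocated"
            narrative.append(f"translocation of {name}")
        else:
            status[name] = "remote_inverted"
            narrative.append(f"remote inversion of {name}")

    exclude = frozenset({CONTROL_NAME})
    bp = len(_adjacency_set(observed.order, exclude)
             - _adjacency_set(anc.order, exclude))

    blocks = _conserved_blocks(observed, anc, status)
    return RearrangementReport(status=status, breakpoint_count=bp,
                               conserved_blocks=blocks, narrative=narrative)


def _conserved_blocks(observed: GeneOrderPerm, anc: GeneOrderPerm,
                      status: dict[str, str]) -> list[list[tuple[str, int]]]:
    """Maximal circular runs of in-place genes whose adjacency is shared
    with the ancestor projected onto the in-place set."""
    in_place = [it for it in observed.order if status[it[0]] == "in_place"]
    if not in_place:
        return []
    keep = {n for n, _ in in_place}
    anc_adj = _adjacency_set([it for it in anc.order if it[0] in keep])
    m = len(in_place)
    if m == 1:
        return [in_place]
    joined = []
    for i in range(m):
        (x, sx), (y, sy) = in_place[i], in_place[(i + 1) % m]
        joined.append(min((x, sx, y, sy), (y, -sy, x, -sx)) in anc_adj)
    if all(joined):
        return [in_place]
    # open the circle at a break
    first_break = joined.index(False) + 1
    ring = in_place[first_break:] + in_place[:first_break]
    ring_joined = joined[first_break:] + joined[:first_break]
    blocks: list[list[tuple[str, int]]] = [[ring[0]]]
    for i in range(1, m):
        if ring_joined[i - 1]:
            blocks[-1].append(ring[i])
        else:
            blocks.append([ring[i]])
    return blocks
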