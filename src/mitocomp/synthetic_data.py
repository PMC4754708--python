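"""Synthetic annotated mitogenomes and codon-evolution simulators.

Every analysis stage in this package is testable without downloads: the
generator emits a circular 37-gene mitogenome (plus control region) with
controllable gene order, per-region base-composition targets, planted
tRNA cloverleaf structures with known mismatch counts, and a planned
spacer/overlap layout — together with a ground-truth record of
everything planted.  Defaults emulate a basal hymenopteran mitogenome:
~11.2 kb of protein-coding sequence at ~79% A+T on the sense strand, an
A+T-richer rRNA/control region, the characteristic 7-bp ATGATAA overlap
between atp8 and atp6, an ATTATAA motif in the nad4/nad4l spacer, and an
incomplete stop codon (T, completed by polyadenylation) on nad5.

Codon-sequence pairs are evolved under a per-site Poisson substitution
process with transition bias kappa; nonsynonymous changes are accepted
with probability proportional to the dN/dS ratio omega, and changes
creating a stop codon (invertebrate mitochondrial code) are rejected.
A separate K80 alignment simulator supports saturation screening.

One integer seed drives everything; per-gene sub-streams are derived
from fixed gene indices so results are independent of generation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .codon_usage import GENETIC_CODE, STOP_CODONS
from .gene_order import (GeneOrderPerm, RearrangementEvent, ancestral_insect_order,
                         apply_rearrangement)
from .genome_io import (CONTROL_NAME, GeneFeature, Mitogenome, MitocompError,
                        PCG_NAMES, RRNA_NAMES, TRNA_NAMES, reverse_complement)
from .trna_spacers import CloverleafStructure, MismatchRecord, fold_cloverleaf

__all__ = ["SimulationSpec", "TrnaPlan", "SpacerJunction", "TruthRecord",
           "SimulationSpecError", "simulate_mitogenome", "simulate_codon_pair",
           "simulate_k80_alignment", "DEFAULT_GENE_LENGTHS",
           "DEFAULT_COMPOSITION", "TRNA_ANTICODONS", "save_truth"]


class SimulationSpecError(MitocompError):
    """An infeasible or inconsistent simulation specification."""


# typical insect mitochondrial anticodons (DNA alphabet)
TRNA_ANTICODONS = {
    "trnA": "TGC", "trnR": "TCG", "trnN": "GTT", "trnD": "GTC", "trnC": "GCA",
    "trnQ": "TTG", "trnE": "TTC", "trnG": "TCC", "trnH": "GTG", "trnI": "GAT",
    "trnK": "CTT", "trnL1": "TAG", "trnL2": "TAA", "trnM": "CAT", "trnF": "GAA",
    "trnP": "TGG", "trnS1": "TCT", "trnS2": "TGA", "trnT": "TGT", "trnW": "TCA",
    "trnV": "TAC", "trnY": "GTA",
}

DEFAULT_GENE_LENGTHS = {
    "cox1": 1539, "cox2": 684, "cox3": 789, "cob": 1140, "nad1": 936,
    "nad2": 1023, "nad3": 354, "nad4": 1341, "nad4l": 294, "nad5": 1719,
    "nad6": 525, "atp6": 678, "atp8": 162,
    "rrnL": 1350, "rrnS": 800, CONTROL_NAME: 350,
}

# per-region sense-strand base targets (A%, C%, G%, T%)
DEFAULT_COMPOSITION = {
    "PCG": (35.2, 10.4, 10.3, 44.1),
    "rRNA": (42.0, 7.5, 8.0, 42.5),
    "control": (42.5, 7.5, 7.5, 42.5),
    "spacer": (42.5, 7.5, 7.5, 42.5),
}

_MISMATCH_PAIRS = (("T", "T"), ("A", "C"), ("A", "A"))
_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass
class TrnaPlan:
    """Planted cloverleaf geometry and mismatch plan for one tRNA."""

    aa_len: int = 7
    spacer_a: int = 2
    dhu_len: int = 4
    dhu_loop: int = 7
    spacer_b: int = 1
    ac_len: int = 5
    var_len: int = 5
    tpsic_len: int = 4
    tpsic_loop: int = 6
    mismatches: list[tuple[str, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        dhu = 2 * self.dhu_len + self.dhu_loop if self.dhu_len else self.dhu_loop
        return (2 * self.aa_len + self.spacer_a + dhu + self.spacer_b
                + 2 * self.ac_len + 7 + self.var_len
                + 2 * self.tpsic_len + self.tpsic_loop)


@dataclass
class SpacerJunction:
    """Planned junction: positive length = gap, negative = overlap."""

    upstream: str
    downstream: str
    signed_length: int
    motif: str | None = None
    motif_strand: str = "J"


def _default_spacer_plan() -> list[SpacerJunction]:
    return [
        SpacerJunction("trnQ", "trnM", 4),
        SpacerJunction("trnM", "nad2", 2),
        SpacerJunction("trnW", "trnC", 10),
        SpacerJunction("cox2", "trnK", 1),
        SpacerJunction("nad3", "trnA", 17),
        SpacerJunction("trnS1", "trnE", 3),
        SpacerJunction("trnE", "trnF", 1),
        SpacerJunction("nad4", "nad4l", 7, motif="ATTATAA", motif_strand="N"),
        SpacerJunction("trnT", "trnP", 5),
        SpacerJunction("trnS2", "nad1", 20),
        SpacerJunction("atp8", "atp6", -7, motif="ATGATAA"),
        SpacerJunction("trnL1", "rrnL", -2),
        SpacerJunction("trnV", "rrnS", -1),
        SpacerJunction("rrnS", CONTROL_NAME, -5),
    ]


def _default_trna_plans() -> dict[str, TrnaPlan]:
    plans = {name: TrnaPlan() for name in TRNA_NAMES}
    # emulate observed structural variety: two D-arm-less tRNAs and a
    # handful of planted mismatches as seen in real sawfly mitogenomes
    plans["trnV"] = TrnaPlan(dhu_len=0, dhu_loop=9)
    plans["trnS1"] = TrnaPlan(dhu_len=0, dhu_loop=9)
    plans["trnA"] = TrnaPlan(mismatches=[("AA", 2)])
    plans["trnE"] = TrnaPlan(mismatches=[("TPSIC", 1)])
    plans["trnG"] = TrnaPlan(mismatches=[("AA", 4)])
    plans["trnL2"] = TrnaPlan(mismatches=[("AA", 1)])
    plans["trnR"] = TrnaPlan(mismatches=[("AA", 3)])
    return plans


@dataclass
class SimulationSpec:
    """Everything the mitogenome generator needs, with study-like defaults."""

    gene_order: GeneOrderPerm = field(default_factory=ancestral_insect_order)
    events: list[RearrangementEvent] = field(default_factory=list)
    per_gene_length: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    composition_target: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION))
    codon_model: tuple[float, float, float] = (0.1, 0.3, 2.0)  # omega, t, kappa
    trna_plans: dict[str, TrnaPlan] = field(default_factory=_default_trna_plans)
    spacer_plan: list[SpacerJunction] = field(default_factory=_default_spacer_plan)
    incomplete_stop_genes: dict[str, str] = field(
        default_factory=lambda: {"nad5": "T"})
    accession: str = "SYN000001"
    organism: str = "Synthetica exemplaris"
    seed: int = 0

    def validate(self) -> None:
        for region, pct in self.composition_target.items():
            if abs(sum(pct) - 100.0) > 1e-9:
                raise SimulationSpecError(
                    f"composition target for {region} sums to {sum(pct)}")
        for name, ln in self.per_gene_length.items():
            if ln <= 0:
                raise SimulationSpecError(f"non-positive length for {name}")
            if name in PCG_NAMES and ln % 3:
                raise SimulationSpecError(
                    f"PCG {name} nominal length {ln} not a codon multiple")
        for j in self.spacer_plan:
            if j.signed_length < 0:
                up_len = self._length_of(j.upstream)
                down_len = self._length_of(j.downstream)
                if -j.signed_length >= min(up_len, down_len):
                    raise SimulationSpecError(
                        f"overlap at {j.upstream}/{j.downstream} exceeds gene length")
            if j.motif and j.signed_length > 0 and len(j.motif) > j.signed_length:
                raise SimulationSpecError(
                    f"motif longer than gap at {j.upstream}/{j.downstream}")

    def _length_of(self, name: str) -> int:
        if name in self.trna_plans:
            return self.trna_plans[name].length
        return self.per_gene_length.get(name, 0)


@dataclass
class TruthRecord:
    """Ground truth for one simulated genome."""

    order: GeneOrderPerm
    events: list[RearrangementEvent]
    spacer_summary: dict
    trna_structures: dict[str, CloverleafStructure]
    trna_mismatches: dict[str, list[MismatchRecord]]
    gene_sequences: dict[str, str]           # sense strand
    peptides: dict[str, str]                 # PCG translations (table 5)
    region_base_counts: dict[str, dict[str, int]]
    pcg_codon_counts: dict[str, int]         # sense codons, stops excluded
    pcg_stop_counts: dict[str, int]


def save_truth(truth: TruthRecord, path) -> None:
    """Persist the scalar parts of a truth record as JSON."""
    payload = {
        "order": [[n, s] for n, s in truth.order.order],
        "events": [[e.kind, e.gene, e.before] for e in truth.events],
        "spacer_summary": {k: list(v) if isinstance(v, tuple) else v
                           for k, v in truth.spacer_summary.items()},
        "trna_mismatch_counts": {k: len(v) for k, v in truth.trna_mismatches.items()},
        "region_base_counts": truth.region_base_counts,
        "pcg_codon_counts": truth.pcg_codon_counts,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# low-level generators
# ---------------------------------------------------------------------------

def _rng_for(seed: int, name: str) -> np.random.Generator:
    """Per-gene substream with a fixed offset, independent of call order."""
    idx = (list(PCG_NAMES) + list(RRNA_NAMES) + list(TRNA_NAMES)
           + [CONTROL_NAME, "@pair", "@k80", "@spacer"]).index(name)
    return np.random.default_rng([seed, idx])


def _draw_bases(rng: np.random.Generator, n: int,
                pct: tuple[float, float, float, float]) -> str:
    probs = np.asarray(pct, dtype=float) / 100.0
    return "".join(np.asarray(list("ACGT"))[rng.choice(4, size=n, p=probs)])


def _make_cds(rng: np.random.Generator, length: int,
              pct: tuple[float, float, float, float],
              incomplete: str | None = None) -> str:
    """A start-ATN, stop-terminated CDS hitting the base target.

    ``length`` is the nominal full length including a complete stop;
    planting an incomplete stop truncates the terminal TAA to T or TA.
    Bases are drawn i.i.d. from the target; in-frame stop codons are
    repaired by swapping their first two bases (TAA->ATA, TAG->ATG),
    which preserves composition exactly.
    """
    if length % 3:
        raise SimulationSpecError(f"CDS nominal length {length} not in frame")
    body_len = length - 3
    bases = list(_draw_bases(rng, body_len, pct))
    bases[0], bases[1] = "A", "T"            # ATN start
    for k in range(1, body_len // 3):
        codon = "".join(bases[3 * k: 3 * k + 3])
        if codon in STOP_CODONS:
            bases[3 * k], bases[3 * k + 1] = bases[3 * k + 1], bases[3 * k]
    return "".join(bases) + (incomplete if incomplete else "TAA")


def _build_trna(rng: np.random.Generator, plan: TrnaPlan, anticodon: str,
                max_tries: int = 100) -> tuple[str, CloverleafStructure,
                                               list[tuple[str, tuple[int, int]]]]:
    """Sequence + structure with planted mismatches, verified recoverable.

    The candidate is refolded with :func:`fold_cloverleaf`; random bases
    are redrawn until the planted structure is recovered exactly, which
    guards against accidental alternative folds.
    """
    n = plan.length
    aa = plan.aa_len
    d0 = aa + plan.spacer_a
    d1 = d0 + (2 * plan.dhu_len + plan.dhu_loop if plan.dhu_len else plan.dhu_loop)
    a0 = d1 + plan.spacer_b
    loop0 = a0 + plan.ac_len
    a1 = loop0 + 7 + plan.ac_len
    t0 = a1 + plan.var_len
    t1 = t0 + 2 * plan.tpsic_len + plan.tpsic_loop
    assert t1 + aa == n

    stems = {
        "AA": [(k, n - 1 - k) for k in range(aa)],
        "DHU": [(d0 + k, d1 - 1 - k) for k in range(plan.dhu_len)],
        "AC": [(loop0 - 1 - k, loop0 + 7 + k) for k in range(plan.ac_len)],
        "TPSIC": [(t0 + k, t1 - 1 - k) for k in range(plan.tpsic_len)],
    }
    planted = CloverleafStructure(
        aa_stem=stems["AA"], dhu_stem=stems["DHU"],
        ac_stem=sorted(stems["AC"]), tpsic_stem=stems["TPSIC"],
        dhu_loop=((d0 + plan.dhu_len, d1 - plan.dhu_len)
                  if plan.dhu_len else (d0, d1)),
        ac_loop=(loop0, loop0 + 7),
        tpsic_loop=(t0 + plan.tpsic_len, t1 - plan.tpsic_len),
        variable_loop=(a1, t0),
        anticodon_positions=(loop0 + 2, loop0 + 3, loop0 + 4),
        degenerate=plan.dhu_len == 0)

    mismatch_at = {}
    for arm, idx in plan.mismatches:
        if idx >= len(stems[arm]):
            raise SimulationSpecError(f"mismatch index {idx} outside {arm} stem")
        mismatch_at[stems[arm][idx]] = _MISMATCH_PAIRS[
            rng.integers(len(_MISMATCH_PAIRS))]

    for _ in range(max_tries):
        seq = [""] * n
        for arm, pairs in stems.items():
            for (i, j) in pairs:
                if (i, j) in mismatch_at:
                    seq[i], seq[j] = mismatch_at[(i, j)]
                else:
                    b = "ATGC"[rng.choice(4, p=[0.35, 0.35, 0.15, 0.15])]
                    seq[i], seq[j] = b, _WC[b]
        # unpaired positions use {A, C}, which cannot pair with each other,
        # so loops and spacers never seed an accidental stem among themselves
        for k in range(n):
            if not seq[k]:
                seq[k] = "AC"[rng.random() > 0.7]
        seq[loop0 + 2: loop0 + 5] = list(anticodon)
        # guard the AA-stem inward extension against pairing with the
        # adjacent (planted) TΨC stem base
        partner = seq[n - 1 - aa]
        seq[aa] = {"T": "C", "U": "C", "G": "A"}.get(partner, seq[aa])
        s = "".join(seq)
        if s.count(anticodon) != 1:
            continue
        folded = fold_cloverleaf(s, anticodon)
        if folded is not None and sorted(folded.all_pairs()) == sorted(planted.all_pairs()):
            mismatch_list = [(arm, stems[arm][idx]) for arm, idx in plan.mismatches]
            return s, planted, mismatch_list
    raise SimulationSpecError(
        f"could not realise a recoverable tRNA for plan {plan}")


# ---------------------------------------------------------------------------
# whole-genome simulation
# ---------------------------------------------------------------------------

def _translate(cds: str) -> str:
    aas = []
    for k in range(len(cds) // 3):
        codon = cds[3 * k: 3 * k + 3]
        aas.append(GENETIC_CODE.get(codon, "X"))
    return "".join(aas)


def simulate_mitogenome(spec: SimulationSpec) -> tuple[Mitogenome, TruthRecord]:
    """Emit an annotated circular mitogenome and its ground truth.

    Deterministic for a fixed spec and seed.  Overlaps keep the upstream
    gene's bases; the special atp8/atp6 junction plants the ATGATAA
    overlap that serves as atp6's start and atp8's stop simultaneously.
    Other overlaps are only allowed where the downstream feature is an
    rRNA or the control region, so planted PCG/tRNA truths stay exact.
    """
    spec.validate()
    order = (apply_rearrangement(spec.gene_order, spec.events)
             if spec.events else spec.gene_order)
    junction = {(j.upstream, j.downstream): j for j in spec.spacer_plan}
    adjacency = {(order.order[i][0], order.order[i + 1][0] if i + 1 < len(order.order)
                  else order.order[0][0]) for i in range(len(order.order))}
    for key in junction:
        if key not in adjacency:
            raise SimulationSpecError(
                f"spacer plan names junction {key} absent from the gene order")

    comp = spec.composition_target
    sense: dict[str, str] = {}
    structures: dict[str, CloverleafStructure] = {}
    mismatches: dict[str, list[MismatchRecord]] = {}

    for name in PCG_NAMES:
        rng = _rng_for(spec.seed, name)
        sense[name] = _make_cds(rng, spec.per_gene_length[name], comp["PCG"],
                                spec.incomplete_stop_genes.get(name))
    for name in RRNA_NAMES:
        rng = _rng_for(spec.seed, name)
        sense[name] = _draw_bases(rng, spec.per_gene_length[name], comp["rRNA"])
    rng = _rng_for(spec.seed, CONTROL_NAME)
    sense[CONTROL_NAME] = _draw_bases(rng, spec.per_gene_length[CONTROL_NAME],
                                      comp["control"])
    for name in TRNA_NAMES:
        rng = _rng_for(spec.seed, name)
        seq, planted, mlist = _build_trna(rng, spec.trna_plans[name],
                                          TRNA_ANTICODONS[name])
        sense[name] = seq
        structures[name] = planted
        rna = seq.replace("T", "U")
        mismatches[name] = [
            MismatchRecord(trna=name, pair=(rna[i], rna[j]), arm=arm,
                           position=(i, j))
            for arm, (i, j) in mlist]

    special = junction.get(("atp8", "atp6"))
    if special and special.signed_length == -7 and special.motif == "ATGATAA":
        a8 = list(sense["atp8"])
        a8[-7:] = list("ATGATAA")
        if "".join(a8[-9:-6]) in STOP_CODONS:   # keep frame stop-free
            a8[-9] = "A"
        sense["atp8"] = "".join(a8)
        a6 = list(sense["atp6"])
        a6[0:7] = list("ATGATAA")
        sense["atp6"] = "".join(a6)
    elif special and special.signed_length < 0:
        raise SimulationSpecError(
            "atp8/atp6 overlap requires the ATGATAA motif construction")

    # --- assembly -----------------------------------------------------------
    spacer_rng = _rng_for(spec.seed, "@spacer")
    parts: list[str] = []
    cursor = 0
    features: list[GeneFeature] = []
    names = [n for n, _ in order.order]
    for i, (name, sign) in enumerate(order.order):
        genomic = sense[name] if sign > 0 else reverse_complement(sense[name])
        skip = 0
        if i > 0:
            j = junction.get((names[i - 1], name))
            signed = j.signed_length if j else 0
            if signed > 0:
                gap = list(_draw_bases(spacer_rng, signed, comp["spacer"]))
                if j.motif:
                    motif = (j.motif if j.motif_strand == "J"
                             else reverse_complement(j.motif))
                    gap[:len(motif)] = list(motif)
                parts.append("".join(gap))
                cursor += signed
            elif signed < 0:
                skip = -signed
                down_class = ("control" if name == CONTROL_NAME
                              else "rRNA" if name in RRNA_NAMES
                              else "PCG" if name in PCG_NAMES else "tRNA")
                if down_class not in ("rRNA", "control") and name != "atp6":
                    raise SimulationSpecError(
                        f"overlap into {name}: downstream must be rRNA/control")
        start = cursor - skip
        parts.append(genomic[skip:])
        cursor += len(genomic) - skip
        fclass = ("PCG" if name in PCG_NAMES else
                  "rRNA" if name in RRNA_NAMES else
                  "control" if name == CONTROL_NAME else "tRNA")
        features.append(GeneFeature(
            name=name, feature_class=fclass, strand="J" if sign > 0 else "N",
            intervals=[(start, start + len(genomic))],
            anticodon=(TRNA_ANTICODONS[name].replace("T", "U")
                       if fclass == "tRNA" else None)))
    wrap = junction.get((names[-1], names[0]))
    if wrap:
        if wrap.signed_length < 0:
            raise SimulationSpecError("overlap across the origin is not supported")
        parts.append(_draw_bases(spacer_rng, wrap.signed_length, comp["spacer"]))
        cursor += wrap.signed_length

    genome = Mitogenome(accession=spec.accession, organism=spec.organism,
                        sequence="".join(parts), topology="circular",
                        features=sorted(features, key=lambda f: f.start))
    genome.validate()

    # --- ground truth -------------------------------------------------------
    realized = {f.name: f.extract(genome.sequence) for f in genome.features}
    n_junc = len(order.order)
    gaps = [j for j in spec.spacer_plan if j.signed_length > 0]
    overs = [j for j in spec.spacer_plan if j.signed_length < 0]
    longest = max(gaps, key=lambda j: j.signed_length, default=None)
    spacer_summary = {
        "total_intergenic_bp": sum(j.signed_length for j in gaps),
        "n_gap_locations": len(gaps),
        "longest_gap": longest.signed_length if longest else 0,
        "longest_gap_junction": ((longest.upstream, longest.downstream)
                                 if longest else None),
        "n_overlaps": len(overs),
        "overlap_length_range": ((min(-j.signed_length for j in overs),
                                  max(-j.signed_length for j in overs))
                                 if overs else (0, 0)),
        "n_abutting": n_junc - len(gaps) - len(overs),
    }

    def counts_of(s: str) -> dict[str, int]:
        return {b: s.count(b) for b in "ACGT"}

    pcg_concat = "".join(realized[n] for n in PCG_NAMES)
    region_counts = {
        "whole": counts_of(genome.sequence),
        "PCGs": counts_of(pcg_concat),
        "rrnL": counts_of(realized["rrnL"]),
        "rrnS": counts_of(realized["rrnS"]),
        "tRNAs": counts_of("".join(realized[n] for n in TRNA_NAMES
                                   if n in realized)),
    }
    codon_counts: dict[str, int] = {}
    stop_counts: dict[str, int] = {}
    for n in PCG_NAMES:
        cds = realized[n]
        for k in range(len(cds) // 3):
            codon = cds[3 * k: 3 * k + 3]
            target = stop_counts if codon in STOP_CODONS else codon_counts
            target[codon] = target.get(codon, 0) + 1

    truth = TruthRecord(
        order=GeneOrderPerm(order=list(order.order), missing=set(order.missing)),
        events=list(spec.events),
        spacer_summary=spacer_summary,
        trna_structures=structures,
        trna_mismatches=mismatches,
        gene_sequences=dict(sense),
        peptides={n: _translate(sense[n][:len(sense[n]) - len(sense[n]) % 3])
                  for n in PCG_NAMES},
        region_base_counts=region_counts,
        pcg_codon_counts=codon_counts,
        pcg_stop_counts=stop_counts)
    return genome, truth


# ---------------------------------------------------------------------------
# codon-pair evolution
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    bases = []
    pct = DEFAULT_COMPOSITION["PCG"]
    while len(bases) < 3 * n_codons:
        codon = _draw_bases(rng, 3, pct)
        if codon not in STOP_CODONS:
            bases.append(codon)
    return "".join(bases)


def simulate_codon_pair(n_codons: int, omega: float, t: float, kappa: float,
                        seed: int) -> tuple[str, str, int, int]:
    """Evolve a descendant CDS from a random ancestor.

    Each nucleotide site receives a Poisson(t) number of proposed
    substitutions; a proposal is a transition with probability
    kappa/(kappa+2), otherwise one of the two transversions.  Proposals
    creating a stop codon are rejected; nonsynonymous proposals are
    accepted with probability min(1, omega) (for omega > 1 the bias is
    applied to synonymous proposals instead).  Returns
    (cds1, cds2, true_Sd, true_Nd) where the truth counts accepted
    events (multiple hits at one site are separate events).
    """
    if n_codons <= 0:
        raise ValueError("n_codons must be positive")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    rng = np.random.default_rng([seed, 1_000_003])
    cds1 = _random_cds(rng, n_codons)
    cur = list(cds1)
    true_sd = true_nd = 0
    p_ts = kappa / (kappa + 2.0)
    n_events = rng.poisson(t, size=3 * n_codons)
    _TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
    _TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
    for site in np.nonzero(n_events)[0]:
        for _ in range(n_events[site]):
            base = cur[site]
            if rng.random() < p_ts:
                new = _TRANSITION[base]
            else:
                new = _TRANSVERSIONS[base][rng.integers(2)]
            cpos = site - site % 3
            old_codon = "".join(cur[cpos:cpos + 3])
            new_codon = (old_codon[:site - cpos] + new
                         + old_codon[site - cpos + 1:])
            if new_codon in STOP_CODONS:
                continue
            synonymous = GENETIC_CODE[new_codon] == GENETIC_CODE[old_codon]
            if omega <= 1.0:
                accept = synonymous or rng.random() < omega
            else:
                accept = (not synonymous) or rng.random() < 1.0 / omega
            if accept:
                cur[site] = new
                if synonymous:
                    true_sd += 1
                else:
                    true_nd += 1
    return cds1, "".join(cur), true_sd, true_nd


# ---------------------------------------------------------------------------
# K80 alignment simulation (saturation screening support)
# ---------------------------------------------------------------------------

def simulate_k80_alignment(n_taxa: int, n_sites: int, t: float, kappa: float,
                           seed: int) -> dict[str, str]:
    """Star-tree alignment under K80 with a spread of tip depths.

    Tip i sits at depth (t/2) * (0.6 + 0.8*i/(n_taxa-1)), so pairwise
    divergences span roughly [0.6t, 1.4t] and the observed-vs-corrected
    distance regression has leverage.
    """
    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    rng = np.random.default_rng([seed, 2_000_003])
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    root = rng.integers(4, size=n_sites)          # order A,G,C,T (purines first)
    bases = np.asarray(list("AGCT"))
    out: dict[str, str] = {}
    for i in range(n_taxa):
        frac = 0.0 if n_taxa == 1 else i / (n_taxa - 1)
        d = (t / 2.0) * (0.6 + 0.8 * frac)
        e1 = np.exp(-4.0 * beta * d)
        e2 = np.exp(-2.0 * (alpha + beta) * d)
        p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
        p_tv = 0.25 - 0.25 * e1               # per transversion target
        u = rng.random(n_sites)
        tip = root.copy()
        # with base order A,G,C,T a transition flips within purines
        # (0<->1) or pyrimidines (2<->3); (root+2)%4 and its ^1 partner
        # are the two transversion targets
        ts_partner = root ^ 1
        tv1 = (root + 2) % 4
        tv2 = tv1 ^ 1
        tip = np.where(u < p_ts, ts_partner, tip)
        sel_tv1 = (u >= p_ts) & (u < p_ts + p_tv)
        sel_tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
        tip = np.where(sel_tv1, tv1, tip)
        tip = np.where(sel_tv2, tv2, tip)
        out[f"taxon{i}"] = "".join(bases[tip])
    return out
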