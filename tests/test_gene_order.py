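"""Gene-order extraction, rearrangement classification and breakpoints."""

import random

import pytest

from mitocomp.gene_order import (GeneOrderError, GeneOrderPerm,
                                 RearrangementEvent, ancestral_insect_order,
                                 apply_rearrangement, breakpoint_distance,
                                 compare_to_ancestor, extract_gene_order)


def brute_force_breakpoints(a, b):
    """Naive adjacency-set oracle, doubled-list enumeration."""
    def adjacencies(order):
        ring = list(order) + [order[0]]
        out = set()
        for (x, sx), (y, sy) in zip(ring, ring[1:]):
            out.add(((x, sx), (y, sy)))
        return out

    def shared(adj, other):
        (x, sx), (y, sy) = adj
        return adj in other or ((y, -sy), (x, -sx)) in other

    adj_a, adj_b = adjacencies(a.order), adjacencies(b.order)
    return sum(1 for adj in adj_a if not shared(adj, adj_b))


def random_signed_perm(rng, n):
    genes = [f"g{i}" for i in range(n)]
    rng.shuffle(genes)
    return GeneOrderPerm(order=[(g, rng.choice([1, -1])) for g in genes])


def test_ancestral_order_constants():
    anc = ancestral_insect_order()
    assert len(anc.order) == 38                  # 37 genes + control region
    assert anc.sign_of("trnW") == 1
    assert anc.sign_of("trnC") == -1 and anc.sign_of("trnY") == -1
    assert [n for n, _ in anc.order[:4]] == ["trnI", "trnQ", "trnM", "nad2"]


def test_rotation_invariance_of_ancestor():
    anc = ancestral_insect_order()
    rotated = GeneOrderPerm(order=anc.order[10:] + anc.order[:10])
    assert breakpoint_distance(anc, rotated) == 0
    rep = compare_to_ancestor(rotated, anc)
    assert rep.breakpoint_count == 0
    assert all(v == "in_place" for v in rep.status.values())


def test_extract_recovers_simulated_order(genome, truth):
    observed = extract_gene_order(genome)
    assert observed.order == truth.order.order


def test_extract_lists_missing_genes(genome):
    import copy
    g = copy.deepcopy(genome)
    drop = {"trnI", "trnQ", "trnM"}
    g.features = [f for f in g.features if f.name not in drop]
    observed = extract_gene_order(g)
    assert drop <= observed.missing
    rep = compare_to_ancestor(observed)
    assert all(v == "in_place" for v in rep.status.values())


def test_apply_rearrangement_identity_and_involution():
    anc = ancestral_insect_order()
    assert apply_rearrangement(anc, []).order == anc.order
    ev = [RearrangementEvent("inversion", "trnW")] * 2
    assert apply_rearrangement(anc, ev).order == anc.order


def test_apply_rearrangement_validates_events():
    anc = ancestral_insect_order()
    with pytest.raises(GeneOrderError):
        apply_rearrangement(anc, [RearrangementEvent("translocation", "nope",
                                                     before="trnI")])
    with pytest.raises(GeneOrderError):
        apply_rearrangement(anc, [RearrangementEvent("translocation", "trnC",
                                                     before="trnC")])


def test_trnc_trny_rearrangement_scenario():
    """trnC translocated and trnY remote-inverted to upstream of trnI-nad2,
    the arrangement observed in a cimbicid sawfly."""
    anc = ancestral_insect_order()
    ev = [RearrangementEvent("translocation", "trnC", before="trnI"),
          RearrangementEvent("remote_inversion", "trnY", before="trnC")]
    new = apply_rearrangement(anc, ev)
    assert new.order[:3] == [("trnY", 1), ("trnC", -1), ("trnI", 1)]
    rep = compare_to_ancestor(new, anc)
    moved = {g: s for g, s in rep.status.items() if s != "in_place"}
    assert moved == {"trnC": "translocated", "trnY": "remote_inverted"}
    assert rep.breakpoint_count >= 2        # at least two events' worth


def test_identity_comparison():
    anc = ancestral_insect_order()
    rep = compare_to_ancestor(anc, anc)
    assert rep.breakpoint_count == 0
    assert rep.narrative == []
    assert len(rep.conserved_blocks) == 1


def test_unknown_gene_raises():
    anc = ancestral_insect_order()
    odd = GeneOrderPerm(order=[("mystery", 1)] + anc.order[:5])
    with pytest.raises(GeneOrderError):
        compare_to_ancestor(odd, anc)


def _positions(order):
    return {n: i for i, (n, _) in enumerate(order)}


def _circular_gap(i, j, n):
    d = abs(i - j)
    return min(d, n - d)


def enumerate_identifiable_single_events(min_gap=3):
    """All single events whose minimal explanation is unambiguous: moves
    of at least ``min_gap`` circular positions, plus all in-place
    inversions."""
    anc = ancestral_insect_order()
    pos = _positions(anc.order)
    n = len(anc.order)
    events = []
    for gene, _ in anc.order:
        events.append(RearrangementEvent("inversion", gene))
        for dest, _ in anc.order:
            if dest == gene:
                continue
            if _circular_gap(pos[gene], pos[dest], n) < min_gap:
                continue
            events.append(RearrangementEvent("translocation", gene, before=dest))
            events.append(RearrangementEvent("remote_inversion", gene, before=dest))
    return events


_KIND_FROM_STATUS = {"translocated": "translocation",
                     "inverted_in_place": "inversion",
                     "remote_inverted": "remote_inversion"}


def recovered_events(report):
    return {(_KIND_FROM_STATUS[s], g)
            for g, s in report.status.items() if s != "in_place"}


def test_single_event_round_trip_exhaustive():
    """Every identifiable single event is recovered exactly."""
    anc = ancestral_insect_order()
    for ev in enumerate_identifiable_single_events():
        new = apply_rearrangement(anc, [ev])
        rep = compare_to_ancestor(new, anc)
        assert recovered_events(rep) == {(ev.kind, ev.gene)}, ev


def test_disjoint_event_pair_round_trip():
    """Seeded disjoint event pairs (all loci well separated) recovered."""
    anc = ancestral_insect_order()
    pos = _positions(anc.order)
    n = len(anc.order)
    rng = random.Random(7)
    names = [g for g, _ in anc.order]
    done = 0
    while done < 100:
        kinds = [rng.choice(["translocation", "remote_inversion", "inversion"])
                 for _ in range(2)]
        genes = rng.sample(names, 2)
        dests = rng.sample(names, 2)
        loci = []
        evs = []
        for kind, gene, dest in zip(kinds, genes, dests):
            loci.append(pos[gene])
            if kind == "inversion":
                evs.append(RearrangementEvent(kind, gene))
            else:
                if dest in genes:
                    break
                loci.append(pos[dest])
                evs.append(RearrangementEvent(kind, gene, before=dest))
        else:
            if any(_circular_gap(a, b, n) < 3
                   for i, a in enumerate(loci) for b in loci[i + 1:]):
                continue
            new = apply_rearrangement(anc, evs)
            rep = compare_to_ancestor(new, anc)
            assert recovered_events(rep) == {(e.kind, e.gene) for e in evs}, evs
            done += 1


def test_breakpoint_distance_identity_and_symmetry():
    rng = random.Random(3)
    a = random_signed_perm(rng, 10)
    b = GeneOrderPerm(order=[(g, s) for g, s in a.order])
    assert breakpoint_distance(a, b) == 0
    c = random_signed_perm(rng, 10)      # same gene universe g0..g9
    assert breakpoint_distance(a, c) == breakpoint_distance(c, a)


def test_full_reversal_has_zero_breakpoints():
    """Mirroring a circular order with sign flips keeps every adjacency
    under the signed-adjacency convention."""
    anc = ancestral_insect_order()
    mirrored = GeneOrderPerm(order=[(g, -s) for g, s in reversed(anc.order)])
    assert breakpoint_distance(anc, mirrored) == 0


def test_breakpoint_distance_matches_oracle_on_random_instances():
    rng = random.Random(99)
    for _ in range(100):
        a = random_signed_perm(rng, 10)
        b = random_signed_perm(rng, 10)
        assert breakpoint_distance(a, b) == brute_force_breakpoints(a, b)


def test_gene_set_mismatch_raises():
    rng = random.Random(1)
    a = random_signed_perm(rng, 6)
    b = GeneOrderPerm(order=[("x", 1), ("y", 1)])
    with pytest.raises(GeneOrderError):
        breakpoint_distance(a, b)
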