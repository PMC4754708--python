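"""Cloverleaf parsing/folding, mismatch census, spacers and motifs."""

import pytest

from mitocomp.genome_io import CONTROL_NAME
from mitocomp.trna_spacers import (StructureParseError, count_mismatches,
                                   find_motif, fold_cloverleaf,
                                   parse_structure_string, spacer_overlap_scan,
                                   to_dot_bracket)

# a compact 3-hairpin cloverleaf dot-bracket (toy geometry)
TOY_SEQ = "GGGGAAACCCCTTTTAAAGGGGTTTTAAACCCCAAAATTTTGGGAAAACCCC"


def make_toy_structure():
    # closing stem 4, three hairpins of 4/4/4 pairs
    db = list("." * len(TOY_SEQ))
    pairs = []
    # closing stem
    for k in range(4):
        pairs.append((k, len(TOY_SEQ) - 1 - k))
    # three hairpins at fixed offsets (stem 3 + loop 4)
    for start in (5, 20, 35):
        for k in range(3):
            pairs.append((start + k, start + 9 - k))
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return "".join(db)


def test_parse_structure_assigns_four_arms():
    db = make_toy_structure()
    s = parse_structure_string(TOY_SEQ, db)
    assert len(s.aa_stem) == 4
    assert len(s.dhu_stem) == len(s.ac_stem) == len(s.tpsic_stem) == 3
    assert not s.degenerate
    assert s.ac_loop is not None and s.anticodon_positions is not None


def test_parse_round_trip_to_dot_bracket():
    db = make_toy_structure()
    s = parse_structure_string(TOY_SEQ, db)
    assert to_dot_bracket(s, len(TOY_SEQ)) == db


def test_parse_two_hairpins_is_degenerate():
    db = list("." * 40)
    for k in range(3):
        db[k], db[39 - k] = "(", ")"
    for start in (6, 22):
        for k in range(3):
            db[start + k], db[start + 9 - k] = "(", ")"
    s = parse_structure_string("A" * 40, "".join(db))
    assert s.degenerate and s.dhu_stem == []
    assert len(s.ac_stem) == 3 and len(s.tpsic_stem) == 3


def test_parse_rejects_unbalanced_brackets():
    with pytest.raises(StructureParseError):
        parse_structure_string("AAAA", "((..")
    with pytest.raises(StructureParseError):
        parse_structure_string("AAAA", ".)..")


def test_fold_recovers_planted_structures(truth):
    """Every generated tRNA refolds to its planted cloverleaf, including
    the two D-arm-less ones."""
    from mitocomp.synthetic_data import TRNA_ANTICODONS
    for name, planted in truth.trna_structures.items():
        seq = truth.gene_sequences[name]
        folded = fold_cloverleaf(seq, TRNA_ANTICODONS[name])
        assert folded is not None, name
        assert sorted(folded.all_pairs()) == sorted(planted.all_pairs()), name
    assert truth.trna_structures["trnV"].degenerate
    assert truth.trna_structures["trnS1"].degenerate


def test_fold_keeps_planted_mismatch_pair(truth):
    """A planted non-canonical pair survives folding (stems are anchored
    by geometry, not by pairing quality alone)."""
    seq = truth.gene_sequences["trnA"]
    from mitocomp.synthetic_data import TRNA_ANTICODONS
    folded = fold_cloverleaf(seq, TRNA_ANTICODONS["trnA"])
    recs = count_mismatches(folded, seq, trna="trnA")
    planted = truth.trna_mismatches["trnA"]
    assert [(r.arm, r.position) for r in recs] == \
        [(r.arm, r.position) for r in planted]


def test_fold_requires_anticodon_present():
    with pytest.raises(ValueError):
        fold_cloverleaf("ACGT" * 16, "TTT")  # TTT absent from ACGT repeats


def test_fold_is_deterministic(truth):
    from mitocomp.synthetic_data import TRNA_ANTICODONS
    seq = truth.gene_sequences["trnK"]
    f1 = fold_cloverleaf(seq, TRNA_ANTICODONS["trnK"])
    f2 = fold_cloverleaf(seq, TRNA_ANTICODONS["trnK"])
    assert f1.all_pairs() == f2.all_pairs()


def test_count_mismatches_examples():
    from mitocomp.trna_spacers import CloverleafStructure
    s = CloverleafStructure(aa_stem=[(0, 10), (1, 9), (2, 8), (3, 7)],
                            dhu_stem=[], ac_stem=[], tpsic_stem=[])
    seq = "GGGGAAACCCC"
    assert count_mismatches(s, seq) == []            # all G-C
    seq_uu = "TGGGAAACCCT"                           # outer pair U-U
    recs = count_mismatches(s, seq_uu)
    assert len(recs) == 1 and recs[0].pair == ("U", "U")
    seq_gu = "TGGGAAACCCG"                           # outer pair U-G wobble
    assert count_mismatches(s, seq_gu) == []


def test_planted_mismatch_counts_match_truth(truth):
    for name, planted in truth.trna_mismatches.items():
        struct = truth.trna_structures[name]
        recs = count_mismatches(struct, truth.gene_sequences[name], trna=name)
        assert len(recs) == len(planted), name


def test_spacer_summary_equals_generator_truth(genome, truth):
    _, summary = spacer_overlap_scan(genome)
    assert summary == truth.spacer_summary


def test_census_conservation_law(genome):
    """Sum of gene lengths + gaps - overlaps equals the genome length."""
    records, _ = spacer_overlap_scan(genome)
    gene_total = sum(f.length for f in genome.features)
    gaps = sum(r.signed_length for r in records if r.signed_length > 0)
    overlaps = -sum(r.signed_length for r in records if r.signed_length < 0)
    assert gene_total + gaps - overlaps == genome.length


def test_abutting_junction_record():
    from mitocomp.genome_io import GeneFeature, Mitogenome
    g = Mitogenome(accession="X", organism="x", sequence="ACGTACGTAC",
                   topology="linear-sequenced-region", features=[
                       GeneFeature("trnA", "tRNA", "J", [(0, 5)]),
                       GeneFeature("trnC", "tRNA", "J", [(5, 10)])])
    records, summary = spacer_overlap_scan(g)
    assert len(records) == 1 and records[0].signed_length == 0
    assert summary["n_abutting"] == 1


def test_atp8_atp6_overlap_motif(genome):
    records, _ = spacer_overlap_scan(genome)
    rec = next(r for r in records
               if (r.upstream, r.downstream) == ("atp8", "atp6"))
    assert rec.signed_length == -7
    assert rec.sequence == ""                 # overlap: no gap sequence
    hits = find_motif(records, "ATGATAA", where="overlaps")
    assert any(h["upstream"] == "atp8" for h in hits)


def test_nad4_nad4l_motif_on_minus_strand(genome):
    records, _ = spacer_overlap_scan(genome)
    hits = find_motif(records, "ATTATAA", where="gaps")
    hit = next(h for h in hits if h["upstream"] == "nad4")
    assert hit["orientation"] == "N"          # motif reads on the N strand


def test_motif_absent_returns_empty(genome):
    records, _ = spacer_overlap_scan(genome)
    assert find_motif(records, "GGGCCCGGGCCC") == []


def test_control_region_flanks_are_junctions(genome):
    records, _ = spacer_overlap_scan(genome)
    names = {r.upstream for r in records} | {r.downstream for r in records}
    assert CONTROL_NAME in names
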