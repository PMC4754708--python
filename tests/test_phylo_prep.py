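"""Supermatrix assembly, codon-position splitting and saturation scan."""

import pytest

from mitocomp.phylo_prep import (AlignedPartition, MatrixError, build_matrix,
                                 export_matrix, import_nexus, saturation_scan,
                                 split_codon_positions, translate_alignment)
from mitocomp.synthetic_data import simulate_k80_alignment


def toy_gene(name, rows):
    return AlignedPartition(name=name, rows=rows, kind="nt", source_gene=name)


@pytest.fixture()
def toy_partitions():
    """Three 'genes' (two coding, one rRNA-like) over three taxa."""
    g1 = toy_gene("gene1", {"taxA": "ATAGGGTTT", "taxB": "ATAGGATTC",
                            "taxC": "ATGGGATTT"})
    g2 = toy_gene("gene2", {"taxA": "TTAATT", "taxB": "TTAATC"})  # taxC absent
    rna = AlignedPartition(name="rrnL", kind="rRNA",
                           rows={"taxA": "AAGGTT", "taxB": "AAGGTA",
                                 "taxC": "AAGCTT"})
    parts = []
    for g in (g1, g2):
        parts.extend(split_codon_positions(g))
        parts.append(translate_alignment(g))
    parts.append(rna)
    return parts


def test_split_codon_positions_and_reinterleave():
    g = toy_gene("g", {"t1": "ABCDEFGHI"})
    p1, p2, p3 = split_codon_positions(g)
    assert p1.rows["t1"] == "ADG"
    assert p2.rows["t1"] == "BEH"
    assert p3.rows["t1"] == "CFI"
    back = "".join("".join(t) for t in
                   zip(p1.rows["t1"], p2.rows["t1"], p3.rows["t1"]))
    assert back == "ABCDEFGHI"


def test_split_requires_codon_multiple():
    with pytest.raises(MatrixError):
        split_codon_positions(toy_gene("g", {"t": "ABCD"}))


def test_translate_alignment_table5_and_gaps():
    g = toy_gene("g", {"t": "ATAGGG", "u": "---GGN"})
    aa = translate_alignment(g)
    assert aa.rows["t"] == "MG"       # ATA is Met in the invertebrate code
    assert aa.rows["u"] == "-X"


def test_p123_is_three_times_aa(toy_partitions):
    p123 = build_matrix(toy_partitions, "P123")
    aa = build_matrix(toy_partitions, "AA")
    assert p123.n_sites == 3 * aa.n_sites
    assert set(p123.taxa) == set(aa.taxa)


def test_charsets_tile_without_overlap(toy_partitions):
    for variant in ("P123", "P123R", "AA"):
        m = build_matrix(toy_partitions, variant)
        cursor = 0
        for _, (a, b) in m.charsets:
            assert a == cursor and b > a
            cursor = b
        assert cursor == m.n_sites


def test_p12t_exclusion_arithmetic(toy_partitions):
    full = build_matrix(toy_partitions, "P123R")
    excluded = ("gene1_p3", "gene2_p3", "rrnL")
    reduced = build_matrix(toy_partitions, "P12T", exclusions=excluded)
    width = {name: b - a for name, (a, b) in full.charsets}
    assert reduced.n_sites == full.n_sites - sum(width[n] for n in excluded)
    assert not ({n for n, _ in reduced.charsets} & set(excluded))


def test_missing_taxon_gap_filled(toy_partitions):
    m = build_matrix(toy_partitions, "P123")
    start, end = dict(m.charsets)["gene2_p1"]
    assert set(m.rows["taxC"][start:end]) == {"-"}


def test_empty_variant_raises(toy_partitions):
    all_names = [p.name for p in toy_partitions]
    with pytest.raises(MatrixError):
        build_matrix(toy_partitions, "P12T", exclusions=tuple(all_names))


def test_nexus_export_import_round_trip(toy_partitions, tmp_path):
    m = build_matrix(toy_partitions, "P123R")
    path = tmp_path / "matrix.nex"
    export_matrix(m, path, fmt="NEXUS")
    text = path.read_text()
    assert text.count("charset") == len(m.charsets)
    back = import_nexus(path)
    assert back.rows == m.rows
    assert back.charsets == m.charsets
    # byte-stable for fixed input
    path2 = tmp_path / "matrix2.nex"
    export_matrix(m, path2, fmt="NEXUS")
    assert path.read_bytes() == path2.read_bytes()


def test_raxml_codon_partition_lines(toy_partitions, tmp_path):
    m = build_matrix(toy_partitions, "P123")
    path = tmp_path / "matrix.phy"
    export_matrix(m, path, fmt="PHYLIP-relaxed",
                  partition_style="RAxML partition file")
    lines = (tmp_path / "matrix.phy.partitions").read_text().splitlines()
    assert len(lines) == len(m.charsets)
    start, end = dict(m.charsets)["gene1_p1"]
    assert f"DNA, gene1_p1 = {start + 1}-{end}\\3" in lines


def test_taxon_name_sanitisation(tmp_path):
    part = AlignedPartition(name="x", kind="rRNA",
                            rows={"bad name(1)": "ACGT", "ok_name": "ACGA",
                                  "third": "ACGG"})
    m = build_matrix([part], "P123R")
    mapping = export_matrix(m, tmp_path / "m.nex", fmt="NEXUS")
    assert mapping["bad name(1)"] == "bad_name_1_"


def test_saturation_identical_sequences_not_flagged():
    part = AlignedPartition(name="x", kind="nt",
                            rows={f"t{i}": "ACGTACGTAC" for i in range(4)})
    res = saturation_scan(part)
    assert res.slope is None
    assert not res.saturated_flag
    assert (res.pairs["p_distance"] == 0).all()


def test_saturation_needs_three_taxa():
    part = AlignedPartition(name="x", kind="nt",
                            rows={"a": "ACGT", "b": "ACGA"})
    with pytest.raises(MatrixError):
        saturation_scan(part)


def test_saturation_low_vs_high_divergence():
    """Slope near 1 at low divergence; much lower and flagged when the
    simulation approaches saturation."""
    low = saturation_scan(AlignedPartition(
        name="low", kind="nt", rows=simulate_k80_alignment(8, 2000, 0.05, 2.0, 1)))
    high = saturation_scan(AlignedPartition(
        name="high", kind="nt", rows=simulate_k80_alignment(8, 2000, 2.0, 2.0, 1)))
    assert 0.9 <= low.slope <= 1.0
    assert not low.saturated_flag
    assert high.slope < low.slope
    assert high.saturated_flag


def test_corrected_distance_dominates_p_distance():
    res = saturation_scan(AlignedPartition(
        name="m", kind="nt", rows=simulate_k80_alignment(6, 1500, 0.4, 2.0, 2)))
    ok = res.pairs.dropna(subset=["corrected_distance"])
    assert (ok["corrected_distance"] >= ok["p_distance"] - 1e-12).all()
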