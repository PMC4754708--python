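"""NG86 Ka/Ks: hand-worked values, oracle equivalence, and properties."""

import itertools
import random

import pytest

from mitocomp.evol_rates import (jukes_cantor, ng86, pathway_differences,
                                 rates_vs_reference, synonymous_site_fraction)
from mitocomp.synthetic_data import simulate_codon_pair

from ng86_oracle import oracle_ng86

ALL_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]


def test_identical_sequences():
    r = ng86("ATGTTTGGA", "ATGTTTGGA")
    assert r.Sd == r.Nd == 0
    assert r.Ka == 0.0 and r.Ks == 0.0
    assert r.ratio is None             # undefined, never printed as 0


def test_hand_worked_synonymous_example():
    """ATG|GGG|AAA vs ATG|GGA|AAA: one synonymous third-position change."""
    r = ng86("ATGGGGAAA", "ATGGGAAAA")
    assert r.S == pytest.approx(5 / 3, abs=1e-12)
    assert r.N == pytest.approx(22 / 3, abs=1e-12)
    assert (r.Sd, r.Nd) == (1.0, 0.0)
    assert r.pS == pytest.approx(0.6)
    assert r.Ks == pytest.approx(1.2070784343, abs=1e-9)
    assert r.Ka == 0.0


def test_hand_worked_nonsynonymous_example():
    r = ng86("AAA", "AAC")
    assert (r.Sd, r.Nd) == (0.0, 1.0)
    assert r.N == pytest.approx(8 / 3, abs=1e-12)
    assert r.pN == pytest.approx(0.375)
    assert r.Ka == pytest.approx(0.5198603854, abs=1e-9)
    assert r.Ks == 0.0
    assert r.ratio is None


def test_length_validation():
    with pytest.raises(ValueError):
        ng86("ATGATG", "ATG")
    with pytest.raises(ValueError):
        ng86("ATGA", "ATGA")


def test_site_counts_sum_to_three_per_codon():
    r = ng86("ATGTTTGGAAAA", "ATATTCGGCAAT")
    assert r.S + r.N == pytest.approx(3 * r.n_codons_compared, abs=1e-9)


def test_symmetry_exact():
    rng = random.Random(11)
    for _ in range(50):
        a = "".join(rng.choice(ALL_CODONS) for _ in range(4))
        b = "".join(rng.choice(ALL_CODONS) for _ in range(4))
        ra, rb = ng86(a, b), ng86(b, a)
        assert (ra.S, ra.N, ra.Sd, ra.Nd) == (rb.S, rb.N, rb.Sd, rb.Nd)


def test_oracle_equivalence_all_single_codon_pairs():
    """Exhaustive 64x64 sweep against the brute-force pathway oracle."""
    for ca in ALL_CODONS:
        for cb in ALL_CODONS:
            r = ng86(ca, cb)
            S, N, Sd, Nd, ks, ka = oracle_ng86(ca, cb)
            assert r.S == pytest.approx(S, abs=1e-12), (ca, cb)
            assert r.N == pytest.approx(N, abs=1e-12), (ca, cb)
            assert r.Sd == pytest.approx(Sd, abs=1e-12), (ca, cb)
            assert r.Nd == pytest.approx(Nd, abs=1e-12), (ca, cb)


def test_oracle_equivalence_random_two_codon_pairs():
    rng = random.Random(2024)
    for _ in range(300):
        a = rng.choice(ALL_CODONS) + rng.choice(ALL_CODONS)
        b = rng.choice(ALL_CODONS) + rng.choice(ALL_CODONS)
        r = ng86(a, b)
        S, N, Sd, Nd, ks, ka = oracle_ng86(a, b)
        assert (r.S, r.N) == pytest.approx((S, N), abs=1e-12)
        assert (r.Sd, r.Nd) == pytest.approx((Sd, Nd), abs=1e-12)
        # the JC map is ill-conditioned near saturation (log of ~0), so the
        # corrected distances are only compared where well defined
        if ks is not None and 1 - 4 * (Sd / S) / 3 > 1e-6:
            assert r.Ks == pytest.approx(ks, rel=1e-9)
        if ka is not None and 1 - 4 * (Nd / N) / 3 > 1e-6:
            assert r.Ka == pytest.approx(ka, rel=1e-9)


def test_jukes_cantor_monotone_and_saturating():
    grid = [i / 100 for i in range(0, 75, 5)]
    values = [jukes_cantor(p) for p in grid]
    assert all(v is not None for v in values)
    assert values == sorted(values)
    assert jukes_cantor(0.75) is None
    assert jukes_cantor(0.9) is None


def test_blocked_pathways_fall_back_to_site_split():
    # TGG (Trp) vs TAA is excluded (stop), but TAT<->TGG style pairs with
    # stop-crossing pathways must still return finite counts
    sd, nd = pathway_differences("TGG", "TTA")
    assert sd >= 0 and nd >= 0 and sd + nd == pytest.approx(2.0)


def test_ratio_monotone_in_omega_on_simulated_pairs():
    means = []
    for omega in (0.1, 0.5):
        ratios = []
        for seed in range(10):
            c1, c2, _, _ = simulate_codon_pair(800, omega, 0.3, 2.0, seed)
            r = ng86(c1, c2)
            assert r.ratio is not None and r.ratio < 1.0
            ratios.append(r.ratio)
        means.append(sum(ratios) / len(ratios))
    assert means[0] < means[1]


def test_rates_vs_reference_self_comparison_is_zero(genome):
    df = rates_vs_reference([genome], genome, genes=("cox1", "cob"))
    assert (df["Ka"] == 0).all() and (df["Ks"] == 0).all()
    assert df["ratio"].isna().all()
    assert "concatenated" in set(df["gene"])


def test_rates_vs_reference_flags_absent_gene(genome):
    import copy
    other = copy.deepcopy(genome)
    other.accession = "SYN2"
    other.features = [f for f in other.features if f.name != "cox2"]
    df = rates_vs_reference([other], genome, genes=("cox1", "cox2"))
    row = df[df["gene"] == "cox2"].iloc[0]
    assert row["flag"] == "absent"
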