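"""Independent brute-force NG86 oracle used only by the test suite.

Deliberately written against a different genetic-code source (Biopython's
table 5) and with naive enumeration, so it shares no code with the
implementation under test.
"""

import math
from functools import lru_cache
from itertools import permutations

from Bio.Seq import Seq


@lru_cache(maxsize=None)
def aa_of(codon: str) -> str:
    return str(Seq(codon).translate(table=5))


@lru_cache(maxsize=None)
def sites_of(codon: str) -> float:
    syn = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            if aa_of(mutant) != "*" and aa_of(mutant) == aa_of(codon):
                syn += 1.0 / 3.0
    return syn


@lru_cache(maxsize=None)
def diffs_of(ca: str, cb: str) -> tuple[float, float]:
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0
    syn_tot = nonsyn_tot = 0.0
    n_ok = 0
    for path in permutations(positions):
        cur = ca
        syn = nonsyn = 0
        ok = True
        for pos in path:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if aa_of(nxt) == "*":
                ok = False
                break
            if aa_of(nxt) == aa_of(cur):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            n_ok += 1
            syn_tot += syn
            nonsyn_tot += nonsyn
    if n_ok == 0:
        frac = (sites_of(ca) + sites_of(cb)) / 6.0
        return len(positions) * frac, len(positions) * (1.0 - frac)
    return syn_tot / n_ok, nonsyn_tot / n_ok


def oracle_ng86(seq_a: str, seq_b: str):
    """(S, N, Sd, Nd, Ks, Ka) from first principles."""
    S = N = Sd = Nd = 0.0
    for k in range(len(seq_a) // 3):
        ca, cb = seq_a[3 * k:3 * k + 3], seq_b[3 * k:3 * k + 3]
        if set(ca + cb) - set("ACGT"):
            continue
        if aa_of(ca) == "*" or aa_of(cb) == "*":
            continue
        S += (sites_of(ca) + sites_of(cb)) / 2.0
        N += 3.0 - (sites_of(ca) + sites_of(cb)) / 2.0
        sd, nd = diffs_of(ca, cb)
        Sd += sd
        Nd += nd

    def jc(p):
        arg = 1.0 - 4.0 * p / 3.0
        return None if arg <= 0 else -0.75 * math.log(arg)

    ks = jc(Sd / S) if S > 0 else None
    ka = jc(Nd / N) if N > 0 else None
    return S, N, Sd, Nd, ks, ka
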