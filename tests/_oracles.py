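"""Independent brute-force oracles used by the test suite.

Each oracle recomputes, by direct enumeration, a quantity that the package
computes by a smarter route (dynamic programming, the U-statistic
recurrence, linear scans), so agreement is a genuine two-route check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from compartmir.hybrid import get_energy_model, revcomp, transition_cost


def duplex_brute_force(mirna: str, window: str, model, max_loop: int,
                       forced: bool = False) -> float:
    """Exhaustive minimum over all legal duplex structures.

    Structures are antiparallel non-crossing pair sets with per-strand gaps
    <= max_loop between consecutive pairs; the energy of a structure is the
    sum of pair energies plus transition costs (shared cost definition).
    With ``forced`` only structures containing a full canonical seed helix
    (miRNA nt 2-7 against an exact seed-match offset) count.
    """
    em = get_energy_model(model)
    m = mirna.upper().replace("U", "T")
    t = window.upper().replace("U", "T")
    M, W = len(m), len(t)
    helices: list[frozenset] = []
    if forced:
        pattern = revcomp(m[1:7])
        for s in range(W - 5):
            if t[s : s + 6] == pattern:
                helices.append(frozenset((q, s + 6 - q) for q in range(1, 7)))
        if not helices:
            return float("inf")
    best = [0.0 if not forced else float("inf")]

    def rec(i0, j0, energy, pairs):
        first = i0 is None
        i_range = range(0 if first else i0 + 1, M)
        for i in i_range:
            if not first and i - i0 - 1 > max_loop:
                break
            js = (
                range(W - 1, -1, -1)
                if first
                else range(j0 - 1, max(-1, j0 - max_loop - 2), -1)
            )
            for j in js:
                pe = em.pair_energy(m[i], t[j])
                if not np.isfinite(pe):
                    continue
                if first:
                    cost = 0.0
                else:
                    stack = (
                        em.stack_energy(m[i0], t[j0], m[i], t[j])
                        if (i - i0 == 1 and j0 - j == 1)
                        else np.inf
                    )
                    cost = transition_cost(em, i - i0 - 1, j0 - j - 1, max_loop, stack)
                e2 = energy + pe + cost
                p2 = pairs | {(i, j)}
                if (not forced) or any(h <= p2 for h in helices):
                    best[0] = min(best[0], e2)
                rec(i, j, e2, p2)

    rec(None, None, 0.0, frozenset())
    return best[0]


def orf_brute_force(seq: str) -> tuple[int, int] | None:
    """All (ATG, in-frame stop) ORFs by direct scanning; longest wins,
    ties to the 5'-most start. 1-based inclusive coordinates."""
    seq = seq.upper().replace("U", "T")
    stops = {"TAA", "TAG", "TGA"}
    orfs = []
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        for p in range(i, len(seq) - 2, 3):
            if seq[p : p + 3] in stops:
                orfs.append((i + 1, p + 3))
                break
    if not orfs:
        return None
    return max(orfs, key=lambda o: (o[1] - o[0] + 1, -o[0]))


def naive_seed_scan(mirna_rna: str, utr_dna: str) -> list[int]:
    """1-based UTR start positions of the seed reverse complement."""
    pattern = revcomp(mirna_rna.replace("U", "T")[1:7])
    return [
        k + 1
        for k in range(len(utr_dna) - 5)
        if utr_dna[k : k + 6] == pattern
    ]


def wilcoxon_enumeration(a, b, alternative: str = "two-sided") -> float:
    """Exact rank-sum p by enumerating all label assignments (no ties)."""
    a, b = list(a), list(b)
    m, n = len(a), len(b)
    combined = sorted(a + b)
    assert len(set(combined)) == len(combined), "oracle requires no ties"

    def u_of(group_a):
        rest = list(combined)
        ga = sorted(group_a)
        return sum(1 for x in ga for y in combined if y not in ga and x > y)

    u_obs = sum(1 for x in a for y in b if x > y)
    us = []
    for idx in itertools.combinations(range(m + n), m):
        ga = {combined[i] for i in idx}
        gb = [v for v in combined if v not in ga]
        us.append(sum(1 for x in ga for y in gb if x > y))
    total = len(us)
    cdf = sum(u <= u_obs for u in us) / total
    sf = sum(u >= u_obs for u in us) / total
    if alternative == "less":
        return min(1.0, cdf)
    if alternative == "greater":
        return min(1.0, sf)
    return min(1.0, 2.0 * min(cdf, sf))
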