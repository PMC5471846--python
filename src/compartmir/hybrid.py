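"""Intermolecular miRNA:target duplex minimum free energy (MFE).

The hybridization model considers only intermolecular base pairs between a
miRNA (5'->3') and a target window (5'->3'). A duplex structure is a set of
pairs (i, j) — miRNA position i with target position j, both 0-based here —
that is antiparallel and non-crossing: i strictly increases while j strictly
decreases. Between consecutive pairs, bulges and internal loops of up to
``max_loop`` unpaired nucleotides per strand are allowed.

Two pluggable energy models are provided:

* :class:`SimpleEnergyModel` — a per-pair score (Watson-Crick and, outside a
  forced seed, G:U wobble) plus a linear per-nucleotide loop penalty. With
  the default scores a perfect n-pair Watson-Crick duplex has energy -n.
* :class:`NearestNeighborModel` — helix stability from a tabulated RNA
  nearest-neighbor stack table (approximate published parameters shipped
  below); unstacked consecutive pairs cost only the loop penalty.

``force_seed`` emulates constraining the seed helix (miRNA nt 2-7) to be
fully, canonically paired: the energy is minimized over exact seed-match
offsets in the window with the six seed pairs clamped, and ``+inf`` is
returned as a "no site" sentinel when the window carries no seed match.

Energies are comparative: absolute values are model-dependent and are used
throughout the package only to rank and filter sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .utr import normalize_sequence

__all__ = [
    "SimpleEnergyModel",
    "NearestNeighborModel",
    "get_energy_model",
    "hybrid_mfe",
    "forced_mfe_at",
    "seed_match_offsets",
    "NO_SITE",
]

NO_SITE = float("inf")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


def revcomp(seq: str) -> str:
    """Reverse complement in the DNA alphabet."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class SimpleEnergyModel:
    """Per-pair scores with a linear loop penalty (kcal/mol-like units)."""

    wc: float = -1.0
    gu: float = -0.5
    loop_per_nt: float = 0.5
    allow_gu: bool = True

    def pair_energy(self, a: str, b: str) -> float:
        if (a, b) in _WC:
            return self.wc
        if self.allow_gu and (a, b) in _GU:
            return self.gu
        return np.inf

    def stack_energy(self, a1: str, b1: str, a2: str, b2: str) -> float:
        return np.inf  # no stacking term; adjacency costs nothing extra


# Approximate RNA nearest-neighbor helix stacks, keyed "XY/ZW" for the
# stack 5'XY3' over 3'ZW5' with X:Z and Y:W the two base pairs, kcal/mol.
# The ten Watson-Crick stacks follow standard published values; a few
# common G:U-containing stacks are included and any stack missing from the
# table contributes no bonus.
_NN_STACKS_CANONICAL = {
    "AA/UU": -0.93,
    "AU/UA": -1.10,
    "UA/AU": -1.33,
    "CU/GA": -2.08,
    "CA/GU": -2.11,
    "GU/CA": -2.24,
    "GA/CU": -2.35,
    "CG/GC": -2.36,
    "GG/CC": -3.26,
    "GC/CG": -3.42,
    "AG/UU": -0.55,
    "GA/UU": -1.36,
    "CG/GU": -1.41,
    "CU/GG": -1.53,
    "GG/UC": -1.80,
    "GG/UU": -0.50,
}

_RNA_PAIRS = {"AU", "UA", "GC", "CG", "GU", "UG"}


def _build_stack_table() -> dict[str, float]:
    # closed under reading the duplex from the other end:
    # 5'XY3'/3'ZW5'  ==  5'WZ3'/3'YX5'
    table: dict[str, float] = {}
    for key, e in _NN_STACKS_CANONICAL.items():
        (x, y), (z, w) = key.split("/")
        assert x + z in _RNA_PAIRS and y + w in _RNA_PAIRS, key
        table[key] = e
        table[f"{w}{z}/{y}{x}"] = e
    return table


_NN_STACKS = _build_stack_table()


@dataclass(frozen=True)
class NearestNeighborModel:
    """Stack-table helix energies; pairs contribute through stacking only."""

    loop_per_nt: float = 0.5
    allow_gu: bool = True

    def pair_energy(self, a: str, b: str) -> float:
        if (a, b) in _WC or (self.allow_gu and (a, b) in _GU):
            return 0.0
        return np.inf

    def stack_energy(self, a1: str, b1: str, a2: str, b2: str) -> float:
        def rna(x: str) -> str:
            return "U" if x == "T" else x

        key = f"{rna(a1)}{rna(a2)}/{rna(b1)}{rna(b2)}"
        return _NN_STACKS.get(key, np.inf)


def get_energy_model(model) -> SimpleEnergyModel | NearestNeighborModel:
    if isinstance(model, (SimpleEnergyModel, NearestNeighborModel)):
        return model
    if model == "simple":
        return SimpleEnergyModel()
    if model == "nn":
        return NearestNeighborModel()
    raise ValueError(f"unknown energy model {model!r}")


def transition_cost(
    model,
    gap_i: int,
    gap_j: int,
    max_loop: int,
    stack: float = np.inf,
) -> float:
    """Cost of chaining two consecutive pairs.

    The loop path costs ``loop_per_nt`` per unpaired nucleotide on either
    strand; directly adjacent pairs (no gaps) may instead take the stacking
    bonus when the model provides one. This single definition is shared by
    the dynamic program and by the exhaustive oracle used in tests.
    """
    if gap_i < 0 or gap_j < 0 or gap_i > max_loop or gap_j > max_loop:
        return np.inf
    cost = model.loop_per_nt * (gap_i + gap_j)
    if gap_i == 0 and gap_j == 0:
        cost = min(cost, stack)
    return cost


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX[b] for b in seq], dtype=np.intp)


def _pair_table(model) -> np.ndarray:
    bases = "ACGT"
    return np.array(
        [[model.pair_energy(a, b) for b in bases] for a in bases], dtype=float
    )


def _pair_matrix(m: str, t: str, model) -> np.ndarray:
    table = _pair_table(model)
    return table[np.ix_(_encode(m), _encode(t))]


def _stack_matrix(m: str, t: str, model) -> np.ndarray | None:
    """ST[i, j] = stack bonus for transition (i-1, j+1) -> (i, j)."""
    if isinstance(model, SimpleEnergyModel):
        return None
    M, W = len(m), len(t)
    ST = np.full((M, W), np.inf)
    for i in range(1, M):
        for j in range(W - 1):
            ST[i, j] = model.stack_energy(m[i - 1], t[j + 1], m[i], t[j])
    return ST


def _dp(
    P: np.ndarray,
    ST: np.ndarray | None,
    c: float,
    L: int,
    start_cost: np.ndarray,
) -> np.ndarray:
    """Chain DP over pairs ordered by increasing i / decreasing j.

    ``E[i, j]`` is the best energy of a chain ending at pair (i, j); each
    chain begins with ``start_cost[i, j]`` (zero everywhere in free mode,
    anchor-transition costs in forced mode).
    """
    M, W = P.shape
    E = np.full((M, W), np.inf)
    R = np.full((M, W), np.inf)  # R[i', j] = min_g E[i', j+1+g] + c*g
    for i in range(M):
        cand = start_cost[i].copy()
        for d in range(1, min(L + 1, i) + 1):
            np.minimum(cand, R[i - d] + c * (d - 1), out=cand)
        if ST is not None and i > 0:
            prev = np.full(W, np.inf)
            prev[:-1] = E[i - 1][1:]
            np.minimum(cand, prev + ST[i], out=cand)
        E[i] = P[i] + cand
        row = np.full(W, np.inf)
        for g in range(min(L, W - 2) + 1):
            sh = np.full(W, np.inf)
            sh[: W - g - 1] = E[i][g + 1 :]
            np.minimum(row, sh + c * g, out=row)
        R[i] = row
    return E


def seed_match_offsets(mirna: str, window: str) -> list[int]:
    """0-based window offsets of exact (Watson-Crick) seed matches.

    The seed is miRNA nt 2-7; a match is an occurrence of its reverse
    complement in the window.
    """
    m = normalize_sequence(mirna)
    w = normalize_sequence(window)
    if len(m) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    pattern = revcomp(m[1:7])
    out = []
    start = 0
    while True:
        k = w.find(pattern, start)
        if k < 0:
            return out
        out.append(k)
        start = k + 1


def hybrid_mfe(
    mirna: str,
    window: str,
    model="simple",
    force_seed: bool = False,
    max_loop: int = 8,
) -> float:
    """Minimum free energy of the miRNA:window duplex.

    With ``force_seed`` the seed helix (miRNA nt 2-7, Watson-Crick only) is
    clamped at each exact seed-match offset and the best total over offsets
    is returned; ``NO_SITE`` (+inf) signals that the window holds no seed
    match. Without it, the unconstrained optimum over all duplex structures
    (including the empty one, energy 0) is returned.
    """
    em = get_energy_model(model)
    m = normalize_sequence(mirna)
    w = normalize_sequence(window)
    if len(w) < 6:
        raise ValueError("window shorter than the 6-nt seed")
    if force_seed:
        offsets = seed_match_offsets(m, w)
        if not offsets:
            return NO_SITE
        return min(forced_mfe_at(m, w, s, em, max_loop) for s in offsets)
    P = _pair_matrix(m, w, em)
    ST = _stack_matrix(m, w, em)
    start = np.zeros_like(P)
    E = _dp(P, ST, em.loop_per_nt, max_loop, start)
    return float(min(0.0, E.min()))


def forced_mfe_at(
    mirna: str,
    window: str,
    offset: int,
    model="simple",
    max_loop: int = 8,
) -> float:
    """MFE with the seed helix clamped at a given seed-match ``offset``.

    Seed pairs are miRNA nt 2..7 (0-based indices 1..6) against window
    positions offset+5..offset. The 3' arm (miRNA nt 8..end, window
    positions left of the seed) is optimized by the chain DP anchored on the
    nt-7 pair; nt 1 may pair right of the seed.
    """
    em = get_energy_model(model)
    m = normalize_sequence(mirna)
    w = normalize_sequence(window)
    s = offset
    if len(m) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    if not (0 <= s and s + 6 <= len(w)):
        raise ValueError("seed offset outside the window")
    if w[s : s + 6] != revcomp(m[1:7]):
        return NO_SITE
    M, W = len(m), len(w)
    c = em.loop_per_nt
    # seed helix: pairs (q, s + 6 - q) for q = 1..6, chained with zero gaps
    seed_pairs = [(q, s + 6 - q) for q in range(1, 7)]
    energy = sum(em.pair_energy(m[i], w[j]) for i, j in seed_pairs)
    for (i0, j0), (i1, j1) in zip(seed_pairs, seed_pairs[1:]):
        stack = em.stack_energy(m[i0], w[j0], m[i1], w[j1])
        energy += transition_cost(em, 0, 0, max_loop, stack)
    # 3' arm: miRNA indices >= 7 pairing window positions < s, chained
    # from the anchor pair (nt 7, s); solved on the subproblem only
    if M > 7 and s > 0:
        m3, w3 = m[7:], w[:s]
        P = _pair_matrix(m3, w3, em)
        ST = _stack_matrix(m3, w3, em)
        # gaps from the anchor: gap_i = arm row index, gap_j = s - 1 - j
        gi = np.arange(len(m3))[:, None].astype(float)
        gj = (s - 1 - np.arange(s))[None, :].astype(float)
        start = c * (gi + gj)
        start[(gi > max_loop) | np.broadcast_to(gj > max_loop, start.shape)] = np.inf
        stack0 = em.stack_energy(m[6], w[s], m[7], w[s - 1])
        start[0, s - 1] = min(start[0, s - 1], stack0)
        E = _dp(P, ST, c, max_loop, start)
        energy += min(0.0, float(E.min()))
    # 5' side: miRNA nt 1 may pair a window position right of the seed
    best5 = 0.0
    for j in range(s + 6, min(W, s + 7 + max_loop)):
        pe = em.pair_energy(m[0], w[j])
        if not np.isfinite(pe):
            continue
        gj = j - (s + 6)
        stack = em.stack_energy(m[0], w[j], m[1], w[s + 5]) if gj == 0 else np.inf
        best5 = min(best5, pe + transition_cost(em, 0, gj, max_loop, stack))
    return float(energy + best5)
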