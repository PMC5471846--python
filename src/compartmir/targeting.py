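"""Canonical miRNA seed sites in 3' UTRs and the miRNA->transcript target map.

A canonical site is an occurrence of the reverse complement of the miRNA
seed (nt 2-7) in a 3' UTR. Sites are classified TargetScan-style:

* ``6mer``    — the bare seed match;
* ``7mer-m8`` — the seed match extended by a Watson-Crick pair to miRNA nt 8
  (the UTR nucleotide immediately 5' of the match);
* ``7mer-A1`` — the seed match with an A in the UTR opposite miRNA nt 1
  (immediately 3' of the match);
* ``8mer``    — both.

Coordinates inside a 3' UTR are 1-based with position 1 the first nucleotide
after the stop codon; ``utr_start``/``utr_end`` span the 6-nt seed match and
``distance_to_stop = utr_start - 1`` counts the nucleotides strictly between
the stop codon and the site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .hybrid import forced_mfe_at, get_energy_model, revcomp
from .utr import TranscriptModel, normalize_sequence

__all__ = ["MiRNA", "TargetSite", "find_seed_sites", "target_map", "SITE_TYPES"]

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA; sequence stored 5'->3' in the RNA alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        if len(seq) < 8:
            raise ValueError(f"{self.id}: miRNA shorter than 8 nt")
        if set(seq) - set("ACGU"):
            raise ValueError(f"{self.id}: invalid miRNA alphabet")
        object.__setattr__(self, "sequence", seq)

    @property
    def seed(self) -> str:
        """Nucleotides 2-7, the canonical seed (RNA alphabet)."""
        return self.sequence[1:7]

    @property
    def dna(self) -> str:
        return self.sequence.replace("U", "T")


@dataclass
class TargetSite:
    """One seed site of one miRNA on one 3' UTR."""

    mirna_id: str
    transcript_id: str
    utr_start: int
    utr_end: int
    site_type: str
    distance_to_stop: int
    energy: float | None = None

    @property
    def abs_energy(self) -> float | None:
        return None if self.energy is None else abs(self.energy)


def find_seed_sites(m: MiRNA, utr3: str, transcript_id: str = "") -> list[TargetSite]:
    """All canonical seed sites of ``m`` in a 3' UTR (energies unset).

    Overlapping occurrences are all reported. Site types follow the module
    docstring; the m8 extension requires a Watson-Crick pair (no G:U).
    """
    utr = normalize_sequence(utr3)
    if len(utr) < 6:
        raise ValueError("3' UTR shorter than the 6-nt seed")
    mdna = m.dna
    pattern = revcomp(mdna[1:7])
    m8_partner = revcomp(mdna[7]) if len(mdna) >= 8 else None
    sites: list[TargetSite] = []
    start = 0
    while True:
        s = utr.find(pattern, start)
        if s < 0:
            break
        start = s + 1
        has_m8 = s >= 1 and m8_partner is not None and utr[s - 1] == m8_partner
        has_a1 = s + 6 < len(utr) and utr[s + 6] == "A"
        if has_m8 and has_a1:
            site_type = "8mer"
        elif has_m8:
            site_type = "7mer-m8"
        elif has_a1:
            site_type = "7mer-A1"
        else:
            site_type = "6mer"
        sites.append(
            TargetSite(
                mirna_id=m.id,
                transcript_id=transcript_id,
                utr_start=s + 1,
                utr_end=s + 6,
                site_type=site_type,
                distance_to_stop=s,
            )
        )
    return sites


def _site_window(utr: str, s0: int, window: int) -> tuple[str, int]:
    """Window of ~``window`` nt centered on the seed match at 0-based s0."""
    flank = max(0, (window - 6) // 2)
    lo = max(0, s0 - flank)
    hi = min(len(utr), s0 + 6 + flank)
    return utr[lo:hi], s0 - lo


def target_map(
    mirnas: Sequence[MiRNA],
    transcripts: Sequence[TranscriptModel],
    energy_cutoff: float = 0.0,
    model="simple",
    window: int = 60,
    max_loop: int = 8,
) -> pd.DataFrame:
    """Seed sites of every miRNA on every transcript 3' UTR, with energies.

    For each site the forced-seed MFE is computed on a local window centered
    on the match; sites with ``|energy| >= energy_cutoff`` are kept (the
    default 0 keeps every seed match). ``is_min_energy`` flags, per
    (miRNA, transcript) pair, the site with the lowest (most negative)
    energy; all sites are retained alongside it.

    Returns a DataFrame with columns mirna_id, transcript_id, utr_start,
    utr_end, site_type, energy, abs_energy, distance_to_stop, utr3_length,
    is_min_energy.
    """
    em = get_energy_model(model)
    rows: list[dict] = []
    for t in transcripts:
        utr = t.utr3
        if len(utr) < 6:
            continue
        for m in mirnas:
            for site in find_seed_sites(m, utr, transcript_id=t.id):
                wseq, rel = _site_window(utr, site.utr_start - 1, window)
                e = forced_mfe_at(m.dna, wseq, rel, em, max_loop)
                if not np.isfinite(e):
                    continue
                if abs(e) < energy_cutoff:
                    continue
                rows.append(
                    {
                        "mirna_id": m.id,
                        "transcript_id": t.id,
                        "utr_start": site.utr_start,
                        "utr_end": site.utr_end,
                        "site_type": site.site_type,
                        "energy": e,
                        "abs_energy": abs(e),
                        "distance_to_stop": site.distance_to_stop,
                        "utr3_length": len(utr),
                    }
                )
    columns = [
        "mirna_id",
        "transcript_id",
        "utr_start",
        "utr_end",
        "site_type",
        "energy",
        "abs_energy",
        "distance_to_stop",
        "utr3_length",
        "is_min_energy",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows)
    idx_min = df.groupby(["mirna_id", "transcript_id"])["energy"].idxmin()
    df["is_min_energy"] = False
    df.loc[idx_min, "is_min_energy"] = True
    return df[columns].reset_index(drop=True)
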