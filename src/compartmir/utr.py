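"""Transcript models: CDS calling, UTR extraction, and PAS-based 3' end correction.

Transcripts arrive as spliced, stranded (5'->3') nucleotide sequences. The
coding region is called as the longest ATG..stop open reading frame, the 5'
and 3' UTRs are the flanks, and annotated 3' ends can be corrected against
polyadenylation-site (PAS) sequencing evidence.

Coordinate conventions (used throughout the package):

* all sequence positions are 1-based and inclusive;
* within a 3' UTR, position 1 is the first nucleotide after the stop codon.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_DNA = frozenset("ACGT")

__all__ = [
    "TranscriptModel",
    "PASRecord",
    "normalize_sequence",
    "find_cds",
    "extract_utrs",
    "correct_utr3_end",
    "utr_length_summary",
]


def normalize_sequence(sequence: str) -> str:
    """Uppercase and convert to the DNA alphabet (U -> T).

    Raises ``ValueError`` listing any symbols outside A/C/G/T/U.
    """
    seq = sequence.upper().replace("U", "T")
    bad = sorted(set(seq) - _DNA)
    if bad:
        raise ValueError(f"invalid characters in sequence: {', '.join(bad)}")
    return seq


@dataclass
class TranscriptModel:
    """One transcript isoform: spliced sequence plus CDS coordinates.

    ``cds_start`` is the 1-based index of the A of the start ATG and
    ``cds_end`` the 1-based index of the last nucleotide of the stop codon.
    """

    id: str
    gene_id: str
    sequence: str
    cds_start: int
    cds_end: int
    strand: str = "+"
    utr3_corrected: bool = False

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        n = len(self.sequence)
        if not (1 <= self.cds_start < self.cds_end <= n):
            raise ValueError(
                f"{self.id}: CDS coordinates ({self.cds_start}, {self.cds_end}) "
                f"outside sequence of length {n}"
            )
        if (self.cds_end - self.cds_start + 1) % 3:
            raise ValueError(f"{self.id}: CDS length not divisible by 3")
        stop = self.sequence[self.cds_end - 3 : self.cds_end]
        if stop not in STOP_CODONS:
            raise ValueError(f"{self.id}: CDS does not end in a stop codon ({stop})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.id}: invalid strand {self.strand!r}")

    # --- derived views ------------------------------------------------
    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def utr5(self) -> str:
        return self.sequence[: self.cds_start - 1]

    @property
    def utr3(self) -> str:
        return self.sequence[self.cds_end :]

    @property
    def utr5_len(self) -> int:
        return self.cds_start - 1

    @property
    def utr3_len(self) -> int:
        return len(self.sequence) - self.cds_end


@dataclass(frozen=True)
class PASRecord:
    """A polyadenylation-site call on one transcript (1-based position)."""

    transcript_id: str
    position: int
    support: int = 0

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("PAS position must be >= 1")
        if self.support < 0:
            raise ValueError("PAS support must be >= 0")


def find_cds(sequence: str) -> tuple[int, int] | None:
    """Call the coding region as the longest ATG..stop ORF.

    Scans all three frames; an ORF runs from an ATG to the first in-frame
    stop codon (stop included). Ties on length are broken toward the
    5'-most start. Returns 1-based ``(cds_start, cds_end)`` or ``None``
    when no complete ORF exists.
    """
    seq = normalize_sequence(sequence)
    n = len(seq)
    if n < 6:
        raise ValueError("sequence shorter than 6 nt cannot contain an ORF")
    best: tuple[int, int] | None = None  # (length, -start) maximized
    best_coords: tuple[int, int] | None = None
    for frame in range(3):
        open_start: int | None = None  # earliest unconsumed ATG (0-based)
        for p in range(frame, n - 2, 3):
            codon = seq[p : p + 3]
            if codon == "ATG" and open_start is None:
                open_start = p
            elif codon in STOP_CODONS and open_start is not None:
                length = p + 3 - open_start
                key = (length, -open_start)
                if best is None or key > best:
                    best = key
                    best_coords = (open_start + 1, p + 3)
                open_start = None
    return best_coords


def extract_utrs(t: TranscriptModel) -> tuple[str, str]:
    """Return ``(utr5, utr3)``; their lengths plus the CDS partition the sequence."""
    return t.utr5, t.utr3


def correct_utr3_end(
    t: TranscriptModel,
    pas: Iterable[PASRecord],
    window: int = 50,
) -> TranscriptModel:
    """Move the annotated 3' end to PAS evidence within ``window`` nt.

    Among the transcript's PAS records within +-window of the annotated end,
    the highest-support one wins (ties: nearest the annotated end, then
    3'-most). A correction that would truncate into the CDS is rejected and
    logged. Correction is one-shot: an already-corrected transcript is
    returned unchanged, which makes the operation idempotent.

    PAS positions beyond the available sequence cannot extend it; the end is
    then clamped to the sequence length (still flagged corrected).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if t.utr3_corrected:
        return t
    end = len(t.sequence)
    cands = [
        r for r in pas if r.transcript_id == t.id and abs(r.position - end) <= window
    ]
    if not cands:
        return replace(t, utr3_corrected=False)
    cands.sort(key=lambda r: (-r.support, abs(r.position - end), -r.position))
    chosen = cands[0]
    new_end = min(chosen.position, end)
    if new_end <= t.cds_end:
        logger.warning(
            "%s: PAS at %d would truncate into the CDS (cds_end=%d); rejected",
            t.id,
            chosen.position,
            t.cds_end,
        )
        return replace(t, utr3_corrected=False)
    return replace(t, sequence=t.sequence[:new_end], utr3_corrected=True)


def utr_length_summary(
    transcripts: Sequence[TranscriptModel],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Per-group UTR length summary with a log10 normality check.

    ``groups`` maps transcript id -> group label. Returns one row per group
    with mean/median/SD of 5' and 3' UTR lengths plus a Shapiro-Wilk p-value
    on log10(3' UTR length) (NaN when the group is too small or has
    zero-length UTRs). Group *comparisons* are delegated to
    :func:`compartmir.stats.compare_distributions`.
    """
    by_id = {t.id: t for t in transcripts}
    labels = sorted(set(groups.values()))
    rows = []
    for label in labels:
        ids = [i for i, g in groups.items() if g == label and i in by_id]
        if not ids:
            raise ValueError(f"group {label!r} is empty")
        u5 = np.array([by_id[i].utr5_len for i in ids], dtype=float)
        u3 = np.array([by_id[i].utr3_len for i in ids], dtype=float)
        if len(u3) >= 3 and (u3 > 0).all() and np.ptp(u3) > 0:
            shapiro_p = float(_st.shapiro(np.log10(u3)).pvalue)
        else:
            shapiro_p = math.nan
        rows.append(
            {
                "group": label,
                "n": len(ids),
                "utr5_mean": float(u5.mean()),
                "utr5_median": float(np.median(u5)),
                "utr5_sd": float(u5.std(ddof=1)) if len(u5) > 1 else 0.0,
                "utr3_mean": float(u3.mean()),
                "utr3_median": float(np.median(u3)),
                "utr3_sd": float(u3.std(ddof=1)) if len(u3) > 1 else 0.0,
                "log10_utr3_shapiro_p": shapiro_p,
            }
        )
    return pd.DataFrame(rows).set_index("group")
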