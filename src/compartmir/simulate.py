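"""Synthetic spermiogenesis fractionation datasets with planted truth.

The generator emulates the statistical regularities the analysis pipeline
is built to detect, so every downstream stage can be validated against a
known ground truth:

* multi-isoform genes sharing one CDS but differing in 3' UTR length, with
  log10 lengths normally distributed around a "short" and a "long" mean;
* a miRNA pool whose members are RNP- or polysome-assigned per stage, with
  a configurable fraction shifting from RNPs to polysomes at the last stage;
* canonical seed sites written into the UTRs: proximal sites of
  RNP-assigned miRNAs on RNP-destined (short-UTR) transcripts, distal sites
  of polysome-assigned miRNAs on polysome-destined (long-UTR) transcripts
  (default means 365 and 461 nt from the stop codon);
* replicated negative-binomial count tables for both fractions across three
  stages, with planted fold changes, per-sample depth factors, and a panel
  of internal-control genes distributed equally between fractions;
* PAS (polyadenylation site) records at the true 3' ends with positional
  jitter and partial coverage.

Every generator is deterministic given ``SimConfig.rng_seed``; each draws
from its own seeded substream so the outputs of one stage do not depend on
whether another stage ran.

A "miRNA-depleted" scenario (modeling the loss of miRNA biogenesis) marks a
fraction of the miRNA pool as depleted: their sites are not written, their
counts collapse to near zero, and transcripts recruited only by depleted
miRNAs lose their planted compartment enrichment. A "null" switch
(``positional_effect=False``) decouples compartment, UTR length and site
position for type-I-error experiments.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .hybrid import revcomp
from .normalize import CountTable
from .targeting import MiRNA
from .utr import PASRecord, TranscriptModel

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "SimConfig",
    "PlantedSite",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_transcriptome",
    "generate_mirnas_and_sites",
    "generate_counts",
    "generate_pas",
    "simulate_dataset",
]

FRACTIONS = ("RNP", "polysome")
_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in _STOPS
]

# rng substream tags, one per generator
_TAG_TRANSCRIPTOME = 1
_TAG_MIRNAS = 2
_TAG_COUNTS = 3
_TAG_PAS = 4


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimConfig:
    """All knobs of the synthetic dataset; defaults are the study conditions.

    Lengths are nucleotides, enrichments are log2 fold changes between
    fractions, ``nb_dispersion`` is the negative-binomial dispersion
    (variance = mean + dispersion * mean^2).
    """

    n_genes: int = 60
    isoforms_per_gene: int = 2
    utr3_log10_mean_short: float = 2.7
    utr3_log10_mean_long: float = 3.0
    utr3_log10_sd: float = 0.15
    cds_len_range: tuple[int, int] = (450, 900)
    utr5_len_range: tuple[int, int] = (50, 150)
    n_mirnas: int = 24
    mirna_len_range: tuple[int, int] = (20, 23)
    n_controls: int = 24
    stages: tuple[str, ...] = ("pachytene", "round", "elongating")
    n_replicates: int = 3
    nb_dispersion: float = 0.05
    planted_log2_enrichment: float = 2.0
    proximal_site_mean: float = 365.0
    distal_site_mean: float = 461.0
    site_sd: float = 30.0
    pas_jitter_sd: float = 10.0
    pas_coverage_frac: float = 0.9
    rng_seed: int = 0
    # secondary knobs
    baseline_range: tuple[float, float] = (100.0, 1000.0)
    scale_factor_range: tuple[float, float] = (0.5, 2.0)
    mirna_shift_frac: float = 0.37
    cross_target_frac: float = 0.3
    sites_per_transcript: int = 2
    stage_trend_log2fc: float = 1.0
    positional_effect: bool = True
    site_redraw_attempts: int = 10

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        counts = {
            "n_genes": self.n_genes,
            "isoforms_per_gene": self.isoforms_per_gene,
            "n_mirnas": self.n_mirnas,
            "n_controls": self.n_controls,
            "n_replicates": self.n_replicates,
            "sites_per_transcript": self.sites_per_transcript,
            "site_redraw_attempts": self.site_redraw_attempts,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ConfigError(f"{name} must be a positive integer")
        if self.n_replicates < 2:
            raise ConfigError(
                "n_replicates must be >= 2 (tests require replicates)"
            )
        for name in ("utr3_log10_sd", "nb_dispersion", "site_sd", "pas_jitter_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("pas_coverage_frac", "mirna_shift_frac", "cross_target_frac"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be in [0, 1]")
        if not self.proximal_site_mean < self.distal_site_mean:
            raise ConfigError(
                "proximal_site_mean must be smaller than distal_site_mean"
            )
        for name in ("cds_len_range", "utr5_len_range", "mirna_len_range",
                     "baseline_range", "scale_factor_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigError(f"{name} must be an increasing positive range")
        if len(self.stages) != len(set(self.stages)):
            raise ConfigError("stages must be unique labels")

    def _rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([int(self.rng_seed), tag])

    @property
    def sample_names(self) -> list[str]:
        return [
            f"{s}_{f}_rep{r}"
            for s in self.stages
            for f in FRACTIONS
            for r in range(1, self.n_replicates + 1)
        ]


class PlantedSite(NamedTuple):
    mirna_id: str
    transcript_id: str
    distance_to_stop: int


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    transcript_ids: list[str] = field(default_factory=list)
    mirna_ids: list[str] = field(default_factory=list)
    scale_factor_by_sample: dict[str, float] = field(default_factory=dict)
    rnp_enriched_ids: dict[str, set[str]] = field(default_factory=dict)
    polysome_enriched_ids: dict[str, set[str]] = field(default_factory=dict)
    control_ids: dict[str, set[str]] = field(default_factory=dict)
    planted_sites: list[PlantedSite] = field(default_factory=list)
    mirna_compartment_by_stage: dict[str, dict[str, str]] = field(default_factory=dict)
    depleted_mirna_ids: set[str] = field(default_factory=set)
    utr3_len_by_id: dict[str, int] = field(default_factory=dict)
    baseline_by_id: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for stage, ctrl in self.control_ids.items():
            if ctrl & self.rnp_enriched_ids.get(stage, set()):
                raise ValueError("control ids overlap RNP-enriched ids")
            if ctrl & self.polysome_enriched_ids.get(stage, set()):
                raise ValueError("control ids overlap polysome-enriched ids")
        for s in self.planted_sites:
            if s.distance_to_stop > self.utr3_len_by_id[s.transcript_id]:
                raise ValueError(
                    f"planted site beyond 3' UTR on {s.transcript_id}"
                )

    def to_json(self) -> str:
        def conv(o):
            if isinstance(o, set):
                return sorted(o)
            raise TypeError(type(o))

        d = asdict(self)
        d["planted_sites"] = [list(s) for s in self.planted_sites]
        return json.dumps(d, default=conv, sort_keys=True, indent=1)


@dataclass
class SyntheticDataset:
    config: SimConfig
    scenario: str
    transcripts: list[TranscriptModel]
    gene_map: dict[str, list[str]]
    mirnas: list[MiRNA]
    truth: SyntheticTruth
    counts_mrna: CountTable
    counts_sncrna: CountTable
    pas: list[PASRecord]


# --- transcriptome ------------------------------------------------------


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _random_cds(rng: np.random.Generator, lo: int, hi: int) -> str:
    n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
    n_codons = max(n_codons, 2)
    body = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 2)
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + "".join(_NONSTOP_CODONS[k] for k in body) + stop


def generate_transcriptome(
    config: SimConfig,
) -> tuple[list[TranscriptModel], dict[str, list[str]]]:
    """Genes with isoforms sharing a CDS but differing in 3' UTR length.

    Within a gene, isoform 0 draws its 3' UTR length from the "short"
    log10-normal component and isoform 1 from the "long" one (alternating
    beyond two isoforms). The CDS (ATG..stop, no internal in-frame stop)
    and the 5' UTR are shared by all isoforms of a gene.
    """
    rng = config._rng(_TAG_TRANSCRIPTOME)
    transcripts: list[TranscriptModel] = []
    gene_map: dict[str, list[str]] = {}
    for g in range(config.n_genes):
        gene_id = f"G{g:04d}"
        cds = _random_cds(rng, *config.cds_len_range)
        u5 = _random_bases(rng, int(rng.integers(*config.utr5_len_range)))
        ids = []
        for k in range(config.isoforms_per_gene):
            mu = (
                config.utr3_log10_mean_short
                if k % 2 == 0
                else config.utr3_log10_mean_long
            )
            u3_len = max(10, int(round(10 ** rng.normal(mu, config.utr3_log10_sd))))
            u3 = _random_bases(rng, u3_len)
            tid = f"{gene_id}.{k}"
            transcripts.append(
                TranscriptModel(
                    id=tid,
                    gene_id=gene_id,
                    sequence=u5 + cds + u3,
                    cds_start=len(u5) + 1,
                    cds_end=len(u5) + len(cds),
                )
            )
            ids.append(tid)
        gene_map[gene_id] = ids
    return transcripts, gene_map


# --- miRNAs and planted sites -------------------------------------------


def _plant_8mer(seq: list[str], utr_offset: int, d: int, mirna_dna: str) -> None:
    """Write an 8mer site at distance ``d``: revcomp(nt 2-8) then an A.

    The seed match occupies 3' UTR positions d+1..d+6 (0-based UTR indices
    d..d+5), the m8 partner sits at index d-1 and the A opposite nt 1 at
    index d+6.
    """
    block = revcomp(mirna_dna[1:8]) + "A"
    start = utr_offset + d - 1
    seq[start : start + 8] = list(block)


def _draw_distance(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    utr_len: int,
    occupied: list[tuple[int, int]],
    attempts: int,
) -> int | None:
    """Distance for a new 8mer site: 1 <= d <= utr_len - 7, non-overlapping.

    Redraws up to ``attempts`` times, then clips toward the largest
    feasible distance; None when the UTR cannot host the site.
    """
    d_max = utr_len - 7
    if d_max < 1:
        return None

    def free(d: int) -> bool:
        lo, hi = d - 1, d + 6
        return all(hi < a or lo > b for a, b in occupied)

    for _ in range(attempts):
        d = int(round(rng.normal(mean, sd)))
        if 1 <= d <= d_max and free(d):
            return d
    d = int(min(max(1, round(mean)), d_max))
    for _ in range(attempts):
        if free(d):
            logger.info(
                "site distance clipped to %d on a %d-nt 3' UTR", d, utr_len
            )
            return d
        d -= 8
        if d < 1:
            break
    logger.warning("could not place a site on a %d-nt 3' UTR; skipped", utr_len)
    return None


def generate_mirnas_and_sites(
    transcripts: Sequence[TranscriptModel],
    config: SimConfig,
    depleted_frac: float = 0.0,
) -> tuple[list[MiRNA], list[TranscriptModel], SyntheticTruth]:
    """miRNA pool plus transcripts with planted seed sites, and the truth.

    RNP-destined (short-UTR) transcripts receive proximal 8mer sites of
    RNP-assigned miRNAs; polysome-destined (long-UTR) transcripts receive
    distal sites of polysome-assigned miRNAs, plus — with probability
    ``cross_target_frac`` — one distal site of an RNP-assigned miRNA (the
    configuration under which distal targeting expels transcripts from
    RNPs). With ``positional_effect=False`` compartments, miRNA identity
    and site positions are all randomized (the no-effect generator).

    ``depleted_frac`` marks that share of miRNAs as depleted: their sites
    are not written and transcripts recruited only by depleted miRNAs lose
    their planted enrichment.
    """
    if not transcripts:
        raise ValueError("transcripts must be non-empty")
    rng = config._rng(_TAG_MIRNAS)
    # pool
    mirnas = []
    for k in range(config.n_mirnas):
        L = int(rng.integers(config.mirna_len_range[0], config.mirna_len_range[1] + 1))
        seq = _random_bases(rng, L).replace("T", "U")
        mirnas.append(MiRNA(id=f"miR-{k:03d}", sequence=seq))
    mirna_ids = [m.id for m in mirnas]
    order = rng.permutation(config.n_mirnas)
    half = config.n_mirnas // 2
    rnp_mirnas = [mirna_ids[i] for i in order[:half]]
    pol_mirnas = [mirna_ids[i] for i in order[half:]]
    n_shift = int(round(config.mirna_shift_frac * len(rnp_mirnas)))
    shift_order = rng.permutation(len(rnp_mirnas))
    shifters = {rnp_mirnas[i] for i in shift_order[:n_shift]}
    depletion_order = rng.permutation(config.n_mirnas)
    n_depleted = int(round(depleted_frac * config.n_mirnas))
    depleted = {mirna_ids[i] for i in depletion_order[:n_depleted]}

    compartment_by_stage: dict[str, dict[str, str]] = {}
    last = config.stages[-1]
    for stage in config.stages:
        comp = {}
        for mid in mirna_ids:
            if mid in depleted:
                continue
            if mid in shifters and stage == last:
                comp[mid] = "POLYSOME"
            else:
                comp[mid] = "RNP" if mid in rnp_mirnas else "POLYSOME"
        compartment_by_stage[stage] = comp

    # transcript roles
    tids = [t.id for t in transcripts]
    control = set(tids[: config.n_controls])
    others = [t for t in transcripts if t.id not in control]
    if config.positional_effect:
        rnp_destined = [t for t in others if int(t.id.rsplit(".", 1)[1]) % 2 == 0]
        pol_destined = [t for t in others if int(t.id.rsplit(".", 1)[1]) % 2 == 1]
    else:
        perm = rng.permutation(len(others))
        half_t = len(others) // 2
        rnp_destined = [others[i] for i in perm[:half_t]]
        pol_destined = [others[i] for i in perm[half_t:]]

    seqs = {t.id: list(t.sequence) for t in transcripts}
    occupied: dict[str, list[tuple[int, int]]] = {t.id: [] for t in transcripts}
    planted: list[PlantedSite] = []
    recruited: dict[str, bool] = {}

    def plant(t: TranscriptModel, pool: list[str], mean: float, uniform: bool,
              n_sites: int) -> None:
        utr_len = t.utr3_len
        k = min(n_sites, len(pool))
        chosen = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
        for mid in chosen:
            if uniform:
                d_max = utr_len - 7
                if d_max < 1:
                    continue
                d = int(rng.integers(1, d_max + 1))
                if any(not (d + 6 < a or d - 1 > b) for a, b in occupied[t.id]):
                    continue
            else:
                d = _draw_distance(
                    rng, mean, config.site_sd, utr_len, occupied[t.id],
                    config.site_redraw_attempts,
                )
                if d is None:
                    continue
            if mid in depleted:
                continue  # the draw is consumed; the site is never written
            mseq = next(m for m in mirnas if m.id == mid).dna
            _plant_8mer(seqs[t.id], t.cds_end, d, mseq)
            occupied[t.id].append((d - 1, d + 6))
            planted.append(PlantedSite(mid, t.id, d))
            recruited[t.id] = True

    if config.positional_effect:
        for t in rnp_destined:
            plant(t, rnp_mirnas, config.proximal_site_mean, False,
                  config.sites_per_transcript)
        for t in pol_destined:
            plant(t, pol_mirnas, config.distal_site_mean, False,
                  config.sites_per_transcript)
            if rng.random() < config.cross_target_frac:
                plant(t, rnp_mirnas, config.distal_site_mean, False, 1)
    else:
        for t in others:
            plant(t, mirna_ids, 0.0, True, config.sites_per_transcript)

    out_transcripts = [
        TranscriptModel(
            id=t.id,
            gene_id=t.gene_id,
            sequence="".join(seqs[t.id]),
            cds_start=t.cds_start,
            cds_end=t.cds_end,
            strand=t.strand,
        )
        for t in transcripts
    ]

    def kept(ts: list[TranscriptModel]) -> set[str]:
        if not depleted:
            return {t.id for t in ts if recruited.get(t.id, True)}
        return {t.id for t in ts if recruited.get(t.id, False)}

    rnp_set, pol_set = kept(rnp_destined), kept(pol_destined)
    truth = SyntheticTruth(
        transcript_ids=tids,
        mirna_ids=mirna_ids,
        rnp_enriched_ids={s: set(rnp_set) for s in config.stages},
        polysome_enriched_ids={s: set(pol_set) for s in config.stages},
        control_ids={s: set(control) for s in config.stages},
        planted_sites=planted,
        mirna_compartment_by_stage=compartment_by_stage,
        depleted_mirna_ids=depleted,
        utr3_len_by_id={t.id: t.utr3_len for t in out_transcripts},
    )
    truth.validate()
    return mirnas, out_transcripts, truth


# --- counts --------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, disp: float) -> np.ndarray:
    if disp == 0:
        return np.rint(mean)
    r = 1.0 / disp
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(float)


def generate_counts(
    truth: SyntheticTruth, config: SimConfig
) -> tuple[CountTable, CountTable]:
    """Replicated NB count tables for mRNAs and small RNAs.

    Expected count = baseline x stage trend x fraction effect x per-sample
    scale factor. Planted RNP/polysome entities split the configured log2
    enrichment symmetrically between fractions; internal controls and
    unplanted entities have a fraction effect of exactly 1. RNP-destined
    transcripts trend up and polysome-destined transcripts trend down
    across stages (``stage_trend_log2fc`` per stage step), providing the
    between-stage differential structure. With ``nb_dispersion == 0``
    counts degenerate to the rounded expectation.
    """
    if config.n_replicates < 2:
        raise ConfigError("n_replicates must be >= 2 (tests require replicates)")
    rng = config._rng(_TAG_COUNTS)
    samples = config.sample_names
    lo, hi = config.scale_factor_range
    factors = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(samples)))
    truth.scale_factor_by_sample = dict(zip(samples, factors.astype(float)))

    blo, bhi = config.baseline_range
    L = config.planted_log2_enrichment
    half = 2 ** (L / 2)

    def build(ids: list[str], cls_for, trend_for, low_ids: set[str]) -> CountTable:
        base = np.exp(rng.uniform(np.log(blo), np.log(bhi), size=len(ids)))
        for k, i in enumerate(ids):
            if i in low_ids:
                base[k] *= 0.01
            truth.baseline_by_id[i] = float(base[k])
        mean = np.empty((len(ids), len(samples)))
        for j, name in enumerate(samples):
            stage, fraction, _ = name.rsplit("_", 2)
            si = config.stages.index(stage)
            for k, i in enumerate(ids):
                cls = cls_for(i, stage)
                if cls == "RNP":
                    fx = half if fraction == "RNP" else 1.0 / half
                elif cls == "POLYSOME":
                    fx = 1.0 / half if fraction == "RNP" else half
                else:
                    fx = 1.0
                mean[k, j] = base[k] * trend_for(i, si) * fx * factors[j]
        counts = _nb_draw(rng, mean, config.nb_dispersion)
        return CountTable(pd.DataFrame(counts, index=ids, columns=samples))

    def mrna_cls(i: str, stage: str) -> str:
        if i in truth.rnp_enriched_ids[stage]:
            return "RNP"
        if i in truth.polysome_enriched_ids[stage]:
            return "POLYSOME"
        return "NONE"

    def mrna_trend(i: str, si: int) -> float:
        s0 = config.stages[0]
        if i in truth.rnp_enriched_ids[s0]:
            return 2 ** (config.stage_trend_log2fc * si)
        if i in truth.polysome_enriched_ids[s0]:
            return 2 ** (-config.stage_trend_log2fc * si)
        return 1.0

    def snc_cls(i: str, stage: str) -> str:
        return truth.mirna_compartment_by_stage[stage].get(i, "NONE")

    mrna = build(truth.transcript_ids, mrna_cls, mrna_trend, set())
    snc = build(
        truth.mirna_ids, snc_cls, lambda i, si: 1.0, truth.depleted_mirna_ids
    )
    return mrna, snc


# --- PAS -----------------------------------------------------------------


def generate_pas(
    transcripts: Sequence[TranscriptModel], config: SimConfig
) -> list[PASRecord]:
    """PAS records at the true 3' ends with positional jitter.

    A fraction ``pas_coverage_frac`` of transcripts receives one record at
    its true end plus Normal(0, pas_jitter_sd) nucleotides.
    """
    if not transcripts:
        raise ValueError("transcripts must be non-empty")
    rng = config._rng(_TAG_PAS)
    records = []
    for t in transcripts:
        if rng.random() < config.pas_coverage_frac:
            pos = len(t.sequence) + int(round(rng.normal(0.0, config.pas_jitter_sd)))
            pos = max(pos, t.cds_end + 1)
            support = int(rng.integers(5, 51))
            records.append(PASRecord(t.id, pos, support))
    return records


# --- orchestration -------------------------------------------------------


def simulate_dataset(
    config: SimConfig,
    scenario: str = "wildtype",
    depletion_frac: float = 0.8,
) -> SyntheticDataset:
    """Run every generator and bundle the outputs.

    ``scenario='mirna_depleted'`` applies ``depletion_frac`` to the miRNA
    pool (the miRNA-biogenesis-knockout emulation); matched seeds share the
    same transcriptome and planting randomness with the wildtype run.
    """
    if scenario not in ("wildtype", "mirna_depleted"):
        raise ConfigError(f"unknown scenario {scenario!r}")
    frac = depletion_frac if scenario == "mirna_depleted" else 0.0
    base_transcripts, gene_map = generate_transcriptome(config)
    mirnas, transcripts, truth = generate_mirnas_and_sites(
        base_transcripts, config, depleted_frac=frac
    )
    counts_mrna, counts_snc = generate_counts(truth, config)
    pas = generate_pas(transcripts, config)
    return SyntheticDataset(
        config=config,
        scenario=scenario,
        transcripts=transcripts,
        gene_map=gene_map,
        mirnas=mirnas,
        truth=truth,
        counts_mrna=counts_mrna,
        counts_sncrna=counts_snc,
        pas=pas,
    )
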