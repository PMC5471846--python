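"""End-to-end orchestration: simulate -> annotate -> normalize -> enrich ->
target -> associate, with a machine-readable report.

The report captures, per stage: enriched-set sizes, mean 3' UTR lengths per
compartment, positional (distance-to-stop) comparisons between compartments,
the miRNA-mRNA compartment association, and the miRNA RNP-to-polysome shift
fraction; plus the discovered position threshold and the between-stage
differential analysis. Runs are fully reproducible given the seed.

Positional and association statistics default to high-confidence (8mer)
sites: bare 6mer seed matches occur by chance every ~4 kb per miRNA, so
with a pool of miRNAs chance matches would dominate any presence/absence
contrast. The filter is configurable (``site_types_for_stats``).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .enrichment import (
    CLASS_POLYSOME,
    CLASS_RNP,
    compartment_enrichment,
    detect_shifters,
    enrichment_classes,
    stage_differential,
)
from .normalize import (
    CountTable,
    apply_factors,
    control_regression_norm,
    expression_floor,
    geometric_median_norm,
    quantile_norm,
    size_factor_norm,
)
from .simulate import ConfigError, SimConfig, simulate_dataset
from .stats import (
    compare_distributions,
    compartment_association,
    position_threshold_discovery,
)
from .targeting import target_map
from .utr import TranscriptModel, correct_utr3_end, find_cds

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full", "annotate_transcripts"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    scenario: str = "wildtype"
    depletion_frac: float = 0.8
    normalization: str = "control_regression"
    alpha_snc: float = 0.05
    alpha_mrna: float = 0.1
    alpha_differential: float = 0.1
    expression_threshold: float = 1.0
    pas_window: int = 50
    energy_model: str = "simple"
    window: int = 60
    max_loop: int = 8
    energy_cutoff: float = 0.0
    site_types_for_stats: tuple[str, ...] = ("8mer",)
    threshold_trees: int = 100
    threshold_stump: bool = False

    def __post_init__(self) -> None:
        if self.scenario not in ("wildtype", "mirna_depleted"):
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        if not (0 <= self.depletion_frac <= 1):
            raise ConfigError("depletion_frac must be in [0, 1]")


def annotate_transcripts(sequences: dict[str, str], gene_of=None) -> list[TranscriptModel]:
    """Call CDSs and build transcript models; sequences with no ORF are skipped."""
    out = []
    for tid, seq in sequences.items():
        cds = find_cds(seq)
        if cds is None:
            logger.warning("%s: no complete ORF; transcript skipped", tid)
            continue
        gene = gene_of(tid) if gene_of else tid
        out.append(
            TranscriptModel(
                id=tid, gene_id=gene, sequence=seq, cds_start=cds[0], cds_end=cds[1]
            )
        )
    return out


def _normalize_mrna(config: RunConfig, table: CountTable, control_ids) -> tuple[dict, CountTable]:
    method = config.normalization
    if method == "control_regression":
        # one reference for the whole table: the control panel is flat in
        # both fraction and stage, so a single reference keeps cross-stage
        # comparisons on a common scale
        ref = f"{table.stages[0]}_RNP_rep1"
        sf, normed = control_regression_norm(table, control_ids, ref)
        return sf.factors.to_dict(), normed
    if method == "geometric":
        sf = geometric_median_norm(table)
        return sf.factors.to_dict(), apply_factors(table, sf)
    if method == "sizefactor":
        sf, normed = size_factor_norm(table)
        return sf.factors.to_dict(), normed
    if method == "quantile":
        return {}, quantile_norm(table)
    raise ConfigError(f"unknown normalization method {method!r}")


def _cmp_dict(cmp) -> dict:
    return {
        "mean_a": cmp.mean_a,
        "mean_b": cmp.mean_b,
        "n_a": cmp.n_a,
        "n_b": cmp.n_b,
        "p_t": cmp.p_t,
        "p_wilcoxon": cmp.p_wilcoxon,
        "p_t_log": cmp.p_t_log,
    }


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        items = sorted(obj) if isinstance(obj, set) else list(obj)
        return [_json_safe(v) for v in items]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def run_full(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full pipeline and return the report dictionary.

    When ``outdir`` is given, the dataset bundle, per-stage enrichment
    table, target-site table, scale factors and ``report.json`` are
    written there.
    """
    ds = simulate_dataset(config.sim, config.scenario, config.depletion_frac)
    stages = list(config.sim.stages)

    # --- annotation + PAS end correction
    sequences = {t.id: t.sequence for t in ds.transcripts}
    gene_of = {t.id: t.gene_id for t in ds.transcripts}
    annotated = annotate_transcripts(sequences, gene_of=lambda i: gene_of[i])
    pas_by_t: dict[str, list] = {}
    for r in ds.pas:
        pas_by_t.setdefault(r.transcript_id, []).append(r)
    annotated = [
        correct_utr3_end(t, pas_by_t.get(t.id, []), window=config.pas_window)
        for t in annotated
    ]
    utr3_len = {t.id: t.utr3_len for t in annotated}
    n_corrected = sum(t.utr3_corrected for t in annotated)

    # --- normalization + expression floor
    control_ids = ds.truth.control_ids[stages[0]]
    factors, mrna_norm = _normalize_mrna(config, ds.counts_mrna, control_ids)
    snc_sf, snc_norm = size_factor_norm(ds.counts_sncrna)
    mrna_norm = expression_floor(mrna_norm, config.expression_threshold)
    snc_norm = expression_floor(snc_norm, config.expression_threshold)

    # --- per-stage enrichment
    mrna_records = {
        s: compartment_enrichment(mrna_norm, s, alpha=config.alpha_mrna)
        for s in stages
    }
    snc_records = {
        s: compartment_enrichment(snc_norm, s, alpha=config.alpha_snc)
        for s in stages
    }

    # --- target map (sequence-level; shared across stages)
    tmap = target_map(
        ds.mirnas,
        annotated,
        energy_cutoff=config.energy_cutoff,
        model=config.energy_model,
        window=config.window,
        max_loop=config.max_loop,
    )
    tm_stats = (
        tmap[tmap["site_type"].isin(config.site_types_for_stats)]
        if len(tmap)
        else tmap
    )

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "scenario": config.scenario,
        "seed": config.sim.rng_seed,
        "n_transcripts": len(ds.transcripts),
        "n_annotated": len(annotated),
        "n_pas_records": len(ds.pas),
        "n_utr3_corrected": n_corrected,
        "n_mirnas": len(ds.mirnas),
        "n_sites_total": int(len(tmap)),
        "n_sites_stats": int(len(tm_stats)),
        "mrna_entities_after_floor": int(len(mrna_norm.df)),
        "sncrna_entities_after_floor": int(len(snc_norm.df)),
        "stages": {},
    }

    for s in stages:
        mrna_classes = enrichment_classes(mrna_records[s])
        mirna_classes = enrichment_classes(snc_records[s])
        rnp_ids = [i for i, c in mrna_classes.items() if c == CLASS_RNP and i in utr3_len]
        pol_ids = [i for i, c in mrna_classes.items() if c == CLASS_POLYSOME and i in utr3_len]
        stage_rep: dict = {
            "n_rnp_mrnas": len(rnp_ids),
            "n_polysome_mrnas": len(pol_ids),
            "n_rnp_mirnas": sum(c == CLASS_RNP for c in mirna_classes.values()),
            "n_polysome_mirnas": sum(
                c == CLASS_POLYSOME for c in mirna_classes.values()
            ),
        }
        if len(rnp_ids) >= 2 and len(pol_ids) >= 2:
            lens_cmp = compare_distributions(
                [utr3_len[i] for i in rnp_ids], [utr3_len[i] for i in pol_ids]
            )
            stage_rep["utr3_length"] = _cmp_dict(lens_cmp)
        sites_rnp = tm_stats[tm_stats["transcript_id"].isin(rnp_ids)]
        sites_pol = tm_stats[tm_stats["transcript_id"].isin(pol_ids)]
        stage_rep["n_sites_on_rnp_mrnas"] = int(len(sites_rnp))
        stage_rep["n_sites_on_polysome_mrnas"] = int(len(sites_pol))
        if len(sites_rnp) >= 2 and len(sites_pol) >= 2:
            dist_cmp = compare_distributions(
                sites_rnp["distance_to_stop"], sites_pol["distance_to_stop"]
            )
            stage_rep["site_distance"] = _cmp_dict(dist_cmp)
        if mrna_classes and mirna_classes:
            assoc = compartment_association(
                mirna_classes,
                mrna_classes,
                tmap,
                site_types=config.site_types_for_stats,
            )
            stage_rep["association"] = {
                "table": assoc.table.astype(int).tolist(),
                "chi2": assoc.chi2,
                "p_value": None if math.isnan(assoc.p_value) else assoc.p_value,
                "odds_ratio": None
                if math.isnan(assoc.odds_ratio)
                else assoc.odds_ratio,
                "degenerate": assoc.degenerate,
            }
            rnp_mirna_ids = {i for i, c in mirna_classes.items() if c == CLASS_RNP}
            targeted = set(
                tm_stats.loc[
                    tm_stats["mirna_id"].isin(rnp_mirna_ids), "transcript_id"
                ]
            )
            stage_rep["frac_rnp_mrnas_targeted_by_rnp_mirnas"] = (
                len(targeted & set(rnp_ids)) / len(rnp_ids) if rnp_ids else None
            )
        report["stages"][s] = stage_rep

    # --- position threshold discovery at the focal (middle) stage
    focal = stages[min(1, len(stages) - 1)]
    classes = enrichment_classes(mrna_records[focal])
    labeled = tm_stats[
        tm_stats["transcript_id"].map(classes).isin([CLASS_RNP, CLASS_POLYSOME])
    ]
    if len(labeled) and labeled["transcript_id"].map(classes).nunique() == 2:
        feats = labeled[
            ["distance_to_stop", "abs_energy", "site_type", "utr3_length"]
        ].reset_index(drop=True)
        labels = labeled["transcript_id"].map(classes).to_numpy()
        try:
            report["position_threshold"] = _json_safe(
                position_threshold_discovery(
                    feats,
                    labels,
                    n_trees=config.threshold_trees,
                    stump=config.threshold_stump,
                    seed=config.sim.rng_seed,
                )
            )
        except ValueError as exc:
            report["position_threshold"] = {"error": str(exc)}
    else:
        report["position_threshold"] = None

    # --- miRNA shifters between the last two stages
    if len(stages) >= 2:
        shift = detect_shifters(
            snc_records, snc_norm, stages[-2], stages[-1], alpha=config.alpha_snc
        )
        report["mirna_shift"] = {
            "from": stages[-2],
            "to": stages[-1],
            "n_rnp_at_from": shift["n_rnp_at_from"],
            "n_shifters": len(shift["shifters"]),
            "shift_fraction": shift["shift_fraction"],
        }

    # --- between-stage mRNA differential in the RNP fraction
    if len(stages) >= 2:
        up, down, _ = stage_differential(
            mrna_norm, "RNP", stages[0], stages[1], alpha=config.alpha_differential
        )
        diff_rep: dict = {"fraction": "RNP", "n_up": len(up), "n_down": len(down)}
        s_up = tm_stats[tm_stats["transcript_id"].isin(up)]
        s_down = tm_stats[tm_stats["transcript_id"].isin(down)]
        if len(s_up) >= 2 and len(s_down) >= 2:
            diff_rep["site_distance_up_vs_down"] = _cmp_dict(
                compare_distributions(
                    s_up["distance_to_stop"], s_down["distance_to_stop"]
                )
            )
        report["rnp_differential"] = diff_rep

    report = _json_safe(report)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cio.write_dataset(ds, outdir / "data")
        cio.write_transcript_table(annotated, outdir / "transcripts_annotated.tsv")
        pd.concat(mrna_records.values()).to_csv(
            outdir / "enrichment_mrna.tsv", sep="\t", index_label="id"
        )
        pd.concat(snc_records.values()).to_csv(
            outdir / "enrichment_sncrna.tsv", sep="\t", index_label="id"
        )
        tmap.to_csv(outdir / "sites.tsv", sep="\t", index=False)
        pd.Series(factors, name="factor").to_csv(
            outdir / "factors.tsv", sep="\t", index_label="sample"
        )
        (outdir / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=1)
        )
    return report
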