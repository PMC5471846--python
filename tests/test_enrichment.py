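"""Compartment enrichment calls, stage differentials, shifter detection."""

import numpy as np
import pandas as pd
import pytest

from compartmir import (
    CLASS_NONE,
    CLASS_POLYSOME,
    CLASS_RNP,
    CountTable,
    SimConfig,
    compartment_enrichment,
    detect_shifters,
    simulate_dataset,
    stage_differential,
)


def two_fraction_table(rnp_rows, pol_rows, ids, stage="round"):
    rnp = np.asarray(rnp_rows, dtype=float)
    pol = np.asarray(pol_rows, dtype=float)
    cols = {}
    for r in range(rnp.shape[1]):
        cols[f"{stage}_RNP_rep{r+1}"] = rnp[:, r]
    for r in range(pol.shape[1]):
        cols[f"{stage}_polysome_rep{r+1}"] = pol[:, r]
    return CountTable(pd.DataFrame(cols, index=ids))


class TestCompartmentEnrichment:
    def test_worked_example_rnp_classed(self):
        # RNP reps (100,110,90) vs polysome (10,11,9): ratio ~ -3.3, RNP
        t = two_fraction_table([[100, 110, 90]], [[10, 11, 9]], ["e"])
        rec = compartment_enrichment(t, "round", alpha=0.05)
        assert rec.loc["e", "class"] == CLASS_RNP
        assert rec.loc["e", "log2_ratio"] == pytest.approx(-3.32, abs=0.1)
        assert rec.loc["e", "p_t"] <= 0.05

    def test_identical_means_unclassified(self):
        t = two_fraction_table([[50, 50, 50]], [[50, 50, 50]], ["e"])
        rec = compartment_enrichment(t, "round")
        assert rec.loc["e", "class"] == CLASS_NONE
        assert rec.loc["e", "log2_ratio"] == 0.0

    def test_low_expressed_excluded(self):
        t = two_fraction_table([[0.2, 0.3, 0.1]], [[0.9, 1.0, 0.8]], ["e"])
        rec = compartment_enrichment(t, "round", min_count=1.0)
        assert rec.loc["e", "low_expressed"]
        assert rec.loc["e", "class"] == CLASS_NONE

    def test_antisymmetry_under_fraction_swap(self):
        rng = np.random.default_rng(0)
        rnp = rng.poisson(100, size=(30, 4)).astype(float)
        pol = rng.poisson(100, size=(30, 4)) * rng.choice([0.2, 1, 5], 30)[:, None]
        ids = [f"e{i}" for i in range(30)]
        fwd = compartment_enrichment(two_fraction_table(rnp, pol, ids), "round")
        rev = compartment_enrichment(two_fraction_table(pol, rnp, ids), "round")
        assert np.allclose(fwd["log2_ratio"], -rev["log2_ratio"])
        swap = {CLASS_RNP: CLASS_POLYSOME, CLASS_POLYSOME: CLASS_RNP,
                CLASS_NONE: CLASS_NONE}
        assert list(rev["class"]) == [swap[c] for c in fwd["class"]]

    def test_single_replicate_rejected(self):
        t = two_fraction_table([[10]], [[20]], ["e"])
        with pytest.raises(ValueError, match="replicates"):
            compartment_enrichment(t, "round")

    def test_bh_correction_is_more_conservative(self):
        rng = np.random.default_rng(1)
        rnp = rng.poisson(100, size=(200, 3)).astype(float)
        pol = rng.poisson(100, size=(200, 3)).astype(float)
        ids = [f"e{i}" for i in range(200)]
        t = two_fraction_table(rnp, pol, ids)
        raw = compartment_enrichment(t, "round", alpha=0.05)
        bh = compartment_enrichment(t, "round", alpha=0.05, mtc="bh")
        assert (bh["class"] != CLASS_NONE).sum() <= (raw["class"] != CLASS_NONE).sum()


class TestRecovery:
    def test_planted_sets_recovered_at_high_effect(self):
        """|log2FC| = 2 with 5 replicates at low dispersion: the planted
        RNP and polysome sets come back with Jaccard >= 0.9."""
        cfg = SimConfig(n_genes=100, stages=("round",), n_replicates=5,
                        nb_dispersion=0.02, planted_log2_enrichment=2.0,
                        scale_factor_range=(1.0, 1.0), rng_seed=11)
        ds = simulate_dataset(cfg)
        rec = compartment_enrichment(ds.counts_mrna, "round", alpha=0.05)
        for cls, truth_set in [
            (CLASS_RNP, ds.truth.rnp_enriched_ids["round"]),
            (CLASS_POLYSOME, ds.truth.polysome_enriched_ids["round"]),
        ]:
            got = set(rec.index[rec["class"] == cls])
            jac = len(got & truth_set) / len(got | truth_set)
            assert jac >= 0.9, (cls, jac)

    def test_null_table_classes_near_alpha(self):
        cfg = SimConfig(n_genes=300, stages=("round",), n_replicates=10,
                        nb_dispersion=0.05, planted_log2_enrichment=0.0,
                        scale_factor_range=(1.0, 1.0), rng_seed=12)
        ds = simulate_dataset(cfg)
        rec = compartment_enrichment(ds.counts_mrna, "round", alpha=0.05)
        frac = (rec["class"] != CLASS_NONE).mean()
        assert frac <= 1.5 * 0.05

    def test_recovery_improves_with_effect_size(self):
        """Mean recovery Jaccard is non-decreasing in the planted effect."""
        def mean_jac(lfc):
            vals = []
            for seed in range(6):
                cfg = SimConfig(n_genes=60, stages=("round",), n_replicates=4,
                                nb_dispersion=0.05, planted_log2_enrichment=lfc,
                                scale_factor_range=(1.0, 1.0), rng_seed=100 + seed)
                ds = simulate_dataset(cfg)
                rec = compartment_enrichment(ds.counts_mrna, "round", 0.05)
                got = set(rec.index[rec["class"] == CLASS_RNP])
                truth = ds.truth.rnp_enriched_ids["round"]
                vals.append(len(got & truth) / len(got | truth))
            return np.mean(vals)

        jacs = [mean_jac(l) for l in (0.5, 1.0, 2.0)]
        assert jacs[0] <= jacs[1] + 0.05 and jacs[1] <= jacs[2] + 0.05


class TestStageDifferential:
    def _two_stage_table(self, a_means, b_means, ids, reps=4, seed=0):
        rng = np.random.default_rng(seed)
        cols = {}
        for r in range(reps):
            cols[f"round_RNP_rep{r+1}"] = rng.poisson(a_means).astype(float)
        for r in range(reps):
            cols[f"elongating_RNP_rep{r+1}"] = rng.poisson(b_means).astype(float)
        return CountTable(pd.DataFrame(cols, index=ids))

    def test_planted_two_fold_increase_detected(self):
        means = np.full(20, 200.0)
        up_means = means.copy()
        up_means[0] = 400.0
        t = self._two_stage_table(means, up_means, [f"e{i}" for i in range(20)])
        up, down, _ = stage_differential(t, "RNP", "round", "elongating", 0.05)
        assert "e0" in up

    def test_same_stage_yields_empty_sets(self):
        t = self._two_stage_table(np.full(5, 100.0), np.full(5, 100.0),
                                  [f"e{i}" for i in range(5)])
        up, down, _ = stage_differential(t, "RNP", "round", "round", 0.05)
        assert up == set() and down == set()

    def test_unknown_fraction_rejected(self):
        t = self._two_stage_table(np.full(5, 100.0), np.full(5, 100.0),
                                  [f"e{i}" for i in range(5)])
        with pytest.raises(ValueError):
            stage_differential(t, "monosome", "round", "elongating")

    def test_null_type_one_error_controlled(self):
        alpha = 0.05
        means = np.full(600, 150.0)
        t = self._two_stage_table(means, means, [f"e{i}" for i in range(600)],
                                  reps=5, seed=3)
        up, down, _ = stage_differential(t, "RNP", "round", "elongating", alpha)
        frac = (len(up) + len(down)) / 600
        assert frac <= 1.5 * alpha


class TestShifters:
    def _mk(self, flip: bool):
        cfg = SimConfig(n_genes=30, rng_seed=21,
                        mirna_shift_frac=1.0 if flip else 0.0,
                        nb_dispersion=0.01, scale_factor_range=(1.0, 1.0),
                        n_replicates=5)
        ds = simulate_dataset(cfg)
        recs = {
            s: compartment_enrichment(ds.counts_sncrna, s, alpha=0.05)
            for s in cfg.stages
        }
        return detect_shifters(recs, ds.counts_sncrna, "round", "elongating")

    def test_planted_flips_detected(self):
        out = self._mk(flip=True)
        assert out["n_rnp_at_from"] > 0
        assert out["shift_fraction"] >= 0.9  # all RNP miRNAs flipped

    def test_no_flips_no_shifters(self):
        out = self._mk(flip=False)
        assert out["shift_fraction"] == 0.0

    def test_missing_stage_rejected(self, default_dataset):
        rec = compartment_enrichment(default_dataset.counts_sncrna, "round")
        with pytest.raises(ValueError, match="enrichment"):
            detect_shifters({"round": rec}, default_dataset.counts_sncrna,
                            "round", "elongating")
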