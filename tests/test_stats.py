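"""Distribution comparisons, exact Wilcoxon, chi-square association,
profiles, and decision-tree threshold mining."""

import itertools

import numpy as np
import pandas as pd
import pytest

from compartmir import (
    compare_distributions,
    compartment_association,
    energy_position_summary,
    position_threshold_discovery,
    rank_sum_test,
    targeting_frequency_profile,
)
from compartmir.stats import association_2x2
from _oracles import wilcoxon_enumeration


class TestRankSum:
    def test_extreme_small_sample_exact_p(self):
        # {1,2,3} vs {4,5,6}: the most extreme of C(6,3)=20 orderings
        assert rank_sum_test([1, 2, 3], [4, 5, 6], "less") == pytest.approx(0.05)

    def test_matches_enumeration_for_all_small_sizes(self):
        rng = np.random.default_rng(0)
        for m, n in itertools.product(range(2, 6), range(2, 6)):
            if m + n > 10:
                continue
            for _ in range(3):
                vals = rng.permutation(np.arange(1.0, m + n + 1))
                a, b = vals[:m], vals[m:]
                for alt in ("two-sided", "less", "greater"):
                    assert rank_sum_test(a, b, alt) == pytest.approx(
                        wilcoxon_enumeration(a, b, alt)
                    ), (m, n, alt)

    def test_large_sample_asymptotic_sensible(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 100)
        b = rng.normal(1, 1, 100)
        assert rank_sum_test(a, b) < 1e-6

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestCompareDistributions:
    def test_identical_groups_nonsignificant(self):
        x = [1.0, 2.0, 3.0, 4.0]
        cmp = compare_distributions(x, x)
        assert cmp.p_t == pytest.approx(1.0)
        assert cmp.p_wilcoxon > 0.9

    def test_log_t_reported_only_for_positive_values(self):
        pos = compare_distributions([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert pos.p_t_log is not None
        mixed = compare_distributions([-1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert mixed.p_t_log is None

    def test_power_at_planted_site_distance_means(self):
        """Normal(365, 50) vs Normal(461, 50) at n=200 is detected by both
        tests in essentially every replicate."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            a = rng.normal(365, 50, 200)
            b = rng.normal(461, 50, 200)
            cmp = compare_distributions(a, b)
            hits += (cmp.p_t < 1e-6) and (cmp.p_wilcoxon < 1e-6)
        assert hits >= 0.99 * n_seeds

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions([1.0], [2.0, 3.0])


class TestAssociation2x2:
    def test_hand_computed_example(self):
        res = association_2x2([[50, 10], [10, 50]])
        assert res.chi2 == pytest.approx(53.33, abs=0.01)
        assert res.odds_ratio == pytest.approx(25.0)
        assert res.p_value < 1e-10

    def test_symmetric_table_null(self):
        res = association_2x2([[30, 30], [30, 30]])
        assert res.chi2 == 0.0
        assert res.odds_ratio == pytest.approx(1.0)

    def test_zero_cell_haldane_correction(self):
        res = association_2x2([[10, 0], [5, 5]])
        assert np.isfinite(res.odds_ratio) and res.odds_ratio > 1

    def test_zero_margin_degenerate(self):
        res = association_2x2([[0, 0], [5, 5]])
        assert res.degenerate and np.isnan(res.p_value)

    def test_chi2_equals_squared_proportion_z(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 80, size=4)
            res = association_2x2([[a, b], [c, d]])
            n1, n2 = a + b, c + d
            p1, p2 = a / n1, c / n2
            p = (a + c) / (n1 + n2)
            z = (p1 - p2) / np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
            assert res.chi2 == pytest.approx(z**2)

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(300):
            row = rng.multinomial(200, [0.25] * 4)
            res = association_2x2(row.reshape(2, 2))
            if not res.degenerate:
                ps.append(res.p_value)
        ps = np.asarray(ps)
        # chi-square approximation: type-I error near nominal at both levels
        assert abs((ps < 0.05).mean() - 0.05) < 0.03
        assert abs((ps < 0.5).mean() - 0.5) < 0.08


class TestCompartmentAssociation:
    def _tmap(self, rows):
        return pd.DataFrame(
            rows, columns=["mirna_id", "transcript_id", "site_type"]
        )

    def test_planted_positive_association(self):
        mirna_classes = {"m1": "RNP", "m2": "POLYSOME"}
        mrna_classes = {f"r{i}": "RNP" for i in range(10)}
        mrna_classes |= {f"p{i}": "POLYSOME" for i in range(10)}
        rows = [("m1", f"r{i}", "8mer") for i in range(9)]
        rows += [("m2", f"p{i}", "8mer") for i in range(9)]
        rows += [("m1", "p0", "8mer")]
        res = compartment_association(mirna_classes, mrna_classes,
                                      self._tmap(rows))
        assert res.odds_ratio > 1 and res.p_value < 0.01

    def test_site_type_filter_applies(self):
        mirna_classes = {"m1": "RNP"}
        mrna_classes = {"r0": "RNP", "p0": "POLYSOME"}
        rows = [("m1", "r0", "6mer")]
        res = compartment_association(mirna_classes, mrna_classes,
                                      self._tmap(rows), site_types=("8mer",))
        assert res.table[0].tolist() == [0, 1]  # the 6mer site is ignored

    def test_empty_class_maps_rejected(self):
        with pytest.raises(ValueError):
            compartment_association({}, {"t": "RNP"}, self._tmap([]))


class TestTargetingFrequencyProfile:
    def _ratio(self, vals):
        return pd.Series(vals, index=[f"t{i}" for i in range(len(vals))])

    def test_no_sites_all_zero(self):
        prof = targeting_frequency_profile(
            pd.DataFrame(columns=["mirna_id", "transcript_id", "site_type"]),
            self._ratio([-1.0, 0.0, 1.0]),
            {"m": "RNP"},
            bins=3,
        )
        assert (prof["mean_rnp_mirna_hits"] == 0).all()

    def test_single_bin_equals_global_mean(self):
        tmap = pd.DataFrame(
            {
                "mirna_id": ["m", "m", "m"],
                "transcript_id": ["t0", "t0", "t1"],
                "site_type": ["8mer"] * 3,
            }
        )
        prof = targeting_frequency_profile(
            tmap, self._ratio([-2.0, -1.0, 3.0]), {"m": "RNP"}, bins=1
        )
        assert len(prof) == 1
        assert prof.loc[0, "mean_rnp_mirna_hits"] == pytest.approx(1.0)

    def test_planted_design_concentrates_mass_left_of_zero(self, default_dataset):
        from compartmir import compartment_enrichment, enrichment_classes, target_map

        ds = default_dataset
        rec_m = compartment_enrichment(ds.counts_mrna, "round", alpha=0.1)
        rec_s = compartment_enrichment(ds.counts_sncrna, "round", alpha=0.05)
        tmap = target_map(ds.mirnas, ds.transcripts)
        prof = targeting_frequency_profile(
            tmap[tmap["site_type"] == "8mer"],
            rec_m["log2_ratio"],
            enrichment_classes(rec_s),
            bins=10,
        )
        left = prof[prof["bin_right"] <= 0]
        right = prof[prof["bin_left"] >= 0]
        w_left = (left["mean_rnp_mirna_hits"] * left["n_mrnas"]).sum()
        w_right = (right["mean_rnp_mirna_hits"] * right["n_mrnas"]).sum()
        assert w_left > w_right


class TestEnergyPositionSummary:
    def _sites(self, dists, energies):
        return pd.DataFrame(
            {"distance_to_stop": dists, "abs_energy": energies}
        )

    def test_group_means_ordered_as_planted(self):
        rng = np.random.default_rng(4)
        sites = self._sites(
            np.r_[rng.normal(300, 20, 50), rng.normal(500, 20, 50)],
            np.r_[rng.normal(20, 2, 50), rng.normal(10, 2, 50)],
        )
        out = energy_position_summary(sites, ["prox"] * 50 + ["dist"] * 50)
        s = out["summary"]
        assert s.loc["prox", "mean_distance"] < s.loc["dist", "mean_distance"]
        assert s.loc["prox", "mean_abs_energy"] > s.loc["dist", "mean_abs_energy"]
        assert out["distance_comparison"].p_t < 1e-6

    def test_single_site_point_mass(self):
        out = energy_position_summary(self._sites([100.0], [5.0]), ["g"])
        grid = out["density"]["g"]["grid"]
        assert grid.sum() == 1

    def test_identical_groups_nonsignificant_under_null(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            sites = self._sites(rng.normal(400, 50, 80), rng.normal(15, 3, 80))
            out = energy_position_summary(sites, ["a", "b"] * 40)
            hits += out["distance_comparison"].p_t < 0.01
        assert hits <= 0.05 * n_seeds + 1


class TestPositionThresholdDiscovery:
    def _features(self, dists):
        return pd.DataFrame({"distance_to_stop": dists})

    def test_perfectly_separated_stump(self):
        dists = np.r_[np.linspace(100, 380, 20), np.linspace(420, 800, 20)]
        labels = ["RNP"] * 20 + ["POLYSOME"] * 20
        out = position_threshold_discovery(self._features(dists), labels,
                                           stump=True, seed=0)
        assert 380 < out["threshold"] <= 420
        assert out["cv_accuracy"] == 1.0

    def test_permuted_labels_no_importance(self):
        rng = np.random.default_rng(5)
        dists = rng.uniform(0, 1000, 200)
        labels = rng.permutation(["RNP"] * 100 + ["POLYSOME"] * 100)
        out = position_threshold_discovery(self._features(dists), labels,
                                           stump=True, seed=0)
        assert abs(out["distance_importance"]) < 0.08
        assert abs(out["cv_accuracy"] - 0.5) < 0.15

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            position_threshold_discovery(
                self._features([1.0, 2.0] * 10), ["RNP"] * 20
            )

    def test_forest_recovers_midpoint_between_planted_means(self):
        rng = np.random.default_rng(6)
        n = 120
        feats = pd.DataFrame(
            {
                "distance_to_stop": np.r_[
                    rng.normal(365, 30, n), rng.normal(461, 30, n)
                ],
                "abs_energy": rng.uniform(5, 25, 2 * n),
            }
        )
        labels = ["RNP"] * n + ["POLYSOME"] * n
        out = position_threshold_discovery(feats, labels, n_trees=50, seed=0)
        assert 380 <= out["threshold"] <= 446
        assert out["distance_importance"] > 0.1
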