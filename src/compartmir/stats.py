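"""Inferential statistics for positional miRNA-targeting analyses.

Covers the package's hypothesis-testing layer: two-sample location
comparisons (Welch t cross-validated by Wilcoxon rank-sum), 2x2 chi-square
association between miRNA and mRNA compartments, targeting-frequency
profiles along the polysome/RNP axis, joint energy-position summaries, and
decision-tree mining of the binding-site distance threshold that separates
RNP- from polysome-destined targets.

The Wilcoxon rank-sum p-value is exact (classic count recurrence for the
null distribution of U) whenever both groups are small (n_a + n_b <= 10)
and tie-free; otherwise the tie-corrected normal approximation is used.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "PositionComparison",
    "AssociationResult",
    "rank_sum_test",
    "compare_distributions",
    "compartment_association",
    "targeting_frequency_profile",
    "energy_position_summary",
    "position_threshold_discovery",
]

EXACT_RANKSUM_MAX_N = 10


@dataclass
class PositionComparison:
    """Two-group comparison: group means with t and Wilcoxon p-values."""

    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    p_t: float
    p_wilcoxon: float
    p_t_log: float | None = None


@dataclass
class AssociationResult:
    """2x2 contingency association (Pearson chi-square and odds ratio)."""

    table: np.ndarray
    chi2: float
    p_value: float
    odds_ratio: float
    degenerate: bool = False


# --- Wilcoxon rank-sum -------------------------------------------------


@lru_cache(maxsize=None)
def _u_count(m: int, n: int, u: int) -> int:
    """Number of label arrangements of m+n tie-free values with U statistic u."""
    if u < 0 or u > m * n:
        return 0
    if m == 0 or n == 0:
        return 1 if u == 0 else 0
    return _u_count(m - 1, n, u - n) + _u_count(m, n - 1, u)


def _exact_u_tails(m: int, n: int, u: int) -> tuple[float, float]:
    total = math.comb(m + n, m)
    cdf = sum(_u_count(m, n, k) for k in range(0, u + 1)) / total
    sf = sum(_u_count(m, n, k) for k in range(u, m * n + 1)) / total
    return cdf, sf


def rank_sum_test(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two-sided",
) -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``alternative='less'`` tests a shifted-down ``a``; 'greater' the
    reverse. Exact for small tie-free samples, otherwise the tie-corrected
    normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    m, n = len(a), len(b)
    values = np.concatenate([a, b])
    has_ties = len(np.unique(values)) < len(values)
    if m + n <= EXACT_RANKSUM_MAX_N and not has_ties:
        u = int(sum(1 for x in a for y in b if x > y))
        cdf, sf = _exact_u_tails(m, n, u)
        if alternative == "less":
            return min(1.0, cdf)
        if alternative == "greater":
            return min(1.0, sf)
        return min(1.0, 2.0 * min(cdf, sf))
    res = _st.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return float(res.pvalue)


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(_st.ttest_ind(a, b, equal_var=False).pvalue)


def compare_distributions(
    values_a: Sequence[float], values_b: Sequence[float]
) -> PositionComparison:
    """Welch t-test cross-validated by Wilcoxon rank-sum, two-sided.

    When all values are positive a Welch t on the log values is also
    reported (``p_t_log``), reflecting the approximate lognormality of most
    of the quantities this package compares.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    p_t = _welch_p(a, b)
    p_w = rank_sum_test(a, b)
    p_t_log = None
    if (a > 0).all() and (b > 0).all():
        p_t_log = _welch_p(np.log(a), np.log(b))
    return PositionComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=len(a),
        n_b=len(b),
        p_t=p_t,
        p_wilcoxon=p_w,
        p_t_log=p_t_log,
    )


# --- compartment association -------------------------------------------


def association_2x2(table: np.ndarray, yates: bool = False) -> AssociationResult:
    """Pearson chi-square (no continuity correction by default) and odds
    ratio (Haldane 0.5 correction when any cell is zero) for a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return AssociationResult(t, 0.0, math.nan, math.nan, degenerate=True)
    chi2, p, _, _ = _st.chi2_contingency(t, correction=yates)
    h = t + 0.5 if (t == 0).any() else t
    odds = (h[0, 0] * h[1, 1]) / (h[0, 1] * h[1, 0])
    return AssociationResult(t, float(chi2), float(p), float(odds))


def compartment_association(
    mirna_classes: Mapping[str, str],
    mrna_classes: Mapping[str, str],
    target_map: pd.DataFrame,
    yates: bool = False,
    site_types: Sequence[str] | None = None,
) -> AssociationResult:
    """Association between mRNA compartment and RNP-miRNA targeting.

    Builds the 2x2 table (mRNA class RNP / POLYSOME) x (targeted by >=1
    RNP-enriched miRNA: yes / no) and applies the Pearson chi-square. Sites
    may be restricted to given ``site_types`` (e.g. high-confidence 8mers).
    """
    if not mirna_classes or not mrna_classes:
        raise ValueError("both class maps must be non-empty")
    rnp_mirnas = {i for i, c in mirna_classes.items() if c == "RNP"}
    tm = target_map
    if site_types is not None and len(tm):
        tm = tm[tm["site_type"].isin(site_types)]
    targeted = set(tm.loc[tm["mirna_id"].isin(rnp_mirnas), "transcript_id"])
    table = np.zeros((2, 2))
    for tid, cls in mrna_classes.items():
        if cls not in ("RNP", "POLYSOME"):
            continue
        row = 0 if cls == "RNP" else 1
        col = 0 if tid in targeted else 1
        table[row, col] += 1
    return association_2x2(table, yates=yates)


# --- targeting-frequency profile ---------------------------------------


def targeting_frequency_profile(
    target_map: pd.DataFrame,
    mrna_log2_ratio: pd.Series,
    mirna_classes: Mapping[str, str],
    bins: int = 20,
    site_types: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean per-mRNA site counts along the log2(polysome/RNP) axis.

    For each bin of the mRNA log2 ratio, the mean number of distinct
    (miRNA, site) hits by RNP-enriched and by polysome-enriched miRNAs.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    tm = target_map
    if site_types is not None and len(tm):
        tm = tm[tm["site_type"].isin(site_types)]
    rnp = {i for i, c in mirna_classes.items() if c == "RNP"}
    pol = {i for i, c in mirna_classes.items() if c == "POLYSOME"}
    counts = pd.DataFrame(index=mrna_log2_ratio.index)
    if len(tm):
        per = tm.groupby("transcript_id")["mirna_id"]
        counts["rnp_hits"] = per.apply(lambda s: int(s.isin(rnp).sum()))
        counts["polysome_hits"] = per.apply(lambda s: int(s.isin(pol).sum()))
    for col in ("rnp_hits", "polysome_hits"):
        if col not in counts:
            counts[col] = 0.0
    counts = counts.reindex(mrna_log2_ratio.index).fillna(0.0)
    lo, hi = float(mrna_log2_ratio.min()), float(mrna_log2_ratio.max())
    if lo == hi:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, bins + 1)
    which = np.clip(np.digitize(mrna_log2_ratio.to_numpy(), edges) - 1, 0, bins - 1)
    rows = []
    for k in range(bins):
        mask = which == k
        rows.append(
            {
                "bin_left": edges[k],
                "bin_right": edges[k + 1],
                "n_mrnas": int(mask.sum()),
                "mean_rnp_mirna_hits": float(counts["rnp_hits"][mask].mean())
                if mask.any()
                else 0.0,
                "mean_polysome_mirna_hits": float(
                    counts["polysome_hits"][mask].mean()
                )
                if mask.any()
                else 0.0,
            }
        )
    return pd.DataFrame(rows)


# --- energy vs position -------------------------------------------------


def energy_position_summary(
    sites: pd.DataFrame,
    groups: Sequence[str],
    grid_bins: int = 25,
) -> dict:
    """Per-group joint summary of |energy| and distance to the stop codon.

    ``groups`` labels each row of ``sites``. Returns per-group means, a 2-D
    density grid per group, and (for exactly two groups) two-sided
    comparisons on both axes.
    """
    if "abs_energy" not in sites or "distance_to_stop" not in sites:
        raise ValueError("sites need abs_energy and distance_to_stop columns")
    g = pd.Series(list(groups), index=sites.index, name="group")
    labels = sorted(g.unique())
    summary = []
    density = {}
    for lab in labels:
        sub = sites[g == lab]
        summary.append(
            {
                "group": lab,
                "n_sites": len(sub),
                "mean_abs_energy": float(sub["abs_energy"].mean()),
                "mean_distance": float(sub["distance_to_stop"].mean()),
            }
        )
        H, xe, ye = np.histogram2d(
            sub["distance_to_stop"], sub["abs_energy"], bins=grid_bins
        )
        density[lab] = {"grid": H, "distance_edges": xe, "energy_edges": ye}
    out = {"summary": pd.DataFrame(summary).set_index("group"), "density": density}
    if len(labels) == 2:
        a = sites[g == labels[0]]
        b = sites[g == labels[1]]
        if len(a) >= 2 and len(b) >= 2:
            out["distance_comparison"] = compare_distributions(
                a["distance_to_stop"], b["distance_to_stop"]
            )
            out["energy_comparison"] = compare_distributions(
                a["abs_energy"], b["abs_energy"]
            )
    return out


# --- decision-tree position-threshold mining ---------------------------


def position_threshold_discovery(
    features: pd.DataFrame,
    labels: Sequence[str],
    n_trees: int = 200,
    max_depth: int = 3,
    cv: int = 5,
    stump: bool = False,
    seed: int = 0,
) -> dict:
    """Mine the distance-to-stop threshold separating site compartments.

    Fits bootstrap + feature-subsampled depth-limited trees over whatever
    feature columns are supplied (``distance_to_stop`` required; typically
    also ``abs_energy``, ``site_type`` and ``utr3_length``) and reports the
    modal split threshold on distance, a permutation importance for the
    distance feature, and k-fold cross-validated accuracy. ``stump=True``
    fits a single depth-1 tree on distance alone, which is deterministic
    given the data.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.inspection import permutation_importance
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.tree import DecisionTreeClassifier

    if "distance_to_stop" not in features:
        raise ValueError("features must include distance_to_stop")
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two site classes")
    X = features.copy()
    if "site_type" in X and X["site_type"].dtype == object:
        X["site_type"] = pd.Categorical(X["site_type"]).codes
    X = X.astype(float)
    dist_idx = list(X.columns).index("distance_to_stop")

    if stump:
        model = DecisionTreeClassifier(max_depth=1, random_state=seed)
        model.fit(X[["distance_to_stop"]], y)
        tree = model.tree_
        thresholds = [float(tree.threshold[0])] if tree.feature[0] == 0 else []
        cv_model = model
        cv_X = X[["distance_to_stop"]]
    else:
        model = RandomForestClassifier(
            n_estimators=n_trees,
            max_depth=max_depth,
            max_features="sqrt",
            random_state=seed,
        )
        model.fit(X, y)
        thresholds = []
        for est in model.estimators_:
            t = est.tree_
            for node in range(t.node_count):
                if t.feature[node] == dist_idx:
                    thresholds.append(float(t.threshold[node]))
        cv_model = RandomForestClassifier(
            n_estimators=n_trees,
            max_depth=max_depth,
            max_features="sqrt",
            random_state=seed,
        )
        cv_X = X

    if thresholds:
        rounded = Counter(int(round(t)) for t in thresholds)
        top = max(rounded.values())
        threshold = float(min(k for k, v in rounded.items() if v == top))
    else:
        threshold = math.nan

    n_splits = int(min(cv, counts.min()))
    if n_splits >= 2:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        acc = float(np.mean(cross_val_score(cv_model, cv_X, y, cv=skf)))
    else:
        acc = math.nan

    perm = permutation_importance(
        model,
        X[["distance_to_stop"]] if stump else X,
        y,
        n_repeats=10,
        random_state=seed,
    )
    imp = float(perm.importances_mean[0 if stump else dist_idx])
    return {
        "threshold": threshold,
        "distance_importance": imp,
        "cv_accuracy": acc,
        "n_per_class": {c: int(k) for c, k in zip(classes, counts)},
    }
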