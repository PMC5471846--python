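"""Count tables and between-sample normalization.

Samples are keyed ``<stage>_<fraction>_rep<k>`` (e.g. ``round_RNP_rep2``).
Four normalization routes are provided, mirroring common RNA-seq practice
for fractionation experiments:

* internal-control linear regression — per sample, a zero-intercept least
  squares fit of that sample's control-gene counts against a reference
  sample's; the fitted slope is the scale factor. Appropriate when a panel
  of genes is known a priori to distribute equally between fractions.
* geometric-median (median-of-ratios against the per-entity geometric mean);
* median-of-ratios size factors (the DESeq-style estimator, numerically the
  same statistic exposed separately with a pseudocount escape hatch);
* quantile normalization (sorted values replaced by cross-sample rank
  means).

An expression floor removes entities below a detection threshold in every
sample.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SampleKey",
    "CountTable",
    "ScaleFactors",
    "control_regression_norm",
    "geometric_median_norm",
    "size_factor_norm",
    "quantile_norm",
    "expression_floor",
    "apply_factors",
]

_SAMPLE_RE = re.compile(r"^(?P<stage>.+)_(?P<fraction>RNP|polysome)_rep(?P<rep>\d+)$")


class SampleKey(NamedTuple):
    stage: str
    fraction: str
    replicate: int

    def __str__(self) -> str:
        return f"{self.stage}_{self.fraction}_rep{self.replicate}"


def parse_sample(name: str) -> SampleKey:
    m = _SAMPLE_RE.match(name)
    if not m:
        raise ValueError(
            f"sample {name!r} does not match <stage>_<RNP|polysome>_rep<k>"
        )
    return SampleKey(m["stage"], m["fraction"], int(m["rep"]))


@dataclass
class CountTable:
    """Non-negative expression values, entities x samples.

    Thin wrapper over a DataFrame whose index holds unique entity ids and
    whose columns are parseable sample keys.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            raise ValueError("duplicate entity ids")
        if self.df.columns.has_duplicates:
            raise ValueError("duplicate sample keys")
        if (self.df.to_numpy() < 0).any():
            raise ValueError("negative values in count table")
        for c in self.df.columns:
            parse_sample(c)  # validates

    @property
    def samples(self) -> list[SampleKey]:
        return [parse_sample(c) for c in self.df.columns]

    @property
    def stages(self) -> list[str]:
        seen: list[str] = []
        for k in self.samples:
            if k.stage not in seen:
                seen.append(k.stage)
        return seen

    def columns_for(self, stage: str | None = None, fraction: str | None = None) -> list[str]:
        out = []
        for c in self.df.columns:
            k = parse_sample(c)
            if stage is not None and k.stage != stage:
                continue
            if fraction is not None and k.fraction != fraction:
                continue
            out.append(c)
        return out

    def select(self, stage: str | None = None, fraction: str | None = None) -> pd.DataFrame:
        return self.df[self.columns_for(stage, fraction)]


@dataclass
class ScaleFactors:
    """Per-sample positive scale factors and the method that produced them."""

    factors: pd.Series
    method: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any() or not np.isfinite(self.factors).all():
            raise ValueError("scale factors must be positive and finite")


def apply_factors(table: CountTable, sf: ScaleFactors) -> CountTable:
    """Divide each sample by its scale factor."""
    return CountTable(table.df.div(sf.factors[table.df.columns], axis=1))


def control_regression_norm(
    table: CountTable,
    control_ids: Iterable[str],
    reference_sample: str,
) -> tuple[ScaleFactors, CountTable]:
    """Internal-control zero-intercept regression normalization.

    For each sample the slope of ``sample ~ 0 + reference`` over the usable
    control entities (present, nonzero in all samples) is the scale factor;
    the reference sample's factor is 1 by construction.
    """
    ctrl = [i for i in control_ids if i in table.df.index]
    sub = table.df.loc[ctrl]
    usable = sub.index[(sub > 0).all(axis=1)]
    if len(usable) < 3:
        raise ValueError(
            f"need >=3 controls with nonzero counts in all samples, have {len(usable)}"
        )
    sub = sub.loc[usable]
    if reference_sample not in table.df.columns:
        raise ValueError(f"reference sample {reference_sample!r} not in table")
    x = sub[reference_sample].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero-variance control counts in reference sample")
    denom = float(np.dot(x, x))
    factors = {}
    for c in sub.columns:
        y = sub[c].to_numpy(dtype=float)
        factors[c] = float(np.dot(x, y) / denom)
    sf = ScaleFactors(pd.Series(factors)[table.df.columns], "control_regression")
    return sf, apply_factors(table, sf)


def _nonzero_reference(df: pd.DataFrame, pseudocount: float | None, what: str) -> pd.DataFrame:
    if pseudocount is not None:
        logger.info("applying pseudocount %g for %s", pseudocount, what)
        return df + pseudocount
    sub = df.loc[(df > 0).all(axis=1)]
    if sub.empty:
        raise ValueError(
            f"no entity with nonzero counts in every sample for {what}; "
            "consider the pseudocount option"
        )
    return sub


def geometric_median_norm(
    table: CountTable, pseudocount: float | None = None
) -> ScaleFactors:
    """Median over entities of value / per-entity geometric mean.

    Entities with a zero in any sample are excluded from the reference set.
    """
    sub = _nonzero_reference(table.df, pseudocount, "geometric-median normalization")
    logged = np.log(sub.to_numpy(dtype=float))
    geomean = logged.mean(axis=1)
    ratios = np.exp(logged - geomean[:, None])
    factors = pd.Series(np.median(ratios, axis=0), index=sub.columns)
    return ScaleFactors(factors, "geometric_median")


def size_factor_norm(
    table: CountTable, pseudocount: float | None = None
) -> tuple[ScaleFactors, CountTable]:
    """Median-of-ratios (DESeq-style) size factors, plus the scaled table."""
    sf = geometric_median_norm(table, pseudocount=pseudocount)
    sf = ScaleFactors(sf.factors, "size_factor")
    return sf, apply_factors(table, sf)


def quantile_norm(table: CountTable) -> CountTable:
    """Replace each sample's sorted values by cross-sample rank means.

    Ties within a sample receive the average of the rank-mean values over
    their tied ranks (fractional ranks are linearly interpolated).
    """
    X = table.df.to_numpy(dtype=float)
    n, p = X.shape
    sorted_means = np.sort(X, axis=0).mean(axis=1)
    from scipy.stats import rankdata

    out = np.empty_like(X)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(p):
        ranks = rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, sorted_means)
    return CountTable(pd.DataFrame(out, index=table.df.index, columns=table.df.columns))


def expression_floor(table: CountTable, threshold: float) -> CountTable:
    """Drop entities whose value is below ``threshold`` in every sample."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = (table.df >= threshold).any(axis=1)
    removed = int((~keep).sum())
    if removed:
        logger.info("expression floor %g removed %d entities", threshold, removed)
    return CountTable(table.df.loc[keep])
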