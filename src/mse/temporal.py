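"""Yearly novelty-trend analytics.

Builds cumulative accumulation curves of total and novel samples per
category, fits ordinary-least-squares slopes to the novel-sample ratios,
compares the observed novelty-score distribution against a matched
simulated normal, and correlates novelty with Shannon alpha-diversity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .similarity import shannon_index


@dataclass
class YearlySeries:
    """Cumulative totals, novel counts and their ratio for one category."""

    grouping: str
    years: list[int]
    totals: list[int]
    novel_counts: list[int]

    @property
    def ratio(self) -> list[float]:
        return [n / t if t else 0.0 for n, t in zip(self.novel_counts, self.totals)]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "total": self.totals,
                "novel": self.novel_counts,
                "ratio": self.ratio,
                "grouping": self.grouping,
            }
        )


@dataclass
class NormalityReport:
    """Agreement of observed values with a matched simulated normal draw."""

    pearson_r: float
    t_test_p: float
    n_bins: int
    seed: int | None
    year: int | None = None


def yearly_series(frame: pd.DataFrame, group_by: str | None = None) -> list[YearlySeries]:
    """Cumulative accumulation curves from a scored sample table.

    `frame` needs columns ``year`` and ``is_novel`` (as produced by
    :func:`mse.scores.panel_frame` joined with metadata) plus the optional
    grouping column (e.g. ``habitat``). Samples without a year are excluded.
    """
    if "year" not in frame.columns or "is_novel" not in frame.columns:
        raise ValidationError("frame needs 'year' and 'is_novel' columns")
    frame = frame[frame["year"].notna()].copy()
    frame["year"] = frame["year"].astype(int)

    def one(group: pd.DataFrame, label: str) -> YearlySeries:
        per_year = group.groupby("year").agg(total=("is_novel", "size"), novel=("is_novel", "sum"))
        per_year = per_year.sort_index()
        return YearlySeries(
            grouping=label,
            years=[int(y) for y in per_year.index],
            totals=[int(v) for v in per_year["total"].cumsum()],
            novel_counts=[int(v) for v in per_year["novel"].cumsum()],
        )

    if group_by is None:
        return [one(frame, "all")]
    if group_by not in frame.columns:
        raise ValidationError(f"no column {group_by!r} to group by")
    return [one(g, str(label)) for label, g in frame.groupby(group_by, sort=True)]


def ratio_slope(series: YearlySeries) -> float:
    """OLS slope (per calendar year) of the novel-sample ratio."""
    if len(series.years) < 2:
        raise ValidationError("ratio_slope needs at least two years")
    result = stats.linregress(series.years, series.ratio)
    return float(result.slope)


def normality_report(
    values,
    n_bins: int | None = None,
    seed: int | None = None,
    year: int | None = None,
    simulated=None,
) -> NormalityReport:
    """Compare observed score values with a simulated normal sample.

    A normal sample of equal size is drawn (seeded) with the observed mean
    and standard deviation; the figure-style overlay comparison is a Pearson
    correlation between observed and simulated bin frequencies on shared
    bins (Sturges' rule by default), and the distribution test is a
    two-tailed Welch two-sample t test. Pass ``simulated`` to bypass the
    draw (e.g. for an exact self-comparison).
    """
    values = np.asarray(list(values), dtype=float)
    if values.size < 30:
        raise ValidationError(f"normality_report needs >= 30 values, got {values.size}")
    if simulated is None:
        rng = np.random.default_rng(seed)
        simulated = rng.normal(values.mean(), values.std(ddof=1), values.size)
    simulated = np.asarray(simulated, dtype=float)
    if n_bins is None:
        n_bins = int(np.ceil(np.log2(values.size)) + 1)  # Sturges
    edges = np.histogram_bin_edges(np.concatenate([values, simulated]), bins=n_bins)
    f_obs, _ = np.histogram(values, bins=edges)
    f_sim, _ = np.histogram(simulated, bins=edges)
    r = stats.pearsonr(f_obs, f_sim).statistic
    p = stats.ttest_ind(values, simulated, equal_var=False).pvalue
    return NormalityReport(
        pearson_r=float(r), t_test_p=float(p), n_bins=int(n_bins), seed=seed, year=year
    )


def mns_shannon_correlation(panels, profiles, phylo, level: str = "genus") -> float:
    """Spearman correlation between per-sample novelty and Shannon diversity.

    `panels` is the list of :class:`~mse.scores.ScorePanel`; `profiles` the
    matching :class:`~mse.profiles.MicrobiomeProfile` objects (any order;
    joined on sample id).
    """
    mns_by_id = {p.sample_id: p.mns for p in panels}
    pairs = [
        (mns_by_id[p.sample_id], shannon_index(p, phylo, level))
        for p in profiles
        if p.sample_id in mns_by_id
    ]
    if len(pairs) < 3:
        raise ValidationError("need at least 3 samples for a rank correlation")
    x, y = zip(*pairs)
    return float(stats.spearmanr(x, y).statistic)
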