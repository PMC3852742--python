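"""Site-level differential statistics.

The test follows the label-free phospho-proteomics convention of this
pipeline's study design: abundances are arcsinh transformed (variance
stabilizing and defined at zero), group differences are assessed with a
two-tailed independent-samples t-test on the transformed values, while fold
changes are the ratio of *raw* within-group means. A site is called up when
p < p_threshold and fold change > fc_up (strict), down when p < p_threshold
and fold change < fc_down (strict); otherwise not significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantio import PhosphoSiteKey, SiteQuantTable


def arcsinh_transform(x):
    """Inverse hyperbolic sine, ln(x + sqrt(x^2 + 1)), for non-negative input."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("abundances must be non-negative")
    return np.arcsinh(x)


@dataclass(frozen=True)
class DifferentialCriteria:
    """Significance and effect-size thresholds (all strict inequalities)."""

    p_threshold: float = 0.05
    fc_up: float = 1.5
    fc_down: float = 0.67
    min_replicates: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if not self.fc_down < 1 < self.fc_up:
            raise ValueError("need fc_down < 1 < fc_up")
        if self.min_replicates < 2:
            raise ValueError("min_replicates must be >= 2")


@dataclass(frozen=True)
class DifferentialResult:
    site: PhosphoSiteKey
    mean_parent: Optional[float]
    mean_ox: Optional[float]
    fold_change: Optional[float]
    p_value: Optional[float]
    t_statistic: Optional[float]
    df: Optional[float]
    site_class: str  # up / down / ns / untested


def _ttest(x: np.ndarray, y: np.ndarray, equal_var: bool) -> tuple[float, float, float]:
    """Two-tailed independent t-test with a defined zero-variance limit.

    When both groups have zero variance the usual statistic is 0/0; we take
    t=0, p=1 for equal means and |t|=inf, p=0 for distinct means (the
    separation is perfect).
    """
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        df = len(x) + len(y) - 2
        if np.isclose(x.mean(), y.mean()):
            return 0.0, 1.0, df
        return math.copysign(math.inf, y.mean() - x.mean()), 0.0, df
    res = stats.ttest_ind(y, x, equal_var=equal_var)
    if equal_var:
        df = len(x) + len(y) - 2
    else:
        df = float(res.df)
    return float(res.statistic), float(res.pvalue), float(df)


def differential_test(
    parent_values: Sequence[float],
    ox_values: Sequence[float],
    criteria: DifferentialCriteria = DifferentialCriteria(),
    site: PhosphoSiteKey | None = None,
    equal_var: bool = True,
) -> DifferentialResult:
    """Test one site: t-test on arcsinh values, fold change on raw means."""
    site = site or PhosphoSiteKey("?", (1,))
    x = np.asarray(parent_values, dtype=float)
    y = np.asarray(ox_values, dtype=float)
    if len(x) < criteria.min_replicates or len(y) < criteria.min_replicates:
        return DifferentialResult(site, None, None, None, None, None, None, "untested")

    t, p, df = _ttest(arcsinh_transform(x), arcsinh_transform(y), equal_var)
    mean_parent = float(x.mean())
    mean_ox = float(y.mean())
    fc = mean_ox / mean_parent if mean_parent > 0 else math.inf if mean_ox > 0 else math.nan

    if p < criteria.p_threshold and fc > criteria.fc_up:
        cls = "up"
    elif p < criteria.p_threshold and fc < criteria.fc_down:
        cls = "down"
    else:
        cls = "ns"
    return DifferentialResult(site, mean_parent, mean_ox, fc, p, t, df, cls)


@dataclass
class DifferentialTable:
    results: list[DifferentialResult]
    criteria: DifferentialCriteria

    @property
    def n_total(self) -> int:
        return len(self.results)

    def _count(self, cls: str) -> int:
        return sum(1 for r in self.results if r.site_class == cls)

    @property
    def n_up(self) -> int:
        return self._count("up")

    @property
    def n_down(self) -> int:
        return self._count("down")

    @property
    def n_ns(self) -> int:
        return self._count("ns")

    @property
    def n_untested(self) -> int:
        return self._count("untested")

    def sites_of_class(self, cls: str) -> set[PhosphoSiteKey]:
        return {r.site for r in self.results if r.site_class == cls}

    @property
    def up_sites(self) -> set[PhosphoSiteKey]:
        return self.sites_of_class("up")

    @property
    def down_sites(self) -> set[PhosphoSiteKey]:
        return self.sites_of_class("down")

    def fold_changes(self) -> dict[PhosphoSiteKey, float]:
        return {
            r.site: r.fold_change
            for r in self.results
            if r.fold_change is not None and math.isfinite(r.fold_change)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "site": r.site.label,
                    "mean_parent": r.mean_parent,
                    "mean_ox": r.mean_ox,
                    "fold_change": r.fold_change,
                    "p_value": r.p_value,
                    "t_statistic": r.t_statistic,
                    "df": r.df,
                    "class": r.site_class,
                }
                for r in self.results
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def classify_partition(
    table: SiteQuantTable,
    criteria: DifferentialCriteria = DifferentialCriteria(),
    group_parent: str = "parent",
    group_ox: str = "CK1tau-OX",
    equal_var: bool = True,
) -> DifferentialTable:
    """Run the differential test over every site of a collated table.

    Sites with fewer than ``criteria.min_replicates`` observed values in
    either condition are reported as untested; the four classes always
    partition the table.
    """
    results: list[DifferentialResult] = []
    groups = (
        set(table.data.columns.get_level_values("group")) if not table.data.empty else set()
    )
    for key in table.sites:
        x = table.group_values(key, group_parent) if group_parent in groups else np.array([])
        y = table.group_values(key, group_ox) if group_ox in groups else np.array([])
        results.append(differential_test(x, y, criteria, site=key, equal_var=equal_var))
    return DifferentialTable(results, criteria)


def volcano_frame(dt: DifferentialTable) -> pd.DataFrame:
    """log2 fold change vs -log10 p for each tested site (volcano-plot data)."""
    rows = []
    for r in dt.results:
        if r.site_class == "untested" or not r.fold_change or not math.isfinite(r.fold_change):
            continue
        rows.append(
            {
                "site": r.site.label,
                "log2_fc": math.log2(r.fold_change) if r.fold_change > 0 else math.nan,
                "neg_log10_p": -math.log10(r.p_value) if r.p_value > 0 else math.inf,
                "class": r.site_class,
            }
        )
    return pd.DataFrame(rows, columns=["site", "log2_fc", "neg_log10_p", "class"])


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Optional BH-adjusted p-values (not applied by default anywhere)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
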