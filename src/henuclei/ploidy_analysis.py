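"""Feature-vs-ploidy statistics.

The exemplar downstream analysis: per-sample summaries (median and variance
of each nuclear feature over neoplastic nuclei) are correlated with the
sample's genomic ploidy using Spearman's rank correlation, and a one-way
ANOVA tests whether ploidy differs between the three anatomical tumour
sites (omentum, peritoneum, tubo-ovarian).  Ploidy enters purely as an
input column — it is estimated upstream from whole-genome sequencing by
published tools outside this package.

Outlier samples (e.g. slides with technical tissue artifacts) are excluded
only by explicit caller-supplied sample ids; exclusions are recorded in the
reports, never silent.  No multiple-testing correction is applied across
the feature x statistic tests; p-values are reported raw.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationReport", "spearman", "correlate_features", "site_anova", "SITES"]

SITES = ("omentum", "peritoneum", "tubo-ovarian")


@dataclass
class CorrelationReport:
    feature: str
    statistic: str  # "median" | "variance"
    rho: float
    p_value: float
    n: int
    excluded: tuple[str, ...] = field(default_factory=tuple)


def spearman(x, y, method: str = "t") -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks (average ranks on ties).
    The p-value uses the t approximation t = rho*sqrt((n-2)/(1-rho^2)) on
    n-2 degrees of freedom (``method="t"``, the default of common
    statistical software), or an exact permutation distribution over all
    rank orderings (``method="exact"``, only for n <= 10).

    Raises on length mismatch, n < 4, or a constant input vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation is undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "exact":
        if n > 10:
            raise ValueError("exact permutation p only supported for n <= 10")
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def _pivot(table: pd.DataFrame) -> pd.DataFrame:
    required = {"sample", "site", "feature", "median", "variance", "ploidy"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"summary table is missing columns: {sorted(missing)}")
    return table


def correlate_features(
    table: pd.DataFrame,
    exclude: tuple[str, ...] = (),
) -> dict[str, list[CorrelationReport]]:
    """Spearman correlation of each feature summary with ploidy.

    ``table`` is long-format with columns
    ``sample, site, feature, median, variance, ploidy``.  For every feature
    present and each of the two summary statistics, the correlation against
    ploidy is computed twice: over all samples (``"all"``) and after
    removing the caller-specified outlier samples (``"filtered"``).  With an
    empty exclusion list the two report sets are identical.

    Raises if an excluded id is not present in the table.
    """
    table = _pivot(table)
    samples = set(table["sample"])
    for sid in exclude:
        if sid not in samples:
            raise ValueError(f"excluded sample {sid!r} not present in the table")

    def reports(df: pd.DataFrame, excluded: tuple[str, ...]) -> list[CorrelationReport]:
        out = []
        for feat, grp in df.groupby("feature", sort=True):
            grp = grp.sort_values("sample")
            if len(grp) < 4:
                raise ValueError(f"fewer than 4 samples for feature {feat!r}")
            for statistic in ("median", "variance"):
                rho, p = spearman(grp[statistic].to_numpy(), grp["ploidy"].to_numpy())
                out.append(
                    CorrelationReport(
                        feature=str(feat), statistic=statistic, rho=rho, p_value=p,
                        n=len(grp), excluded=excluded,
                    )
                )
        return out

    kept = table[~table["sample"].isin(exclude)]
    return {
        "all": reports(table, ()),
        "filtered": reports(kept, tuple(exclude)),
    }


def site_anova(table: pd.DataFrame) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of ploidy on anatomical site.

    The long-format table repeats each sample's ploidy per feature row, so
    samples are deduplicated first.  Returns (F, p) with p from the F
    distribution; a completely flat ploidy column yields F = 0, p = 1.

    Raises if fewer than 2 sites have at least 2 samples each.
    """
    table = _pivot(table)
    per_sample = table.drop_duplicates("sample")
    groups = [g["ploidy"].to_numpy(dtype=float) for _, g in per_sample.groupby("site")]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 sites with >= 2 samples each")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = all_vals.size - len(groups)
    if ssb == 0:
        return 0.0, 1.0
    if ssw == 0:
        return float("inf"), 0.0
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p
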