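"""Percent lesion length (PLL) computation and aggregation.

PLL is the fire-blight susceptibility phenotype: necrotic shoot length
divided by total shoot length, times 100. Shoot-level values are
averaged to genotype x year means, then to an overall per-genotype
mean across years (mean of year means, so unequal replicate counts do
not bias a year; a pooled mode is available).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ["genotype_id", "year", "replicate", "shoot_length_mm", "necrosis_length_mm"]


def pll(necrosis_length: float, shoot_length: float) -> float:
    """Percent lesion length of one shoot: 100 * necrosis / shoot length."""
    if shoot_length <= 0:
        raise ValueError(f"shoot_length must be > 0 (got {shoot_length})")
    if necrosis_length < 0:
        raise ValueError("necrosis_length must be >= 0")
    if necrosis_length > shoot_length:
        raise ValueError(
            f"necrosis_length {necrosis_length} exceeds shoot_length {shoot_length}"
        )
    return 100.0 * necrosis_length / shoot_length


def aggregate_pll(measurements: pd.DataFrame, pooled: bool = False) -> pd.DataFrame:
    """Aggregate shoot measurements to per-genotype mean PLL.

    Returns a DataFrame indexed by genotype_id with one ``pll_<year>``
    column per year present and a ``pll_mean`` column. By default the
    overall mean is the unweighted mean of the available year means;
    ``pooled=True`` averages all shoots directly.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in measurements.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    df = measurements.copy()
    if (df["shoot_length_mm"] <= 0).any():
        raise ValueError("non-positive shoot length in measurements")
    if (df["necrosis_length_mm"] > df["shoot_length_mm"]).any():
        raise ValueError("necrosis longer than shoot in measurements")
    df["pll"] = 100.0 * df["necrosis_length_mm"] / df["shoot_length_mm"]

    year_means = df.groupby(["genotype_id", "year"])["pll"].mean().unstack("year")
    out = year_means.rename(columns=lambda y: f"pll_{y}")
    if pooled:
        out["pll_mean"] = df.groupby("genotype_id")["pll"].mean()
    else:
        out["pll_mean"] = year_means.mean(axis=1)  # skips absent years
    return out


def year_correlation(aggregated: pd.DataFrame, year_a: int, year_b: int,
                     method: str = "pearson") -> float:
    """Between-year correlation of genotype mean PLL.

    Uses genotypes with means in both years; requires at least 3 such
    pairs and non-constant vectors. ``method`` is "pearson" (default)
    or "spearman".
    """
    ca, cb = f"pll_{year_a}", f"pll_{year_b}"
    for c in (ca, cb):
        if c not in aggregated.columns:
            raise ValueError(f"missing year column {c}")
    paired = aggregated[[ca, cb]].dropna()
    if len(paired) < 3:
        raise ValueError(f"need >=3 genotypes with both years (got {len(paired)})")
    x, y = paired[ca].to_numpy(), paired[cb].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant year vector")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")
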