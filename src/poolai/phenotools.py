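"""Phenotype-side computations: whiteness index, divergent-family
selection, and group summary statistics.

The unit of summary is the family average: groups are formed by ranking
family means for a trait and contrasting the top- against the
bottom-ranked families, and group means/SDs are computed over those family
averages (not over individual fish).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from poolai.imbalance import TraitDesign


def whiteness_index(L: float, a: float, b: float) -> float:
    """Fillet whiteness from colorimeter L* (lightness), a* (redness),
    b* (yellowness):

        whiteness = 100 - sqrt((100 - L)^2 + a^2 + b^2)

    A perfectly white sample (L=100, a=b=0) scores 100; the index is
    monotone increasing in L and decreasing in |a| and |b|.
    """
    return 100.0 - math.sqrt((100.0 - L) ** 2 + a**2 + b**2)


def select_divergent_families(
    family_means: pd.Series | dict[str, float],
    trait: str,
    n_high: int = 4,
    n_low: int = 4,
) -> TraitDesign:
    """Rank families by trait mean and contrast top n_high vs bottom n_low.

    Ties are broken by family id, so selection is deterministic and
    invariant to input ordering.  Raises if the two selections would
    overlap (n_high + n_low exceeds the number of families).
    """
    means = pd.Series(family_means, dtype=float)
    if n_high < 1 or n_low < 1:
        raise ValueError("n_high and n_low must be positive")
    if n_high + n_low > len(means):
        raise ValueError(
            f"cannot pick {n_high}+{n_low} disjoint families from {len(means)}"
        )
    df = means.rename("mean").rename_axis("family").reset_index()
    ranked = df.sort_values(["mean", "family"], ascending=[False, True])
    high = tuple(ranked["family"].iloc[:n_high])
    low = tuple(ranked["family"].iloc[-n_low:][::-1])
    return TraitDesign(trait, high_families=high, low_families=low)


@dataclass(frozen=True)
class GroupSummary:
    """Per-group mean +/- SD (from family averages) and a Welch test."""

    trait: str
    mean_high: float
    sd_high: float
    n_high: int
    mean_low: float
    sd_low: float
    n_low: int
    p_value: float

    def __str__(self) -> str:
        return (
            f"{self.trait}: {self.mean_high:.2f} +/- {self.sd_high:.2f} vs. "
            f"{self.mean_low:.2f} +/- {self.sd_low:.2f} (p={self.p_value:.3g})"
        )


def group_summary(
    design: TraitDesign, family_means: pd.Series | dict[str, float]
) -> GroupSummary:
    """Mean and sample SD (n-1) per group over family averages, plus a
    Welch two-sample t-test p-value for the group difference.

    Raises if either group has fewer than two families (SD undefined).
    """
    means = pd.Series(family_means, dtype=float)
    missing = (set(design.high_families) | set(design.low_families)) - set(means.index)
    if missing:
        raise KeyError(f"families without phenotype values: {sorted(missing)}")
    high = means.loc[list(design.high_families)].to_numpy()
    low = means.loc[list(design.low_families)].to_numpy()
    if len(high) < 2 or len(low) < 2:
        raise ValueError(f"{design.trait}: need >=2 families per group for SD")
    t = stats.ttest_ind(high, low, equal_var=False)
    return GroupSummary(
        trait=design.trait,
        mean_high=float(np.mean(high)),
        sd_high=float(np.std(high, ddof=1)),
        n_high=len(high),
        mean_low=float(np.mean(low)),
        sd_low=float(np.std(low, ddof=1)),
        n_low=len(low),
        p_value=float(t.pvalue),
    )
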