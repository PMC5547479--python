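"""The allelic-imbalance score, its classification, and the 2x2 chi-square.

For each SNP and each trait, read counts are summed over the high-ranked
families and over the low-ranked families.  Writing fA/fB for the
alternate/reference allele frequencies within a group, the AI score is

    score = (fA_high / fB_high) / (fA_low / fB_low),

i.e. the ratio of allele-frequency odds between groups.  It ranges over
(0, inf); a score >= 2.0 is called an amplification and <= 0.5 a loss of
heterozygosity.  When an allele is absent from exactly one group the score
is undefined (0 or inf) and the site is classified as exclusive to the
group that carries both alleles -- the "0.0/1.0" category.

Significance is assessed by a Pearson chi-square on the 2x2 table of
summed allele counts (high/low x allele A/B) without continuity
correction; sites with a zero marginal are reported as chi-square
undefined (the "counts for only one allele" stratum) rather than dropped.
"""

from __future__ import annotations

import enum
import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from poolai.variant_io import PooledSiteCount, SnpKey


class ImbalanceClass(enum.Enum):
    AMPLIFICATION = "amplification"
    LOH = "loss_of_heterozygosity"
    NONE = "none"
    EXCLUSIVE_HIGH = "exclusive_high"
    EXCLUSIVE_LOW = "exclusive_low"

    @property
    def is_imbalanced(self) -> bool:
        return self is not ImbalanceClass.NONE


class Exclusive(enum.Enum):
    """Score-undefined flag: the SNP segregates in only one group."""

    HIGH = "exclusive_high"
    LOW = "exclusive_low"


@dataclass(frozen=True)
class TraitDesign:
    """A trait contrast: which families form the high and low groups."""

    trait: str
    high_families: tuple[str, ...]
    low_families: tuple[str, ...]

    def __post_init__(self) -> None:
        high, low = set(self.high_families), set(self.low_families)
        if not high or not low:
            raise ValueError(f"{self.trait}: both groups must be non-empty")
        if high & low:
            raise ValueError(f"{self.trait}: groups overlap: {sorted(high & low)}")
        for name, group in (("high", high), ("low", low)):
            if not 1 <= len(group) <= 10:
                warnings.warn(
                    f"{self.trait}: {name} group has {len(group)} families, "
                    "outside the typical 3-5 per group",
                    stacklevel=2,
                )

    def swapped(self) -> "TraitDesign":
        return TraitDesign(self.trait, self.low_families, self.high_families)


@dataclass(frozen=True)
class GroupFrequencies:
    """Summed allele counts and frequencies per phenotype group.

    Allele A is the alternate allele, allele B the reference.  Because the
    classification thresholds are reciprocal (2.0 and 0.5), the labelling
    affects only which direction is called amplification versus loss of
    heterozygosity, never membership in the imbalanced set.
    """

    snp: SnpKey
    trait: str
    count_a_high: int
    count_b_high: int
    count_a_low: int
    count_b_low: int

    @property
    def total_high(self) -> int:
        return self.count_a_high + self.count_b_high

    @property
    def total_low(self) -> int:
        return self.count_a_low + self.count_b_low

    @property
    def fa_high(self) -> float:
        return self.count_a_high / self.total_high

    @property
    def fb_high(self) -> float:
        return self.count_b_high / self.total_high

    @property
    def fa_low(self) -> float:
        return self.count_a_low / self.total_low

    @property
    def fb_low(self) -> float:
        return self.count_b_low / self.total_low


class ZeroCoverageError(ValueError):
    """No reads in one or both groups at a site."""


def pool_group_frequencies(
    site_counts: Sequence[PooledSiteCount],
    design: TraitDesign,
) -> GroupFrequencies:
    """Sum one site's per-family counts into group totals for one trait.

    Group frequency is the frequency of the summed counts (not the mean of
    per-family frequencies), which keeps the chi-square on exact allele
    counts coherent with the score.
    """
    keys = {c.key for c in site_counts}
    if len(keys) != 1:
        raise ValueError(f"counts span multiple sites: {sorted(map(str, keys))}")
    (key,) = keys
    high = set(design.high_families)
    low = set(design.low_families)
    a_high = b_high = a_low = b_low = 0
    for c in site_counts:
        if c.family in high:
            a_high += c.alt_reads
            b_high += c.ref_reads
        elif c.family in low:
            a_low += c.alt_reads
            b_low += c.ref_reads
    if a_high + b_high == 0 or a_low + b_low == 0:
        raise ZeroCoverageError(f"{key}: zero coverage in a group for {design.trait}")
    return GroupFrequencies(key, design.trait, a_high, b_high, a_low, b_low)


def imbalance_score(g: GroupFrequencies) -> float | Exclusive:
    """AI score, or an exclusive flag when the ratio is undefined.

    The score is defined only when all four group allele frequencies are
    positive.  If one allele has zero count in exactly one group the site
    is exclusive to the other group; a site with zero counts for the same
    allele in both groups is monomorphic and rejected.
    """
    zero_high = g.count_a_high == 0 or g.count_b_high == 0
    zero_low = g.count_a_low == 0 or g.count_b_low == 0
    if not zero_high and not zero_low:
        return (g.fa_high / g.fb_high) / (g.fa_low / g.fb_low)
    if (g.count_a_high == 0 and g.count_a_low == 0) or (
        g.count_b_high == 0 and g.count_b_low == 0
    ):
        raise ValueError(f"{g.snp}: monomorphic in both groups")
    # Both alleles seen overall, but one group is missing an allele: the
    # polymorphism is exclusive to the group where the alt allele appears
    # (for opposite fixations, to the group carrying the alt allele).
    if zero_high and not zero_low:
        return Exclusive.LOW
    if zero_low and not zero_high:
        return Exclusive.HIGH
    return Exclusive.HIGH if g.count_a_high > 0 else Exclusive.LOW


@dataclass(frozen=True)
class ClassifyThresholds:
    """Score cutoffs; inclusive=True implements >= 2.0 and <= 0.5."""

    amplification: float = 2.0
    loh: float = 0.5
    inclusive: bool = True

    def __post_init__(self) -> None:
        if not math.isclose(self.amplification * self.loh, 1.0, rel_tol=1e-9):
            warnings.warn(
                "thresholds are not reciprocal; amplification and LOH calls "
                "will be asymmetric",
                stacklevel=2,
            )


def classify_imbalance(
    score: float | Exclusive,
    thresholds: ClassifyThresholds = ClassifyThresholds(),
) -> ImbalanceClass:
    """Map a score (or exclusive flag) to its imbalance class."""
    if isinstance(score, Exclusive):
        return (
            ImbalanceClass.EXCLUSIVE_HIGH
            if score is Exclusive.HIGH
            else ImbalanceClass.EXCLUSIVE_LOW
        )
    if thresholds.inclusive:
        if score >= thresholds.amplification:
            return ImbalanceClass.AMPLIFICATION
        if score <= thresholds.loh:
            return ImbalanceClass.LOH
    else:
        if score > thresholds.amplification:
            return ImbalanceClass.AMPLIFICATION
        if score < thresholds.loh:
            return ImbalanceClass.LOH
    return ImbalanceClass.NONE


def chi_square_2x2(
    counts_high: tuple[int, int], counts_low: tuple[int, int]
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    Rows are the high/low groups, columns the two alleles.  Returns
    ``(nan, nan)`` when any marginal is zero, where the statistic is
    undefined; such sites form the one-allele stratum and are reported,
    not discarded.
    """
    table = np.array([counts_high, counts_low], dtype=float)
    if table.min() < 0:
        raise ValueError("negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return (math.nan, math.nan)
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return (float(stat), float(p))


@dataclass(frozen=True)
class ImbalanceResult:
    """Per-SNP, per-trait outcome of the AI analysis."""

    snp: SnpKey
    trait: str
    frequencies: GroupFrequencies
    score: float | None  # None when exclusive
    imbalance_class: ImbalanceClass
    chi2: float  # nan when undefined
    p_value: float  # nan when undefined
    significant: bool  # p < alpha; False when p undefined

    @property
    def chi2_defined(self) -> bool:
        return not math.isnan(self.chi2)


def score_site(
    site_counts: Sequence[PooledSiteCount],
    design: TraitDesign,
    thresholds: ClassifyThresholds = ClassifyThresholds(),
    alpha: float = 0.05,
) -> ImbalanceResult:
    """Full per-site scoring: frequencies, score, class, chi-square."""
    g = pool_group_frequencies(site_counts, design)
    s = imbalance_score(g)
    cls = classify_imbalance(s, thresholds)
    chi2, p = chi_square_2x2(
        (g.count_a_high, g.count_b_high), (g.count_a_low, g.count_b_low)
    )
    return ImbalanceResult(
        snp=g.snp,
        trait=design.trait,
        frequencies=g,
        score=None if isinstance(s, Exclusive) else s,
        imbalance_class=cls,
        chi2=chi2,
        p_value=p,
        significant=bool(p < alpha) if not math.isnan(p) else False,
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH q-values; NaNs propagate.  Emitted alongside raw p, not used to
    classify (the analysis reports raw p < 0.05)."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = stats.false_discovery_control(p[ok], method="bh")
    return q


@dataclass(frozen=True)
class MergedSnpSet:
    """Cross-trait non-redundant SNP set."""

    membership: dict[SnpKey, tuple[tuple[str, ImbalanceClass], ...]]
    sharing_histogram: dict[int, int]  # n_traits -> n_snps
    # distinct keys sharing chrom/pos with different alt alleles
    multiallelic_positions: tuple[tuple[SnpKey, ...], ...]

    @property
    def snps(self) -> frozenset[SnpKey]:
        return frozenset(self.membership)


def merge_traits(
    per_trait_results: Mapping[str, Iterable[ImbalanceResult]],
    *,
    imbalanced_only: bool = True,
) -> MergedSnpSet:
    """Merge per-trait results into a non-redundant SNP set.

    Each distinct (chrom, pos, ref, alt) is one SNP; keys sharing a
    position but differing in alt allele stay distinct yet are listed in a
    reconciliation report, mirroring how multi-allelic sites are
    footnoted rather than collapsed.
    """
    membership: dict[SnpKey, list[tuple[str, ImbalanceClass]]] = {}
    for trait, results in per_trait_results.items():
        for r in results:
            if imbalanced_only and not r.imbalance_class.is_imbalanced:
                continue
            membership.setdefault(r.snp, []).append((trait, r.imbalance_class))
    histogram = Counter(len(traits) for traits in membership.values())
    by_pos: dict[tuple[str, int], list[SnpKey]] = {}
    for key in membership:
        by_pos.setdefault((key.chrom, key.pos), []).append(key)
    multi = tuple(
        tuple(sorted(keys)) for pos, keys in sorted(by_pos.items()) if len(keys) > 1
    )
    return MergedSnpSet(
        membership={k: tuple(v) for k, v in sorted(membership.items())},
        sharing_histogram=dict(sorted(histogram.items())),
        multiallelic_positions=multi,
    )
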