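"""Validation-side analytics for genotyping assays.

Covers the bookkeeping around wet-lab confirmation of SNPs called from
pooled RNA-Seq: flank-based assay-design filters, success-rate tables
over assay outcome counts, DNA-versus-cDNA genotype concordance with
mono-allelic expression detection, Mendelian-inheritance checks, and
segregation-distortion tests in mapping families.

Genotypes are unordered allele pairs written ``"A/G"`` (alleles sorted);
missing calls are empty strings, ``"./."`` or NaN.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from poolai._util import percent
from poolai.variant_io import SnpKey

_MISSING = {"", ".", "./.", "NA", "nan"}


def _parse_genotype(g: object) -> tuple[str, str] | None:
    if g is None or (isinstance(g, float) and math.isnan(g)):
        return None
    s = str(g).strip()
    if s in _MISSING:
        return None
    alleles = tuple(sorted(re.split(r"[/|]", s)))
    if len(alleles) != 2:
        raise ValueError(f"malformed genotype {g!r}")
    return alleles  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# assay design


@dataclass(frozen=True)
class AssayDesignDecision:
    keep: bool
    reason: str | None = None
    flank_truncated: bool = False

    def __bool__(self) -> bool:
        return self.keep


def assay_design_filter(
    snp_pos: int,
    gap_positions: Iterable[int],
    neighbor_snp_positions: Iterable[int],
    *,
    min_gap_distance: int = 60,
    min_snp_distance: int = 30,
    flank: int = 250,
    contig_length: int | None = None,
) -> AssayDesignDecision:
    """Decide whether a SNP is usable for genotyping-assay design.

    A SNP is removed when an assembly gap base lies strictly closer than
    ``min_gap_distance`` (60 bp) or another SNP strictly closer than
    ``min_snp_distance`` (30 bp); a neighbour exactly at the threshold is
    kept.  Distances are base-to-base on the same sequence; only
    positions within ``flank`` (250 bp) of the SNP are considered, since
    that is the extent of the extracted flanking sequence.  A SNP within
    ``flank`` of a contig end is noted as truncated, not removed.
    """
    truncated = snp_pos <= flank or (
        contig_length is not None and contig_length - snp_pos < flank
    )
    for gp in gap_positions:
        d = abs(gp - snp_pos)
        if d <= flank and d < min_gap_distance:
            return AssayDesignDecision(False, f"gap at {d} bp", truncated)
    for np_ in neighbor_snp_positions:
        d = abs(np_ - snp_pos)
        if d == 0:
            continue
        if d <= flank and d < min_snp_distance:
            return AssayDesignDecision(False, f"neighboring SNP at {d} bp", truncated)
    return AssayDesignDecision(True, flank_truncated=truncated)


def find_gap_positions(sequence: str, start_pos: int = 1) -> list[int]:
    """1-based positions of ambiguous (N) bases in a sequence slice."""
    return [start_pos + i for i, b in enumerate(sequence.upper()) if b == "N"]


# ---------------------------------------------------------------------------
# success-rate table


@dataclass(frozen=True)
class AssayRecord:
    """Outcome of one genotyping assay for one SNP."""

    snp: SnpKey
    source_set: str
    outcome: str  # polymorphic | monomorphic | failed

    def __post_init__(self) -> None:
        if self.outcome not in ("polymorphic", "monomorphic", "failed"):
            raise ValueError(f"unknown outcome {self.outcome!r}")


def success_rate(polymorphic: int, monomorphic: int, failed: int) -> float:
    """Validation success rate, in percent to one decimal.

    Failed assays are excluded from the denominator: an assay can fail
    for primer-design reasons unrelated to whether the SNP call was
    correct, so the rate is polymorphic / (total - failed) * 100.
    """
    total = polymorphic + monomorphic + failed
    working = total - failed
    if working == 0:
        raise ZeroDivisionError("no working assays: success rate undefined")
    return percent(polymorphic, working, 1)


def success_rate_table(
    records: Iterable[AssayRecord] | pd.DataFrame,
) -> pd.DataFrame:
    """Per-source-set assay outcome counts and success rates.

    Accepts assay records, or a pre-counted DataFrame with columns
    ``set, polymorphic, monomorphic, failed`` (the published-table entry
    point).  Output adds ``total`` and ``success_rate`` columns; a set
    with no working assays gets a NaN rate.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows: dict[str, dict[str, int]] = {}
        for r in records:
            d = rows.setdefault(
                r.source_set, {"polymorphic": 0, "monomorphic": 0, "failed": 0}
            )
            d[r.outcome] += 1
        df = (
            pd.DataFrame.from_dict(rows, orient="index")
            .rename_axis("set")
            .reset_index()
        )
    df["total"] = df["polymorphic"] + df["monomorphic"] + df["failed"]
    rates = []
    for _, row in df.iterrows():
        try:
            rates.append(success_rate(row["polymorphic"], row["monomorphic"], row["failed"]))
        except ZeroDivisionError:
            rates.append(math.nan)
    df["success_rate"] = rates
    return df


# ---------------------------------------------------------------------------
# DNA / cDNA concordance and mono-allelic expression


@dataclass(frozen=True)
class MonoallelicEvent:
    fish: str
    snp: str
    dna_genotype: str
    cdna_genotype: str


@dataclass(frozen=True)
class ConcordanceResult:
    n_comparable: int
    n_concordant: int
    n_het_dna: int
    events: tuple[MonoallelicEvent, ...]

    @property
    def concordance_rate(self) -> float:
        """Percent of comparable (fish, SNP) pairs with equal genotypes."""
        return percent(self.n_concordant, self.n_comparable, 1)

    def monoallelic_rate(self, denominator: str = "het_dna") -> float:
        """Percent of pairs that are mono-allelic events.

        ``denominator='het_dna'`` (default) uses comparable pairs with
        heterozygous DNA — the pairs at which an event is observable;
        ``'all'`` uses every comparable pair.
        """
        if denominator == "het_dna":
            return percent(len(self.events), self.n_het_dna, 2)
        if denominator == "all":
            return percent(len(self.events), self.n_comparable, 2)
        raise ValueError(f"unknown denominator {denominator!r}")


def genotype_concordance(
    dna: pd.DataFrame, cdna: pd.DataFrame
) -> ConcordanceResult:
    """Compare fish x SNP genotype matrices from DNA and cDNA.

    A pair is comparable when both calls are non-missing.  A pair is a
    mono-allelic expression event when the DNA call is heterozygous and
    the cDNA call is homozygous: the fish carries both alleles but
    expresses only one.  Matrices must share fish (rows) and SNP
    (columns) indices exactly.
    """
    if not dna.index.equals(cdna.index) or not dna.columns.equals(cdna.columns):
        raise ValueError("DNA and cDNA matrices are misaligned")
    n_comparable = n_concordant = n_het = 0
    events: list[MonoallelicEvent] = []
    for fish in dna.index:
        for snp in dna.columns:
            g_dna = _parse_genotype(dna.at[fish, snp])
            g_cdna = _parse_genotype(cdna.at[fish, snp])
            if g_dna is None or g_cdna is None:
                continue
            n_comparable += 1
            if g_dna == g_cdna:
                n_concordant += 1
            het_dna = g_dna[0] != g_dna[1]
            if het_dna:
                n_het += 1
                if g_cdna[0] == g_cdna[1]:
                    events.append(
                        MonoallelicEvent(
                            fish=str(fish),
                            snp=str(snp),
                            dna_genotype="/".join(g_dna),
                            cdna_genotype="/".join(g_cdna),
                        )
                    )
    return ConcordanceResult(n_comparable, n_concordant, n_het, tuple(events))


# ---------------------------------------------------------------------------
# Mendelian consistency and segregation distortion


def mendelian_consistent(
    parent1: str, parent2: str, offspring: str
) -> bool:
    """True iff the offspring genotype can be formed from one allele of
    each parent (biallelic logic)."""
    p1, p2, off = map(_parse_genotype, (parent1, parent2, offspring))
    if p1 is None or p2 is None or off is None:
        raise ValueError("missing genotype in Mendelian check")
    return any(
        tuple(sorted((a, b))) == off for a, b in itertools.product(p1, p2)
    )


def mendelian_check(
    parents: Mapping[str, tuple[str, str]],
    offspring: pd.DataFrame,
) -> pd.DataFrame:
    """List Mendelian inconsistencies across a panel.

    ``parents`` maps SNP id -> (parent1, parent2) genotypes; ``offspring``
    is a fish x SNP genotype matrix.  SNPs with a missing parent genotype
    are skipped (noted with reason); missing offspring calls are ignored.
    Returns a tidy frame of (snp, fish, parent1, parent2, offspring,
    status) rows, status in {inconsistent, skipped}.
    """
    rows = []
    for snp in offspring.columns:
        if snp not in parents:
            rows.append((snp, None, None, None, None, "skipped"))
            continue
        p1, p2 = parents[snp]
        if _parse_genotype(p1) is None or _parse_genotype(p2) is None:
            rows.append((snp, None, p1, p2, None, "skipped"))
            continue
        for fish in offspring.index:
            g = offspring.at[fish, snp]
            if _parse_genotype(g) is None:
                continue
            if not mendelian_consistent(p1, p2, g):
                rows.append((snp, fish, p1, p2, g, "inconsistent"))
    return pd.DataFrame(
        rows, columns=["snp", "fish", "parent1", "parent2", "offspring", "status"]
    )


@dataclass(frozen=True)
class SegregationResult:
    snp: str
    chi2: float
    p_value: float
    distorted: bool  # p < alpha -> reported as assay-failed
    expected: dict[str, float]
    observed: dict[str, int]


def segregation_distortion(
    snp: str,
    offspring_genotypes: Sequence[str],
    parent1: str,
    parent2: str,
    alpha: float = 0.01,
) -> SegregationResult | None:
    """Chi-square goodness-of-fit of offspring genotype ratios against
    Mendelian expectations for the parental cross.

    het x het expects 1:2:1 over (AA, AB, BB); hom x het expects 1:1 over
    the two reachable genotypes.  Crosses with both parents homozygous
    are uninformative and return None.  SNPs with p < alpha (default
    0.01) are flagged as distorted and treated as assay failures
    downstream.
    """
    p1 = _parse_genotype(parent1)
    p2 = _parse_genotype(parent2)
    if p1 is None or p2 is None:
        return None
    het1, het2 = p1[0] != p1[1], p2[0] != p2[1]
    if not het1 and not het2:
        return None
    expected_counts: dict[tuple[str, str], float] = {}
    for a, b in itertools.product(p1, p2):
        g = tuple(sorted((a, b)))
        expected_counts[g] = expected_counts.get(g, 0.0) + 0.25
    observed: dict[tuple[str, str], int] = {g: 0 for g in expected_counts}
    for og in offspring_genotypes:
        g = _parse_genotype(og)
        if g is None:
            continue
        if g not in observed:
            # impossible genotype under the cross; Mendelian check catches
            # it — excluded from the ratio test
            continue
        observed[g] += 1
    n = sum(observed.values())
    if n == 0:
        return None
    genotypes = sorted(expected_counts)
    obs = np.array([observed[g] for g in genotypes], dtype=float)
    exp = np.array([expected_counts[g] * n for g in genotypes])
    chi2, p = stats.chisquare(obs, exp)
    return SegregationResult(
        snp=snp,
        chi2=float(chi2),
        p_value=float(p),
        distorted=bool(p < alpha),
        expected={"/".join(g): expected_counts[g] * n for g in genotypes},
        observed={"/".join(g): observed[g] for g in genotypes},
    )
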