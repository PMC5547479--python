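"""Reading per-family pooled VCFs and the site-level filters.

One VCF per family, one sample per VCF: the sample's AD field carries the
pooled read counts for the reference and alternate alleles (5 fish pooled
per family, so counts estimate pool allele frequencies).  Multi-allelic
records are decomposed into one biallelic entry per alternate allele.
Coordinates are 1-based inclusive throughout, matching VCF and GFF3.

Two families of filters are provided:

* hard filters on per-site quality annotations (QD, FS, MQ) with the
  GATK-conventional failing directions, and
* pool-level count filters (total reads, minor-allele count, minor-allele
  frequency) computed on counts summed over all families in the run.

``merge_pipelines`` reconciles SNP sets produced by two variant-calling
pipelines, reporting same-position/different-allele conflicts separately.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

_BASES = frozenset("ACGT")


@functools.total_ordering
@dataclass(frozen=True)
class SnpKey:
    """Identity of a biallelic SNP: (chromosome, position, ref, alt).

    Ordering is lexicographic on chromosome, then numeric on position,
    then lexicographic on alleles, so sorted output is stable.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    def _sort_key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    def __lt__(self, other: "SnpKey") -> bool:
        return self._sort_key() < other._sort_key()

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def from_string(cls, s: str) -> "SnpKey":
        chrom, pos, ref, alt = s.split(":")
        return cls(chrom, int(pos), ref, alt)


@dataclass(frozen=True)
class VariantSiteQuality:
    """GATK-style site annotations; any may be absent (None)."""

    QD: float | None = None
    FS: float | None = None
    MQ: float | None = None
    DP: int | None = None


@dataclass(frozen=True)
class PooledSiteCount:
    """Pooled ref/alt read counts for one biallelic site in one family."""

    family: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ref_reads: int
    alt_reads: int
    quality: VariantSiteQuality = field(default_factory=VariantSiteQuality)

    def __post_init__(self) -> None:
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValueError("negative read count")
        if self.ref == self.alt:
            raise ValueError("ref == alt")

    @property
    def key(self) -> SnpKey:
        return SnpKey(self.chrom, self.pos, self.ref, self.alt)

    @property
    def total(self) -> int:
        return self.ref_reads + self.alt_reads


class VcfFormatError(ValueError):
    """A record that cannot be interpreted as pooled allele counts."""


def read_family_vcf(
    path: str | Path,
    family: str,
    *,
    skip_indels: bool = True,
) -> list[PooledSiteCount]:
    """Read one family's VCF into pooled per-site allele counts.

    Multi-allelic records are decomposed into one :class:`PooledSiteCount`
    per alternate allele, each paired with the shared reference count.
    Indels (any allele longer than one base) are skipped by default, since
    the analysis covers SNPs only.

    Raises :class:`VcfFormatError` naming the record if the allele-depth
    (AD) field is missing.
    """
    out: list[PooledSiteCount] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise VcfFormatError(f"{path}: VCF has no sample column")
        sample = samples[0]
        for rec in vcf:
            if rec.alts is None:
                continue
            alleles = [rec.ref, *rec.alts]
            if skip_indels and any(len(a) != 1 for a in alleles):
                continue
            call = rec.samples[sample]
            ad = call.get("AD")
            if ad is None or all(v is None for v in ad):
                raise VcfFormatError(
                    f"{path}: missing AD field at {rec.chrom}:{rec.pos}"
                )
            if len(ad) != len(alleles):
                raise VcfFormatError(
                    f"{path}: AD length {len(ad)} != {len(alleles)} alleles "
                    f"at {rec.chrom}:{rec.pos}"
                )
            info = rec.info
            qual = VariantSiteQuality(
                QD=info.get("QD"),
                FS=info.get("FS"),
                MQ=info.get("MQ"),
                DP=info.get("DP"),
            )
            ref_reads = int(ad[0])
            for alt, alt_reads in zip(rec.alts, ad[1:]):
                out.append(
                    PooledSiteCount(
                        family=family,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref.upper(),
                        alt=alt.upper(),
                        ref_reads=ref_reads,
                        alt_reads=int(alt_reads),
                        quality=qual,
                    )
                )
    return out


@dataclass(frozen=True)
class HardFilterThresholds:
    """GATK hard-filter gates: fail if QD < qd_min, FS > fs_max, MQ < mq_min."""

    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0

    def __post_init__(self) -> None:
        if self.qd_min < 0 or self.fs_max < 0 or self.mq_min < 0:
            raise ValueError("hard-filter thresholds must be non-negative")


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reason: str | None = None
    warning: str | None = None

    def __bool__(self) -> bool:
        return self.passed


def apply_hard_filters(
    q: VariantSiteQuality,
    thresholds: HardFilterThresholds = HardFilterThresholds(),
) -> FilterResult:
    """Apply QD/FS/MQ hard filters to one site.

    Failing directions follow GATK documentation: low quality-by-depth,
    high Fisher-strand bias, low RMS mapping quality.  Values exactly at
    a threshold pass (the fail condition is a strict inequality).  A
    missing annotation passes with a warning recorded.
    """
    missing = [
        name for name, v in (("QD", q.QD), ("FS", q.FS), ("MQ", q.MQ)) if v is None
    ]
    if q.QD is not None and q.QD < thresholds.qd_min:
        return FilterResult(False, f"QD<{thresholds.qd_min}")
    if q.FS is not None and q.FS > thresholds.fs_max:
        return FilterResult(False, f"FS>{thresholds.fs_max}")
    if q.MQ is not None and q.MQ < thresholds.mq_min:
        return FilterResult(False, f"MQ<{thresholds.mq_min}")
    warning = f"missing annotations: {','.join(missing)}" if missing else None
    return FilterResult(True, warning=warning)


@dataclass(frozen=True)
class PoolFilterThresholds:
    """Pool count gates: total reads > 10, minor count > 4, MAF > 0.05."""

    min_reads: int = 10
    min_minor_count: int = 4
    min_maf: float = 0.05


def apply_pool_filters(
    counts: Sequence[PooledSiteCount],
    thresholds: PoolFilterThresholds = PoolFilterThresholds(),
) -> FilterResult:
    """Apply the pooled-count site filters over all families at one site.

    Counts are summed across families; all three gates are strict
    inequalities (a total of exactly 10 reads, a minor-allele count of
    exactly 4, or a MAF of exactly 0.05 all fail).
    """
    if not counts:
        return FilterResult(False, "no coverage")
    ref_total = sum(c.ref_reads for c in counts)
    alt_total = sum(c.alt_reads for c in counts)
    total = ref_total + alt_total
    if total <= thresholds.min_reads:
        return FilterResult(False, f"total reads<={thresholds.min_reads}")
    minor = min(ref_total, alt_total)
    if minor <= thresholds.min_minor_count:
        return FilterResult(False, f"minor allele count<={thresholds.min_minor_count}")
    if minor / total <= thresholds.min_maf:
        return FilterResult(False, f"MAF<={thresholds.min_maf}")
    return FilterResult(True)


@dataclass(frozen=True)
class MergeResult:
    """Reconciliation of two pipelines' SNP sets."""

    common: frozenset[SnpKey]
    unique_a: frozenset[SnpKey]
    unique_b: frozenset[SnpKey]
    union: frozenset[SnpKey]
    # same chrom/pos, different alt allele between the two sets
    conflicts: tuple[tuple[SnpKey, SnpKey], ...]


def merge_pipelines(
    set_a: Iterable[SnpKey], set_b: Iterable[SnpKey]
) -> MergeResult:
    """Intersect/union two pipelines' SNP sets on exact (chrom,pos,ref,alt).

    Sites where the two pipelines called the same position but different
    alternate alleles are not counted as common; each such pair is listed
    in ``conflicts`` so multi-allelic disagreements stay visible.
    """
    a = frozenset(set_a)
    b = frozenset(set_b)
    common = a & b
    unique_a = a - b
    unique_b = b - a
    by_pos_b: dict[tuple[str, int], list[SnpKey]] = {}
    for k in unique_b:
        by_pos_b.setdefault((k.chrom, k.pos), []).append(k)
    conflicts: list[tuple[SnpKey, SnpKey]] = []
    for ka in sorted(unique_a):
        for kb in sorted(by_pos_b.get((ka.chrom, ka.pos), [])):
            conflicts.append((ka, kb))
    return MergeResult(
        common=common,
        unique_a=unique_a,
        unique_b=unique_b,
        union=a | b,
        conflicts=tuple(conflicts),
    )


def group_counts_by_site(
    counts: Iterable[PooledSiteCount],
) -> dict[SnpKey, list[PooledSiteCount]]:
    """Index per-family counts by SNP key (insertion order preserved)."""
    out: dict[SnpKey, list[PooledSiteCount]] = {}
    for c in counts:
        out.setdefault(c.key, []).append(c)
    return out
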