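"""Per-chromosome SNP counts and densities (SNPs per 100 kb).

Densities are reported per whole chromosome, one value per sequence;
scaffolds not assigned to chromosomes can be aggregated under a single
"Unknown" bin selected by a sequence-name pattern, with its length taken
as the summed scaffold length.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from poolai.variant_io import SnpKey

DENSITY_WINDOW = 100_000  # SNPs per 100,000 nucleotides


def chromosome_density(
    snps: Iterable[SnpKey],
    chrom_lengths: Mapping[str, int],
    *,
    per_trait: Mapping[str, Iterable[SnpKey]] | None = None,
    unknown_pattern: str | None = None,
    unknown_label: str = "Unknown",
) -> pd.DataFrame:
    """Count SNPs per chromosome and derive density per 100 kb.

    ``unknown_pattern`` is a regex; sequences matching it are pooled into
    one ``unknown_label`` row whose length is their summed length.  A SNP
    on a sequence with no known length (and no matching pattern) is an
    error listing the offending sequences.

    With ``per_trait`` given, one extra count column per trait is added;
    a SNP shared by several traits is counted once in each trait column,
    so trait columns sum to more than the total when traits overlap.
    """
    pat = re.compile(unknown_pattern) if unknown_pattern else None

    def bin_of(chrom: str) -> str:
        if pat is not None and pat.search(chrom):
            return unknown_label
        return chrom

    lengths: dict[str, int] = {}
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"{chrom}: non-positive length")
        if pat is not None and pat.search(chrom):
            lengths[unknown_label] = lengths.get(unknown_label, 0) + length
        else:
            lengths[chrom] = length

    def count_into(keys: Iterable[SnpKey]) -> dict[str, int]:
        counts = {c: 0 for c in lengths}
        bad: set[str] = set()
        for k in keys:
            b = bin_of(k.chrom)
            if b not in counts:
                bad.add(k.chrom)
                continue
            counts[b] += 1
        if bad:
            raise KeyError(f"SNPs on sequences without a known length: {sorted(bad)}")
        return counts

    rows = pd.DataFrame(
        {"chrom": list(lengths), "length": [lengths[c] for c in lengths]}
    )
    total = count_into(snps)
    rows["snp_count"] = rows["chrom"].map(total)
    rows["density"] = rows["snp_count"] / rows["length"] * DENSITY_WINDOW
    if per_trait:
        for trait, keys in per_trait.items():
            rows[f"count_{trait}"] = rows["chrom"].map(count_into(keys))
    return rows


def correlation_count_vs_length(stats_table: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation of per-chromosome SNP count against length.

    Requires at least three chromosomes; a constant count or length
    vector makes the correlation undefined (ValueError).
    """
    if len(stats_table) < 3:
        raise ValueError("need >= 3 chromosomes for a correlation")
    counts = stats_table["snp_count"].to_numpy(dtype=float)
    lengths = stats_table["length"].to_numpy(dtype=float)
    if counts.std() == 0 or lengths.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(counts, lengths)
    return float(r), float(p)
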