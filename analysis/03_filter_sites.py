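"""Read the per-family pooled VCFs and apply the site filters.

Hard filters (QD < 2, FS > 60, MQ < 40 fail) act on the site quality
annotations; pool filters (total reads > 10, minor-allele count > 4,
MAF > 0.05) act on counts summed across all 22 families.  Passing sites
with their pooled counts go to results/filtered_sites.tsv.
"""

from pathlib import Path

import pandas as pd

from poolai import pipeline
from poolai.variant_io import group_counts_by_site, read_family_vcf

ROOT = Path(__file__).resolve().parent.parent
vcf_dir = ROOT / "scratch" / "sim" / "vcf"

counts = []
for path in sorted(vcf_dir.glob("*.vcf")):
    counts.extend(read_family_vcf(path, path.stem))
by_site = group_counts_by_site(counts)
kept, summary = pipeline.filter_sites(by_site)

rows = [
    {
        "chrom": k.chrom,
        "pos": k.pos,
        "ref": k.ref,
        "alt": k.alt,
        "ref_reads": sum(c.ref_reads for c in v),
        "alt_reads": sum(c.alt_reads for c in v),
    }
    for k, v in sorted(kept.items())
]
out = ROOT / "scratch" / "filtered_sites.tsv"
pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
print(
    f"{summary.n_pass}/{summary.n_input} sites pass "
    f"({summary.n_hard_fail} hard-filter fails, "
    f"{summary.n_pool_fail} pool-filter fails)"
)
print(f"wrote {out}")
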