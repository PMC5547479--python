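"""Genome distribution of the imbalanced SNPs.

Counts and densities (SNPs per 100 kb) per chromosome, stratified by
trait, plus the Pearson correlation of per-chromosome SNP count against
chromosome length.  Output: results/density.tsv.
"""

from pathlib import Path

import pandas as pd

from poolai import genomedist
from poolai.variant_io import SnpKey

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"

lengths = {}
with open(SIM / "reference" / "genome.fa.fai") as fh:
    for line in fh:
        name, length, *_ = line.split("\t")
        lengths[name] = int(length)

per_trait = {}
all_keys: set[SnpKey] = set()
for p in sorted((ROOT / "scratch" / "score").glob("*.tsv")):
    df = pd.read_csv(p, sep="\t")
    imb = df[df["class"] != "none"]
    keys = {
        SnpKey(r["chrom"], int(r["pos"]), r["ref"], r["alt"])
        for _, r in imb.iterrows()
    }
    per_trait[p.stem] = keys
    all_keys |= keys

stats = genomedist.chromosome_density(all_keys, lengths, per_trait=per_trait)
stats.to_csv(RESULTS / "density.tsv", sep="\t", index=False)
print(stats.to_string(index=False))
r, p = genomedist.correlation_count_vs_length(stats)
print(f"SNP count vs chromosome length: Pearson r={r:.3f} (p={p:.3g})")
print(f"wrote {RESULTS / 'density.tsv'}")
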