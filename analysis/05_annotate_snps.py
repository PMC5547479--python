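"""Classify the imbalanced SNPs by genomic context and coding effect.

Each SNP gets exactly one context (CDS > 5'UTR > 3'UTR > intron inside
genes; lncRNA; upstream/downstream within 5 kb; far intergenic), and CDS
SNPs get a codon-level effect call against the reference genome.  The
class summary table goes to results/annotation/.
"""

from pathlib import Path

import pandas as pd
import pyfaidx

import poolai.annotate as ann
from poolai.variant_io import SnpKey

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "annotation"
OUT.mkdir(parents=True, exist_ok=True)
simdir = ROOT / "scratch" / "sim"
SCORE = ROOT / "scratch" / "score"

# the non-redundant imbalanced SNPs from the scoring stage
frames = [
    pd.read_csv(p, sep="\t") for p in sorted(SCORE.glob("*.tsv"))
]
merged = pd.concat(frames)
imb = merged[
    merged["class"].isin(
        ["amplification", "loss_of_heterozygosity", "exclusive_high", "exclusive_low"]
    )
]
keys = sorted(
    {
        SnpKey(r["chrom"], int(r["pos"]), r["ref"], r["alt"])
        for _, r in imb.iterrows()
    }
)

fa = pyfaidx.Fasta(str(simdir / "reference" / "genome.fa"))
genome = {name: str(fa[name][:]) for name in fa.keys()}
index = ann.GenomeAnnotationIndex(
    ann.load_transcripts(simdir / "reference" / "genes.gff3"),
    ann.load_lncrnas(simdir / "reference" / "lncrna.gtf"),
    {c: len(s) for c, s in genome.items()},
)
annotations = ann.annotate_snps(keys, index, genome)

rows = [
    (str(a.snp), a.context.value, a.feature_id or "",
     a.coding_effect.value, a.ref_aa or "", a.alt_aa or "")
    for a in annotations
]
pd.DataFrame(
    rows, columns=["site", "context", "feature", "effect", "ref_aa", "alt_aa"]
).to_csv(ROOT / "scratch" / "annotations.tsv", sep="\t", index=False)

summary = ann.summarize_classes(annotations)
summary.to_csv(OUT / "class_summary.tsv", sep="\t", index=False)
print(f"annotated {len(keys)} non-redundant imbalanced SNPs")
print(summary.to_string(index=False))
print(f"wrote {OUT}")
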