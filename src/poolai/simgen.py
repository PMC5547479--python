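"""Synthetic pooled RNA-Seq study generator with machine-readable truth.

Emulates the study design the analysis expects: a small multi-chromosome
genome with protein-coding genes (gene -> mRNA -> exon/CDS, both strands,
UTRs, multi-exon) and lncRNAs; 22 full-sib families, five traits each
contrasting 4 high- vs 4 low-ranked families; one pooled VCF per family
(5 fish pooled, read counts binomial around the family allele frequency);
a minority of truly imbalanced sites planted on a null background; family
phenotype tables; and DNA/cDNA genotype panels with rare planted
mono-allelic expression events.

The generative model for pooled counts: each site has a base alternate-
allele frequency p0 ~ U(0.1, 0.9).  For a site planted imbalanced for a
trait, the allele-frequency odds in the trait's high and low family
groups are moved apart so their ratio equals ``planted_ratio``
(symmetrically on the log-odds scale, direction random).  Family
frequencies are beta-distributed around their group value (family-to-
family overdispersion), and reads are binomial(depth, family frequency)
with Poisson depth.  Exclusive sites have the alternate allele entirely
absent from one group's families.

Everything is driven by a single master seed; named child streams are
derived with ``numpy.random.SeedSequence.spawn``, so identical configs
give byte-identical output files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from poolai.annotate import LncRnaModel, TranscriptModel
from poolai.imbalance import TraitDesign
from poolai.variant_io import PooledSiteCount, SnpKey, VariantSiteQuality

TRAITS = ("WBW", "muscle_yield", "fat", "shear", "whiteness")

# target group means/SDs per trait: ((high mean, high sd), (low mean, low sd));
# WBW grams, yield/fat percent, shear g-force/g, whiteness index units
PHENOTYPE_TARGETS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "WBW": ((1221.6, 84.25), (502.1, 28.0)),
    "muscle_yield": ((50.9, 1.6), (43.3, 2.3)),
    "fat": ((9.24, 1.2), (4.77, 1.3)),
    "shear": ((539.64, 12.3), (310.01, 49.2)),
    "whiteness": ((44.7, 0.8), (41.23, 0.4)),
}

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SizingError(ValueError):
    """The configured chromosome length cannot hold the requested features."""


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study.

    Defaults are the study conditions the analysis is meant to emulate:
    22 families, five traits with 4 high vs 4 low families each, ~100
    reads per pooled site, 5,000 sites of which 5% are planted imbalanced
    with an odds-ratio of 3 between groups, 1% exclusive to one group,
    and a 4.64% mono-allelic expression rate among heterozygous DNA
    calls.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 400_000
    n_genes: int = 30
    n_lncrnas: int = 8
    n_families: int = 22
    pool_depth_mean: float = 100.0
    n_sites: int = 5_000
    frac_imbalanced: float = 0.05
    frac_exclusive: float = 0.01
    planted_ratio: float = 3.0
    frac_monoallelic: float = 0.0464
    traits: tuple[str, ...] = TRAITS
    n_high: int = 4
    n_low: int = 4
    # family allele frequencies ~ Beta around the group value with this
    # concentration; larger = less family-to-family variation
    beta_concentration: float = 200.0
    # fraction of sites given a failing QD/FS/MQ annotation
    frac_lowqual: float = 0.02
    # fraction of sites placed inside gene spans (RNA-Seq variants come
    # from transcribed sequence); the rest are uniform over the genome
    genic_fraction: float = 0.6
    n_panel_fish: int = 35
    n_panel_snps: int = 72
    # scales the planted high-low separation of phenotype group means
    phenotype_separation: float = 1.0

    def __post_init__(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length": self.chrom_length,
            "n_genes": self.n_genes,
            "n_families": self.n_families,
            "n_sites": self.n_sites,
            "n_high": self.n_high,
            "n_low": self.n_low,
            "n_panel_fish": self.n_panel_fish,
            "n_panel_snps": self.n_panel_snps,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0 (got {v})")
        if self.n_lncrnas < 0:
            raise ValueError("n_lncrnas must be >= 0")
        for name, v in (
            ("frac_imbalanced", self.frac_imbalanced),
            ("frac_exclusive", self.frac_exclusive),
            ("frac_monoallelic", self.frac_monoallelic),
            ("frac_lowqual", self.frac_lowqual),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1] (got {v})")
        if self.planted_ratio < 1.0:
            raise ValueError("planted_ratio must be >= 1")
        if self.n_high + self.n_low > self.n_families:
            raise ValueError("n_high + n_low exceeds n_families")

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(f"F{i + 1:02d}" for i in range(self.n_families))

    def streams(self) -> dict[str, np.random.Generator]:
        """Named deterministic child RNG streams from the master seed."""
        names = ("reference", "designs", "phenotypes", "pools", "quality", "panel")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# reference genome + annotations


@dataclass
class ReferenceBundle:
    """In-memory toy genome with its annotations and serialisers."""

    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    lncrnas: list[LncRnaModel]
    gff3_lines: list[str]
    gtf_lines: list[str]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "genome.fa"
        with fasta.open("w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        gff = outdir / "genes.gff3"
        gff.write_text("##gff-version 3\n" + "".join(self.gff3_lines))
        gtf = outdir / "lncrna.gtf"
        gtf.write_text("".join(self.gtf_lines))
        return {"fasta": fasta, "gff3": gff, "gtf": gtf}


def _make_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(len(_CODONS), size=n_codons - 2)
    stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
    return "ATG" + "".join(_CODONS[i] for i in body) + stop


def _build_gene(
    rng: np.random.Generator, gene_id: str, chrom: str, start: int
) -> tuple[TranscriptModel, str, int]:
    """Construct one gene laid out from ``start``; returns the transcript
    model, its CDS sequence (5'->3'), and the genomic end position."""
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(1, 5))
    n_codons = int(rng.integers(100, 300))
    cds_len = 3 * n_codons
    utr5 = int(rng.integers(20, 150))
    utr3 = int(rng.integers(50, 300))
    tx_len = utr5 + cds_len + utr3
    # split the transcript into exons at random interior cut points
    if n_exons > 1:
        cuts = np.sort(rng.choice(np.arange(1, tx_len), size=n_exons - 1, replace=False))
        exon_lens = np.diff(np.concatenate([[0], cuts, [tx_len]]))
    else:
        exon_lens = np.array([tx_len])
    intron_lens = rng.integers(60, 800, size=n_exons - 1)
    # genomic exon intervals, left to right
    exons: list[tuple[int, int]] = []
    cursor = start
    # transcript runs left->right genomically for '+', right->left for '-'
    lens = exon_lens if strand == "+" else exon_lens[::-1]
    for i, el in enumerate(lens):
        exons.append((cursor, cursor + int(el) - 1))
        cursor += int(el)
        if i < n_exons - 1:
            cursor += int(intron_lens[i])
    end = exons[-1][1]
    # map transcript-space CDS [utr5, utr5+cds_len) onto genomic exons
    cds_intervals: list[tuple[int, int]] = []
    t_lo, t_hi = utr5, utr5 + cds_len  # half-open, transcript coords
    t_cursor = 0
    ordered = exons if strand == "+" else exons[::-1]
    for gs, ge in ordered:
        el = ge - gs + 1
        a = max(t_lo, t_cursor)
        b = min(t_hi, t_cursor + el)
        if a < b:
            if strand == "+":
                cds_intervals.append((gs + (a - t_cursor), gs + (b - t_cursor) - 1))
            else:
                cds_intervals.append((ge - (b - t_cursor) + 1, ge - (a - t_cursor)))
        t_cursor += el
    cds_intervals.sort()
    cds_seq = _make_cds(rng, n_codons)
    tx = TranscriptModel(
        transcript_id=f"{gene_id}.t1",
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        start=start,
        end=end,
        exons=tuple(exons),
        cds=tuple(cds_intervals),
    )
    return tx, cds_seq, end


def _gff3_records(tx: TranscriptModel) -> list[str]:
    def line(ftype: str, s: int, e: int, attrs: str) -> str:
        return (
            f"{tx.chrom}\tpoolai_sim\t{ftype}\t{s}\t{e}\t.\t{tx.strand}\t"
            f"{'.' if ftype != 'CDS' else '0'}\t{attrs}\n"
        )

    gid, tid = tx.gene_id, tx.transcript_id
    out = [
        line("gene", tx.start, tx.end, f"ID={gid}"),
        line("mRNA", tx.start, tx.end, f"ID={tid};Parent={gid}"),
    ]
    for i, (s, e) in enumerate(tx.exons, 1):
        out.append(line("exon", s, e, f"ID={tid}.exon{i};Parent={tid}"))
    # CDS features share an ID per GFF3 convention; explicit UTRs emitted
    # so the annotation is self-describing even without exon/CDS inference
    cds_start = min(s for s, _ in tx.cds)
    cds_end = max(e for _, e in tx.cds)
    phase = 0
    ordered = tx.cds if tx.strand == "+" else tx.cds[::-1]
    for s, e in ordered:
        out.append(
            f"{tx.chrom}\tpoolai_sim\tCDS\t{s}\t{e}\t.\t{tx.strand}\t{phase}\t"
            f"ID={tid}.cds;Parent={tid}\n"
        )
        phase = (3 - ((e - s + 1 - phase) % 3)) % 3
    for s, e in tx.exons:
        for lo, hi, left_of_cds in ((s, min(e, cds_start - 1), True), (max(s, cds_end + 1), e, False)):
            if lo > hi:
                continue
            if tx.strand == "+":
                utr = "five_prime_UTR" if left_of_cds else "three_prime_UTR"
            else:
                utr = "three_prime_UTR" if left_of_cds else "five_prime_UTR"
            out.append(line(utr, lo, hi, f"Parent={tid}"))
    return out


def generate_reference(config: SimConfig) -> ReferenceBundle:
    """Build the toy genome, gene GFF3 and lncRNA GTF.

    Genes are laid out left to right with intergenic gaps larger than
    10 kb, so every context class (including far-intergenic) is
    reachable; lncRNAs and short assembly gaps (runs of N) are placed in
    intergenic space without overlapping protein-coding mRNAs.  Raises
    :class:`SizingError` if the chromosomes cannot hold the requested
    features.
    """
    rng = config.streams()["reference"]
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    # karyotype-like length gradient (longest = chrom_length, shortest 60%)
    denom = max(1, config.n_chromosomes - 1)
    lengths = [
        int(config.chrom_length * (1.0 - 0.4 * i / denom))
        for i in range(config.n_chromosomes)
    ]
    genome = {
        c: rng.choice(list("ACGT"), size=ln) for c, ln in zip(chroms, lengths)
    }
    # genes allocated proportional to chromosome length (largest remainder)
    shares = [ln / sum(lengths) * config.n_genes for ln in lengths]
    per_chrom = [int(s) for s in shares]
    order_rem = sorted(
        range(config.n_chromosomes), key=lambda i: shares[i] - per_chrom[i],
        reverse=True,
    )
    for i in order_rem[: config.n_genes - sum(per_chrom)]:
        per_chrom[i] += 1
    transcripts: list[TranscriptModel] = []
    gff3: list[str] = []
    intergenic: list[tuple[str, int, int]] = []
    gene_i = 0
    for chrom, chrom_len, n_here in zip(chroms, lengths, per_chrom):
        cursor = int(rng.integers(12_000, 18_000))
        prev_end = 0
        for _ in range(n_here):
            gene_i += 1
            gid = f"gene{gene_i:04d}"
            tx, cds_seq, end = _build_gene(rng, gid, chrom, cursor)
            if end > chrom_len - 1_000:
                raise SizingError(
                    f"chrom_length {config.chrom_length} too small for "
                    f"{n_here} genes on {chrom} (length {chrom_len})"
                )
            # write the CDS sequence into the genome (left-to-right genomic
            # order equals the reverse complement for minus-strand genes)
            genomic = cds_seq if tx.strand == "+" else cds_seq.translate(_COMPLEMENT)[::-1]
            off = 0
            for s, e in tx.cds:
                n = e - s + 1
                genome[chrom][s - 1 : e] = list(genomic[off : off + n])
                off += n
            transcripts.append(tx)
            gff3.extend(_gff3_records(tx))
            if cursor - prev_end > 2_000:
                intergenic.append((chrom, prev_end + 1_000, cursor - 1_000))
            prev_end = end
            cursor = end + int(rng.integers(10_500, 16_000))
        if chrom_len - prev_end > 2_000:
            intergenic.append((chrom, prev_end + 1_000, chrom_len - 500))

    # lncRNAs into intergenic space (shuffled deterministic order)
    order = rng.permutation(len(intergenic))
    slots = [intergenic[i] for i in order]
    lncrnas: list[LncRnaModel] = []
    gtf: list[str] = []
    li = 0
    used_slots: set[int] = set()
    for si, (chrom, lo, hi) in enumerate(slots):
        if li >= config.n_lncrnas:
            break
        length = int(rng.integers(400, 2_000))
        if hi - lo < length + 200:
            continue
        used_slots.add(si)
        start = int(rng.integers(lo, hi - length))
        strand = "+" if rng.random() < 0.5 else "-"
        li += 1
        lid = f"lnc{li:04d}"
        ln = LncRnaModel(f"{lid}.1", chrom, strand, start, start + length - 1)
        lncrnas.append(ln)
        attrs = f'gene_id "{lid}"; transcript_id "{lid}.1";'
        for ftype in ("transcript", "exon"):
            gtf.append(
                f"{chrom}\tpoolai_sim\t{ftype}\t{ln.start}\t{ln.end}\t.\t"
                f"{strand}\t.\t{attrs}\n"
            )
    if li < config.n_lncrnas:
        raise SizingError(
            f"could only place {li} of {config.n_lncrnas} lncRNAs; "
            "increase chrom_length or reduce n_genes"
        )
    # assembly gaps (runs of N) in remaining intergenic space
    placed_gaps = 0
    for si, (chrom, lo, hi) in enumerate(slots):
        if placed_gaps >= 2 * config.n_chromosomes:
            break
        if si in used_slots or hi - lo < 800:
            continue
        start = hi - 400
        genome[chrom][start - 1 : start + 149] = list("N" * 150)
        placed_gaps += 1

    genome_str = {c: "".join(genome[c]) for c in chroms}
    return ReferenceBundle(
        genome=genome_str,
        transcripts=transcripts,
        lncrnas=lncrnas,
        gff3_lines=gff3,
        gtf_lines=gtf,
    )


# ---------------------------------------------------------------------------
# trait designs and phenotypes


def generate_trait_designs(config: SimConfig) -> dict[str, TraitDesign]:
    """Assign each trait its high/low family groups (families reused
    across traits, as in a shared panel of divergent families)."""
    rng = config.streams()["designs"]
    fams = np.array(config.families)
    designs = {}
    for trait in config.traits:
        picked = rng.choice(len(fams), size=config.n_high + config.n_low, replace=False)
        designs[trait] = TraitDesign(
            trait,
            tuple(sorted(fams[picked[: config.n_high]])),
            tuple(sorted(fams[picked[config.n_high :]])),
        )
    return designs


def generate_phenotypes(
    config: SimConfig, designs: dict[str, TraitDesign] | None = None
) -> pd.DataFrame:
    """Family-average phenotype table consistent with the trait designs.

    Members of a trait's planted high/low group draw their family mean
    from that group's target distribution (separation scaled by
    ``phenotype_separation``); unselected families sit between the
    groups.  Fillet colour is emitted as L*/a*/b* triplets chosen so the
    derived whiteness index hits the target whiteness distribution.
    """
    if designs is None:
        designs = generate_trait_designs(config)
    rng = config.streams()["phenotypes"]
    fams = list(config.families)
    table: dict[str, np.ndarray] = {}
    for trait in config.traits:
        (mu_hi, sd_hi), (mu_lo, sd_lo) = PHENOTYPE_TARGETS.get(
            trait, ((1.0, 0.1), (0.0, 0.1))
        )
        mid = (mu_hi + mu_lo) / 2.0
        half = (mu_hi - mu_lo) / 2.0 * config.phenotype_separation
        design = designs[trait]
        values = np.empty(len(fams))
        for i, fam in enumerate(fams):
            if fam in design.high_families:
                values[i] = rng.normal(mid + half, sd_hi)
            elif fam in design.low_families:
                values[i] = rng.normal(mid - half, sd_lo)
            else:
                # unselected families fill the central band between groups
                values[i] = rng.uniform(mid - abs(half) / 2, mid + abs(half) / 2)
        table[trait] = values
    df = pd.DataFrame(table, index=pd.Index(fams, name="family"))
    if "whiteness" in df.columns:
        w = df["whiteness"].clip(upper=90.0)
        a = rng.uniform(1.0, 4.0, size=len(df))
        b = rng.uniform(4.0, 8.0, size=len(df))
        L = 100.0 - np.sqrt(np.maximum((100.0 - w) ** 2 - a**2 - b**2, 0.0))
        df["L"], df["a"], df["b"] = L, a, b
        df["whiteness"] = 100.0 - np.sqrt((100.0 - L) ** 2 + a**2 + b**2)
    return df


# ---------------------------------------------------------------------------
# family pools + truth


NULL = "null"
IMB_HIGH = "imbalanced_high"
IMB_LOW = "imbalanced_low"
EXC_HIGH = "exclusive_high"
EXC_LOW = "exclusive_low"


@dataclass
class PoolData:
    """Simulated pooled counts for all families plus the truth table."""

    config: SimConfig
    sites: list[SnpKey]
    families: tuple[str, ...]
    ref_reads: np.ndarray  # (n_sites, n_families)
    alt_reads: np.ndarray
    quality: pd.DataFrame  # per site: QD FS MQ DP lowqual
    truth: pd.DataFrame  # per site: p0 + class/freq columns per trait

    def to_pooled_counts(self) -> dict[SnpKey, list[PooledSiteCount]]:
        out: dict[SnpKey, list[PooledSiteCount]] = {}
        for i, key in enumerate(self.sites):
            q = self.quality.iloc[i]
            qual = VariantSiteQuality(
                QD=float(q["QD"]), FS=float(q["FS"]), MQ=float(q["MQ"]), DP=int(q["DP"])
            )
            out[key] = [
                PooledSiteCount(
                    family=fam,
                    chrom=key.chrom,
                    pos=key.pos,
                    ref=key.ref,
                    alt=key.alt,
                    ref_reads=int(self.ref_reads[i, j]),
                    alt_reads=int(self.alt_reads[i, j]),
                    quality=qual,
                )
                for j, fam in enumerate(self.families)
            ]
        return out

    def write_vcfs(self, outdir: str | Path, chrom_lengths: dict[str, int]) -> dict[str, Path]:
        """One VCF v4.2 per family (single pooled sample, GT:AD:DP)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = ["##fileformat=VCFv4.2\n"]
        for chrom in sorted(chrom_lengths):
            header.append(f"##contig=<ID={chrom},length={chrom_lengths[chrom]}>\n")
        header += [
            '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n',
            '##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand phred">\n',
            '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n',
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n',
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n',
        ]
        paths = {}
        for j, fam in enumerate(self.families):
            path = outdir / f"{fam}.vcf"
            with path.open("w") as fh:
                fh.writelines(header)
                fh.write(
                    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                    f"{fam}\n"
                )
                for i, key in enumerate(self.sites):
                    r, a = int(self.ref_reads[i, j]), int(self.alt_reads[i, j])
                    gt = "0/0" if a == 0 else ("1/1" if r == 0 else "0/1")
                    q = self.quality.iloc[i]
                    info = (
                        f"QD={q['QD']:.2f};FS={q['FS']:.2f};"
                        f"MQ={q['MQ']:.2f};DP={int(q['DP'])}"
                    )
                    fh.write(
                        f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\t"
                        f"PASS\t{info}\tGT:AD:DP\t{gt}:{r},{a}:{r + a}\n"
                    )
            paths[fam] = path
        return paths


def _plant_classes(
    config: SimConfig, rng: np.random.Generator
) -> list[dict[str, str]]:
    """Per-site dict of trait -> truth class (traits at null omitted)."""
    out: list[dict[str, str]] = []
    traits = list(config.traits)
    # geometric-ish weights for how many traits share an imbalanced site
    kmax = len(traits)
    kw = np.array([2.0**-k for k in range(1, kmax + 1)])
    kw /= kw.sum()
    for _ in range(config.n_sites):
        u = rng.random()
        planted: dict[str, str] = {}
        if u < config.frac_exclusive:
            trait = traits[rng.integers(kmax)]
            planted[trait] = EXC_HIGH if rng.random() < 0.5 else EXC_LOW
        elif u < config.frac_exclusive + config.frac_imbalanced:
            k = int(rng.choice(np.arange(1, kmax + 1), p=kw))
            for ti in rng.choice(kmax, size=k, replace=False):
                planted[traits[ti]] = IMB_HIGH if rng.random() < 0.5 else IMB_LOW
        out.append(planted)
    return out


def generate_family_pools(
    config: SimConfig,
    reference: ReferenceBundle,
    designs: dict[str, TraitDesign] | None = None,
) -> PoolData:
    """Simulate pooled per-family allele counts at n_sites SNPs.

    Sites are dropped uniformly over the genome (their ref allele is the
    genome base).  The truth table records, per trait, the planted class
    and the realised expected group allele frequencies; when one site is
    planted for several traits with overlapping family groups, later
    traits take precedence in the family-frequency assignment and the
    realised frequencies reflect that.
    """
    if designs is None:
        designs = generate_trait_designs(config)
    streams = config.streams()
    rng = streams["pools"]
    qrng = streams["quality"]
    chroms = sorted(reference.genome)
    lengths = np.array([len(reference.genome[c]) for c in chroms], dtype=float)

    # unique genomic positions: a configurable fraction inside gene spans
    # (transcribed origin), the rest uniform with chromosome ~ length
    sites: list[SnpKey] = []
    seen: set[tuple[str, int]] = set()
    bases = "ACGT"
    txs = reference.transcripts
    tx_spans = np.array([t.end - t.start + 1 for t in txs], dtype=float)
    while len(sites) < config.n_sites:
        if txs and rng.random() < config.genic_fraction:
            tx = txs[int(rng.choice(len(txs), p=tx_spans / tx_spans.sum()))]
            chrom = tx.chrom
            pos = int(rng.integers(tx.start, tx.end + 1))
        else:
            ci = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
            chrom = chroms[ci]
            pos = int(rng.integers(1, len(reference.genome[chrom]) + 1))
        if (chrom, pos) in seen:
            continue
        ref = reference.genome[chrom][pos - 1]
        if ref not in bases:
            continue
        alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
        seen.add((chrom, pos))
        sites.append(SnpKey(chrom, pos, ref, alt))
    sites.sort()

    planted = _plant_classes(config, rng)
    fams = config.families
    fam_index = {f: j for j, f in enumerate(fams)}
    n, m = config.n_sites, len(fams)
    p0 = rng.uniform(0.1, 0.9, size=n)
    freq = np.tile(p0[:, None], (1, m))
    sqrt_r = np.sqrt(config.planted_ratio)

    truth_cols: dict[str, list] = {f"class_{t}": [NULL] * n for t in config.traits}
    for i, site_classes in enumerate(planted):
        odds0 = p0[i] / (1 - p0[i])
        for trait in config.traits:  # canonical order: later traits win
            cls = site_classes.get(trait)
            if cls is None:
                continue
            truth_cols[f"class_{trait}"][i] = cls
            d = designs[trait]
            hi = [fam_index[f] for f in d.high_families]
            lo = [fam_index[f] for f in d.low_families]
            if cls in (IMB_HIGH, IMB_LOW):
                sign = 1.0 if cls == IMB_HIGH else -1.0
                p_hi = odds0 * sqrt_r**sign / (1 + odds0 * sqrt_r**sign)
                p_lo = odds0 * sqrt_r**-sign / (1 + odds0 * sqrt_r**-sign)
                freq[i, hi] = p_hi
                freq[i, lo] = p_lo
            else:
                p_ex = float(np.clip(p0[i], 0.4, 0.7))
                present, absent = (hi, lo) if cls == EXC_HIGH else (lo, hi)
                freq[i, present] = p_ex
                freq[i, absent] = 0.0

    # family-to-family overdispersion (exact zeros/ones stay exact)
    c = config.beta_concentration
    interior = (freq > 0) & (freq < 1)
    jit = freq.copy()
    jit[interior] = rng.beta(freq[interior] * c, (1 - freq[interior]) * c)
    depth = rng.poisson(config.pool_depth_mean, size=(n, m))
    alt_reads = rng.binomial(depth, jit)
    ref_reads = depth - alt_reads

    # site-level quality annotations; a small fraction fail a hard filter
    qd = qrng.uniform(15, 35, size=n)
    fs = qrng.uniform(0, 10, size=n)
    mq = qrng.uniform(50, 60, size=n)
    lowqual = qrng.random(n) < config.frac_lowqual
    which = qrng.integers(0, 3, size=n)
    qd = np.where(lowqual & (which == 0), qrng.uniform(0.0, 1.9, size=n), qd)
    fs = np.where(lowqual & (which == 1), qrng.uniform(61.0, 180.0, size=n), fs)
    mq = np.where(lowqual & (which == 2), qrng.uniform(10.0, 39.0, size=n), mq)
    quality = pd.DataFrame(
        {
            "QD": np.round(qd, 2),
            "FS": np.round(fs, 2),
            "MQ": np.round(mq, 2),
            "DP": depth.sum(axis=1),
            "lowqual": lowqual,
        }
    )

    truth = pd.DataFrame(
        {
            "site": [str(k) for k in sites],
            "chrom": [k.chrom for k in sites],
            "pos": [k.pos for k in sites],
            "ref": [k.ref for k in sites],
            "alt": [k.alt for k in sites],
            "p0": p0,
            "lowqual": lowqual,
        }
    )
    for trait in config.traits:
        truth[f"class_{trait}"] = truth_cols[f"class_{trait}"]
        d = designs[trait]
        hi = [fam_index[f] for f in d.high_families]
        lo = [fam_index[f] for f in d.low_families]
        truth[f"fhigh_{trait}"] = freq[:, hi].mean(axis=1)
        truth[f"flow_{trait}"] = freq[:, lo].mean(axis=1)
    return PoolData(
        config=config,
        sites=sites,
        families=fams,
        ref_reads=ref_reads,
        alt_reads=alt_reads,
        quality=quality,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# DNA / cDNA genotype panel


@dataclass
class PanelData:
    dna: pd.DataFrame  # fish x SNP genotype strings
    cdna: pd.DataFrame
    events: pd.DataFrame  # fish, snp, dna_genotype, cdna_genotype


def generate_genotype_panel(config: SimConfig, pools: PoolData) -> PanelData:
    """Simulate fish-level DNA and cDNA genotypes for a SNP subset.

    DNA genotypes follow Hardy-Weinberg at each site's base frequency.
    cDNA equals DNA except at planted mono-allelic expression events:
    with probability ``frac_monoallelic`` a DNA-heterozygous call becomes
    homozygous for one randomly chosen allele in cDNA.
    """
    rng = config.streams()["panel"]
    n_snps = min(config.n_panel_snps, len(pools.sites))
    idx = np.sort(rng.choice(len(pools.sites), size=n_snps, replace=False))
    fish = [f"fish{i + 1:02d}" for i in range(config.n_panel_fish)]
    snp_ids = [str(pools.sites[i]) for i in idx]
    dna = {}
    for i in idx:
        key = pools.sites[i]
        p = float(pools.truth["p0"].iloc[i])
        gts = rng.choice(
            3, size=config.n_panel_fish, p=[(1 - p) ** 2, 2 * p * (1 - p), p**2]
        )
        col = []
        het = "/".join(sorted((key.ref, key.alt)))
        for g in gts:
            col.append({0: f"{key.ref}/{key.ref}", 1: het, 2: f"{key.alt}/{key.alt}"}[g])
        dna[str(key)] = col
    dna_df = pd.DataFrame(dna, index=pd.Index(fish, name="fish"))[snp_ids]
    cdna_df = dna_df.copy()
    events = []
    het_cells = [
        (f, s)
        for s in snp_ids
        for f in fish
        if len(set(dna_df.at[f, s].split("/"))) == 2
    ]
    if config.frac_monoallelic > 0 and not het_cells:
        warnings.warn("frac_monoallelic > 0 but no heterozygous DNA calls", stacklevel=2)
    for f, s in het_cells:
        if rng.random() < config.frac_monoallelic:
            alleles = dna_df.at[f, s].split("/")
            hom = alleles[int(rng.integers(2))]
            cdna_df.at[f, s] = f"{hom}/{hom}"
            events.append((f, s, dna_df.at[f, s], cdna_df.at[f, s]))
    events_df = pd.DataFrame(
        events, columns=["fish", "snp", "dna_genotype", "cdna_genotype"]
    )
    return PanelData(dna=dna_df, cdna=cdna_df, events=events_df)


# ---------------------------------------------------------------------------
# whole-study orchestration


@dataclass
class SimulatedStudy:
    config: SimConfig
    reference: ReferenceBundle
    designs: dict[str, TraitDesign]
    phenotypes: pd.DataFrame
    pools: PoolData
    panel: PanelData

    def write(self, outdir: str | Path) -> dict[str, object]:
        """Serialise the full study (FASTA/GFF3/GTF/VCFs/TSVs)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, object] = self.reference.write(outdir / "reference")
        paths["vcfs"] = self.pools.write_vcfs(
            outdir / "vcf", self.reference.chrom_lengths
        )
        self.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t")
        self.pools.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.panel.dna.to_csv(outdir / "panel_dna.tsv", sep="\t")
        self.panel.cdna.to_csv(outdir / "panel_cdna.tsv", sep="\t")
        self.panel.events.to_csv(outdir / "panel_events.tsv", sep="\t", index=False)
        rows = []
        for trait, d in self.designs.items():
            rows.append((trait, ",".join(d.high_families), ",".join(d.low_families)))
        pd.DataFrame(rows, columns=["trait", "high_families", "low_families"]).to_csv(
            outdir / "designs.tsv", sep="\t", index=False
        )
        paths["outdir"] = outdir
        return paths


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate the complete synthetic study in memory."""
    reference = generate_reference(config)
    designs = generate_trait_designs(config)
    phenotypes = generate_phenotypes(config, designs)
    pools = generate_family_pools(config, reference, designs)
    panel = generate_genotype_panel(config, pools)
    return SimulatedStudy(
        config=config,
        reference=reference,
        designs=designs,
        phenotypes=phenotypes,
        pools=pools,
        panel=panel,
    )


def read_designs(path: str | Path) -> dict[str, TraitDesign]:
    """Read a designs.tsv back into TraitDesign objects."""
    df = pd.read_csv(path, sep="\t")
    return {
        row["trait"]: TraitDesign(
            row["trait"],
            tuple(row["high_families"].split(",")),
            tuple(row["low_families"].split(",")),
        )
        for _, row in df.iterrows()
    }
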