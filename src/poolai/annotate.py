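"""Genomic-context classification of SNPs and coding-effect calling.

Each SNP receives exactly one context class.  Within an mRNA span the
precedence is CDS > 5'UTR > 3'UTR > intron (most severe consequence
first, deterministic under overlapping transcripts).  SNPs outside every
protein-coding mRNA are checked against lncRNA annotations; remaining
intergenic SNPs within 5 kb (inclusive) of an mRNA are labelled upstream
or downstream relative to that mRNA's strand, the rest intergenic_far.

Coding effects are called by rebuilding the codon containing the SNP from
the spliced CDS (reverse-complemented on the minus strand) and
translating reference and alternate codons with the standard genetic
code.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from poolai._util import round_half_away
from poolai.variant_io import SnpKey

UPSTREAM_WINDOW = 5_000  # bp, inclusive


class Context(enum.Enum):
    CDS = "CDS"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    INTRON = "intron"
    UPSTREAM = "upstream_5kb"
    DOWNSTREAM = "downstream_5kb"
    INTERGENIC_FAR = "intergenic_far"
    LNCRNA = "lncRNA"


class CodingEffect(enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    NOT_APPLICABLE = "not_applicable"


# genic precedence when transcripts overlap, most severe first
_GENIC_PRECEDENCE = (Context.CDS, Context.UTR5, Context.UTR3, Context.INTRON)


@dataclass(frozen=True)
class TranscriptModel:
    """An mRNA with its exon and CDS intervals (1-based inclusive)."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def tss(self) -> int:
        """Transcription start (genomic position of the 5' end)."""
        return self.start if self.strand == "+" else self.end

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def subcontext(self, pos: int) -> Context:
        """CDS / UTR5 / UTR3 / intron for a position inside the span."""
        if any(s <= pos <= e for s, e in self.cds):
            return Context.CDS
        in_exon = any(s <= pos <= e for s, e in self.exons)
        if not in_exon:
            return Context.INTRON
        if not self.cds:
            # non-coding transcript modelled as mRNA: call exonic UTR3
            return Context.UTR3
        cds_start = min(s for s, _ in self.cds)
        cds_end = max(e for _, e in self.cds)
        if pos < cds_start:
            return Context.UTR5 if self.strand == "+" else Context.UTR3
        if pos > cds_end:
            return Context.UTR3 if self.strand == "+" else Context.UTR5
        return Context.INTRON  # between CDS chunks but exonic: unreachable
                               # for consistent models


@dataclass(frozen=True)
class LncRnaModel:
    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int


@dataclass(frozen=True)
class SnpAnnotation:
    snp: SnpKey
    context: Context
    feature_id: str | None = None  # host gene or lncRNA transcript
    coding_effect: CodingEffect = CodingEffect.NOT_APPLICABLE
    ref_aa: str | None = None
    alt_aa: str | None = None


# ---------------------------------------------------------------------------
# annotation loading


def _tx_from_db(db: gffutils.FeatureDB) -> list[TranscriptModel]:
    out = []
    for mrna in db.features_of_type("mRNA"):
        exons = tuple(
            sorted((f.start, f.end) for f in db.children(mrna, featuretype="exon"))
        )
        cds = tuple(
            sorted((f.start, f.end) for f in db.children(mrna, featuretype="CDS"))
        )
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        out.append(
            TranscriptModel(
                transcript_id=mrna.id,
                gene_id=gene_id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                start=mrna.start,
                end=mrna.end,
                exons=exons or ((mrna.start, mrna.end),),
                cds=cds,
            )
        )
    return out


def load_transcripts(gff3_path: str | Path) -> list[TranscriptModel]:
    """Load gene -> mRNA -> exon/CDS models from a GFF3 file."""
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    return _tx_from_db(db)


def load_lncrnas(gtf_path: str | Path) -> list[LncRnaModel]:
    """Load lncRNA transcript spans from a GTF file (may be empty)."""
    path = Path(gtf_path)
    if path.stat().st_size == 0:
        return []
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force_gff=False,
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    out = []
    for tr in db.features_of_type("transcript"):
        tid = tr.attributes.get("transcript_id", [tr.id])[0]
        out.append(LncRnaModel(tid, tr.seqid, tr.strand, tr.start, tr.end))
    return out


# ---------------------------------------------------------------------------
# context classification


class GenomeAnnotationIndex:
    """Interval indexes over transcripts and lncRNAs for fast lookup."""

    def __init__(
        self,
        transcripts: Sequence[TranscriptModel],
        lncrnas: Sequence[LncRnaModel] = (),
        chrom_lengths: Mapping[str, int] | None = None,
    ):
        self.transcripts = list(transcripts)
        self.lncrnas = list(lncrnas)
        self.chrom_lengths = dict(chrom_lengths or {})
        self._tx_tree: dict[str, IntervalTree] = {}
        self._tx_window: dict[str, IntervalTree] = {}
        self._lnc_tree: dict[str, IntervalTree] = {}
        for tx in self.transcripts:
            # intervaltree is half-open; +1 converts inclusive ends
            self._tx_tree.setdefault(tx.chrom, IntervalTree()).addi(
                tx.start, tx.end + 1, tx
            )
            self._tx_window.setdefault(tx.chrom, IntervalTree()).addi(
                max(1, tx.start - UPSTREAM_WINDOW), tx.end + UPSTREAM_WINDOW + 1, tx
            )
        for ln in self.lncrnas:
            self._lnc_tree.setdefault(ln.chrom, IntervalTree()).addi(
                ln.start, ln.end + 1, ln
            )

    def classify(self, snp: SnpKey) -> SnpAnnotation:
        """Assign the single genomic-context class for one SNP."""
        if self.chrom_lengths:
            length = self.chrom_lengths.get(snp.chrom)
            if length is not None and not 1 <= snp.pos <= length:
                raise ValueError(
                    f"{snp}: position outside {snp.chrom} (length {length})"
                )
        containing = [
            iv.data
            for iv in self._tx_tree.get(snp.chrom, IntervalTree()).at(snp.pos)
        ]
        if containing:
            best: tuple[int, str, TranscriptModel] | None = None
            for tx in containing:
                ctx = tx.subcontext(snp.pos)
                rank = _GENIC_PRECEDENCE.index(ctx)
                if best is None or (rank, tx.gene_id) < (best[0], best[1]):
                    best = (rank, tx.gene_id, tx)
            rank, gene_id, _ = best
            return SnpAnnotation(snp, _GENIC_PRECEDENCE[rank], gene_id)
        lnc = sorted(
            (iv.data for iv in self._lnc_tree.get(snp.chrom, IntervalTree()).at(snp.pos)),
            key=lambda l: l.transcript_id,
        )
        if lnc:
            return SnpAnnotation(snp, Context.LNCRNA, lnc[0].transcript_id)
        nearby = [
            iv.data
            for iv in self._tx_window.get(snp.chrom, IntervalTree()).at(snp.pos)
        ]
        candidates = []
        for tx in nearby:
            if snp.pos < tx.start:
                dist = tx.start - snp.pos
                side_5prime = tx.strand == "+"
            else:
                dist = snp.pos - tx.end
                side_5prime = tx.strand == "-"
            if dist <= UPSTREAM_WINDOW:
                candidates.append((dist, tx.gene_id, side_5prime))
        if candidates:
            _, gene_id, side_5prime = min(candidates)
            ctx = Context.UPSTREAM if side_5prime else Context.DOWNSTREAM
            return SnpAnnotation(snp, ctx, gene_id)
        return SnpAnnotation(snp, Context.INTERGENIC_FAR)

    def classify_all(self, snps: Iterable[SnpKey]) -> list[SnpAnnotation]:
        return [self.classify(s) for s in snps]


# ---------------------------------------------------------------------------
# coding effect


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


class ReferenceMismatchError(ValueError):
    """The reference base in the genome disagrees with the SNP's ref allele."""


def spliced_cds(tx: TranscriptModel, genome: Mapping[str, str]) -> str:
    """The transcript's CDS sequence in translation (5'->3') order."""
    chrom_seq = genome[tx.chrom]
    parts = [str(chrom_seq[s - 1 : e]).upper() for s, e in tx.cds]
    seq = "".join(parts)
    return _revcomp(seq) if tx.strand == "-" else seq


def coding_effect(
    snp: SnpKey, tx: TranscriptModel, genome: Mapping[str, str]
) -> tuple[CodingEffect, str, str]:
    """Call the protein-level effect of a CDS SNP on one transcript.

    Returns (effect, ref_aa, alt_aa).  Raises ``ReferenceMismatchError``
    when the genome base at the SNP position differs from the SNP's ref
    allele, and ValueError when the SNP is outside the CDS or the CDS
    length is not a multiple of 3 (flagged transcript, site skipped by
    callers).
    """
    if tx.cds_length % 3 != 0:
        raise ValueError(f"{tx.transcript_id}: CDS length not divisible by 3")
    # genomic offset into the plus-strand concatenation of CDS chunks
    plus_offset = 0
    found = False
    for s, e in tx.cds:
        if s <= snp.pos <= e:
            plus_offset += snp.pos - s
            found = True
            break
        plus_offset += e - s + 1
    if not found:
        raise ValueError(f"{snp} not within CDS of {tx.transcript_id}")
    cds_seq = spliced_cds(tx, genome)
    if tx.strand == "+":
        offset = plus_offset
        ref_base, alt_base = snp.ref, snp.alt
    else:
        offset = len(cds_seq) - 1 - plus_offset
        ref_base = snp.ref.translate(_COMPLEMENT)
        alt_base = snp.alt.translate(_COMPLEMENT)
    if cds_seq[offset] != ref_base:
        raise ReferenceMismatchError(
            f"{snp}: CDS has {cds_seq[offset]} where ref allele implies {ref_base}"
        )
    codon_i = offset // 3
    within = offset % 3
    ref_codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        effect = CodingEffect.SYNONYMOUS
    elif alt_aa == "*":
        effect = CodingEffect.STOP_GAIN
    elif ref_aa == "*":
        effect = CodingEffect.STOP_LOSS
    else:
        effect = CodingEffect.MISSENSE
    return effect, ref_aa, alt_aa


def annotate_snps(
    snps: Iterable[SnpKey],
    index: GenomeAnnotationIndex,
    genome: Mapping[str, str] | None = None,
) -> list[SnpAnnotation]:
    """Classify contexts and, when a genome is given, call coding effects
    for CDS SNPs.  Reference mismatches and inconsistent transcripts are
    recorded as annotations without an effect call rather than raised."""
    tx_by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in index.transcripts:
        tx_by_gene.setdefault(tx.gene_id, []).append(tx)
    out = []
    for snp in snps:
        ann = index.classify(snp)
        if ann.context is Context.CDS and genome is not None:
            host = next(
                (
                    tx
                    for tx in tx_by_gene.get(ann.feature_id, [])
                    if any(s <= snp.pos <= e for s, e in tx.cds)
                ),
                None,
            )
            if host is not None:
                try:
                    effect, ref_aa, alt_aa = coding_effect(snp, host, genome)
                    ann = SnpAnnotation(
                        snp, Context.CDS, ann.feature_id, effect, ref_aa, alt_aa
                    )
                except (ReferenceMismatchError, ValueError):
                    pass
        out.append(ann)
    return out


# ---------------------------------------------------------------------------
# summary table


def summarize_classes(annotations: Sequence[SnpAnnotation]) -> pd.DataFrame:
    """Context and coding-effect tally with percentages of the total.

    Emits one row per context plus aggregate rows: ``genic`` (CDS + UTRs
    + intron), ``intergenic`` (upstream + downstream + far) and
    ``non_synonymous`` (missense + stop gain/loss among CDS SNPs).
    lncRNA is its own context row.  Percentages are count/total*100 to
    two decimals; context counts partition the input, so they sum to the
    total.
    """
    total = len(annotations)
    ctx_counts = {c: 0 for c in Context}
    eff_counts = {e: 0 for e in CodingEffect}
    for a in annotations:
        ctx_counts[a.context] += 1
        eff_counts[a.coding_effect] += 1
    rows: list[tuple[str, int]] = []
    genic = sum(
        ctx_counts[c]
        for c in (Context.CDS, Context.UTR5, Context.UTR3, Context.INTRON)
    )
    intergenic = sum(
        ctx_counts[c]
        for c in (Context.UPSTREAM, Context.DOWNSTREAM, Context.INTERGENIC_FAR)
    )
    rows.append(("intergenic", intergenic))
    rows.append(("intergenic_far", ctx_counts[Context.INTERGENIC_FAR]))
    rows.append(("upstream_5kb", ctx_counts[Context.UPSTREAM]))
    rows.append(("downstream_5kb", ctx_counts[Context.DOWNSTREAM]))
    rows.append(("genic", genic))
    rows.append(("UTR5", ctx_counts[Context.UTR5]))
    rows.append(("UTR3", ctx_counts[Context.UTR3]))
    rows.append(("CDS", ctx_counts[Context.CDS]))
    rows.append(("intron", ctx_counts[Context.INTRON]))
    nonsyn = (
        eff_counts[CodingEffect.MISSENSE]
        + eff_counts[CodingEffect.STOP_GAIN]
        + eff_counts[CodingEffect.STOP_LOSS]
    )
    rows.append(("non_synonymous", nonsyn))
    rows.append(("stop_gain", eff_counts[CodingEffect.STOP_GAIN]))
    rows.append(("missense", eff_counts[CodingEffect.MISSENSE]))
    rows.append(("synonymous", eff_counts[CodingEffect.SYNONYMOUS]))
    rows.append(("lncRNA", ctx_counts[Context.LNCRNA]))
    rows.append(("total", total))
    df = pd.DataFrame(rows, columns=["class", "count"])
    df["percent"] = [
        round_half_away(c / total * 100.0, 2) if total else 0.0 for c in df["count"]
    ]
    return df


def class_percentage(count: int, total: int) -> float:
    """A single printed-table percentage: count/total*100 to two decimals."""
    return round_half_away(count / total * 100.0, 2)
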