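"""Genomic-context classification and coding-effect calling."""

import numpy as np
import pytest
from Bio.Seq import Seq

from poolai.annotate import (
    CodingEffect,
    Context,
    GenomeAnnotationIndex,
    LncRnaModel,
    ReferenceMismatchError,
    SnpAnnotation,
    TranscriptModel,
    class_percentage,
    coding_effect,
    spliced_cds,
    summarize_classes,
)
from poolai.variant_io import SnpKey

# a two-exon plus-strand gene: exon1 1001-1200, intron, exon2 1501-1800;
# CDS 1101-1200 + 1501-1700, so 5'UTR 1001-1100 and 3'UTR 1701-1800
TX_PLUS = TranscriptModel(
    "g1.t1", "g1", "chr1", "+", 1001, 1800,
    exons=((1001, 1200), (1501, 1800)),
    cds=((1101, 1200), (1501, 1700)),
)


def key(pos, ref="A", alt="G", chrom="chr1"):
    return SnpKey(chrom, pos, ref, alt)


class TestContextClassification:
    index = GenomeAnnotationIndex([TX_PLUS])

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (1150, Context.CDS),
            (1600, Context.CDS),
            (1050, Context.UTR5),
            (1750, Context.UTR3),
            (1350, Context.INTRON),  # inside span, between exons
            (1001, Context.UTR5),
            (1800, Context.UTR3),
        ],
    )
    def test_genic_subcontexts(self, pos, expected):
        assert self.index.classify(key(pos)).context is expected

    @pytest.mark.parametrize(
        "offset,expected",
        [
            (-4999, Context.UPSTREAM),
            (-5000, Context.UPSTREAM),  # inclusive boundary
            (-5001, Context.INTERGENIC_FAR),
        ],
    )
    def test_5kb_upstream_boundary(self, offset, expected):
        # same gene shifted away from the chromosome origin
        tx = TranscriptModel(
            "g1.t1", "g1", "chr1", "+", 100_001, 100_800,
            exons=((100_001, 100_800),), cds=((100_101, 100_700),),
        )
        index = GenomeAnnotationIndex([tx])
        assert index.classify(key(100_001 + offset)).context is expected

    @pytest.mark.parametrize(
        "offset,expected",
        [
            (5000, Context.DOWNSTREAM),
            (5001, Context.INTERGENIC_FAR),
        ],
    )
    def test_5kb_downstream_boundary(self, offset, expected):
        assert self.index.classify(key(1800 + offset)).context is expected

    def test_minus_strand_flips_upstream_downstream(self):
        tx = TranscriptModel(
            "g2.t1", "g2", "chr1", "-", 1001, 1800,
            exons=TX_PLUS.exons, cds=TX_PLUS.cds,
        )
        index = GenomeAnnotationIndex([tx])
        assert index.classify(key(900)).context is Context.DOWNSTREAM
        assert index.classify(key(2000)).context is Context.UPSTREAM
        # UTRs flip too: genomic-left of CDS is 3' on the minus strand
        assert index.classify(key(1050)).context is Context.UTR3
        assert index.classify(key(1750)).context is Context.UTR5

    def test_cds_takes_precedence_over_overlapping_intron(self):
        # second transcript whose intron covers the first's CDS
        tx2 = TranscriptModel(
            "g0.t1", "g0", "chr1", "+", 901, 2000,
            exons=((901, 950), (1901, 2000)), cds=((901, 950), (1901, 2000)),
        )
        index = GenomeAnnotationIndex([TX_PLUS, tx2])
        assert index.classify(key(1150)).context is Context.CDS
        assert index.classify(key(1150)).feature_id == "g1"

    def test_lncrna_only_outside_mrnas(self):
        lnc_inside = LncRnaModel("ln1.1", "chr1", "+", 1100, 1300)
        lnc_outside = LncRnaModel("ln2.1", "chr1", "+", 9000, 9500)
        index = GenomeAnnotationIndex([TX_PLUS], [lnc_inside, lnc_outside])
        assert index.classify(key(1150)).context is Context.CDS
        assert index.classify(key(9100)).context is Context.LNCRNA

    def test_position_beyond_chromosome_is_an_error(self):
        index = GenomeAnnotationIndex([TX_PLUS], chrom_lengths={"chr1": 10_000})
        with pytest.raises(ValueError, match="outside"):
            index.classify(key(10_001))


def make_genome_with(tx, cds_seq, length=3000, seed=0):
    rng = np.random.default_rng(seed)
    arr = rng.choice(list("ACGT"), size=length)
    genomic = cds_seq if tx.strand == "+" else str(Seq(cds_seq).reverse_complement())
    off = 0
    for s, e in tx.cds:
        arr[s - 1 : e] = list(genomic[off : off + (e - s + 1)])
        off += e - s + 1
    return {tx.chrom: "".join(arr)}


class TestCodingEffect:
    tx = TranscriptModel(
        "g1.t1", "g1", "chr1", "+", 101, 400,
        exons=((101, 400),), cds=((101, 112),),
    )

    def test_synonymous_wobble(self):
        genome = make_genome_with(self.tx, "ATGGAACCCTAA")
        # GAA -> GAG at the codon's third base: Glu -> Glu
        effect, ref_aa, alt_aa = coding_effect(key(106, "A", "G"), self.tx, genome)
        assert effect is CodingEffect.SYNONYMOUS
        assert (ref_aa, alt_aa) == ("E", "E")

    def test_missense(self):
        genome = make_genome_with(self.tx, "ATGGAACCCTAA")
        # CCC -> ACC at the codon's first base: Pro -> Thr
        effect, ref_aa, alt_aa = coding_effect(key(107, "C", "A"), self.tx, genome)
        assert effect is CodingEffect.MISSENSE
        assert (ref_aa, alt_aa) == ("P", "T")

    def test_stop_gain(self):
        genome = make_genome_with(self.tx, "ATGTGGCCCTAA")
        # TGG -> TGA: Trp -> stop
        effect, ref_aa, alt_aa = coding_effect(key(106, "G", "A"), self.tx, genome)
        assert effect is CodingEffect.STOP_GAIN
        assert (ref_aa, alt_aa) == ("W", "*")

    def test_stop_loss(self):
        genome = make_genome_with(self.tx, "ATGTGGCCCTAA")
        # TAA -> CAA: stop -> Gln
        effect, *_ = coding_effect(key(110, "T", "C"), self.tx, genome)
        assert effect is CodingEffect.STOP_LOSS

    def test_reference_mismatch_raises(self):
        genome = make_genome_with(self.tx, "ATGGAACCCTAA")
        with pytest.raises(ReferenceMismatchError):
            coding_effect(key(106, "T", "G"), self.tx, genome)

    def test_inconsistent_cds_length_rejected(self):
        tx = TranscriptModel(
            "g.t", "g", "chr1", "+", 101, 400, exons=((101, 400),), cds=((101, 111),)
        )
        with pytest.raises(ValueError, match="divisible"):
            coding_effect(key(106, "A", "G"), tx, {"chr1": "A" * 400})


class TestBruteForceOracle:
    """Codon-level effect call vs translation of the whole mutated CDS."""

    def random_transcript(self, rng, tid):
        from poolai.simgen import _build_gene

        tx, cds_seq, _ = _build_gene(rng, tid, "chr1", int(rng.integers(101, 2000)))
        return tx, cds_seq

    def test_agrees_on_random_toy_transcripts(self):
        rng = np.random.default_rng(42)
        n_checked = 0
        for i in range(200):
            tx, cds_seq = self.random_transcript(rng, f"g{i}")
            genome = make_genome_with(tx, cds_seq, length=30_000, seed=i)
            # pick a random CDS base to mutate
            intervals = tx.cds
            s, e = intervals[int(rng.integers(len(intervals)))]
            pos = int(rng.integers(s, e + 1))
            ref = genome[tx.chrom][pos - 1]
            alt = "ACGT"[("ACGT".index(ref) + 1 + int(rng.integers(3))) % 4]
            effect, ref_aa, alt_aa = coding_effect(
                key(pos, ref, alt), tx, genome
            )
            # oracle: translate the full mutated CDS and diff the proteins
            mutated = dict(genome)
            seq = list(mutated[tx.chrom])
            seq[pos - 1] = alt
            mutated[tx.chrom] = "".join(seq)
            prot_ref = str(Seq(spliced_cds(tx, genome)).translate())
            prot_alt = str(Seq(spliced_cds(tx, mutated)).translate())
            diffs = [
                (i, a, b) for i, (a, b) in enumerate(zip(prot_ref, prot_alt)) if a != b
            ]
            if effect is CodingEffect.SYNONYMOUS:
                assert not diffs
            else:
                assert len(diffs) == 1
                _, a, b = diffs[0]
                assert (a, b) == (ref_aa, alt_aa)
                expected = (
                    CodingEffect.STOP_GAIN
                    if b == "*"
                    else CodingEffect.STOP_LOSS if a == "*" else CodingEffect.MISSENSE
                )
                assert effect is expected
            n_checked += 1
        assert n_checked == 200


class TestSummary:
    def test_percentage_arithmetic(self):
        assert class_percentage(504, 7930) == pytest.approx(6.36)

    def test_partition_sums_to_total(self, small_study):
        index = GenomeAnnotationIndex(
            small_study.reference.transcripts,
            small_study.reference.lncrnas,
            small_study.reference.chrom_lengths,
        )
        anns = index.classify_all(small_study.pools.sites)
        df = summarize_classes(anns).set_index("class")
        contexts = [
            "intergenic_far", "upstream_5kb", "downstream_5kb",
            "UTR5", "UTR3", "CDS", "intron", "lncRNA",
        ]
        assert df.loc[contexts, "count"].sum() == df.loc["total", "count"]
        assert df.loc["genic", "count"] == df.loc[
            ["UTR5", "UTR3", "CDS", "intron"], "count"
        ].sum()

    def test_single_class_is_100_percent(self):
        anns = [SnpAnnotation(key(i), Context.INTERGENIC_FAR) for i in range(5)]
        df = summarize_classes(anns).set_index("class")
        assert df.loc["intergenic_far", "percent"] == 100.0
        assert df.loc["CDS", "percent"] == 0.0
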