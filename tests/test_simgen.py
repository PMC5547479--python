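"""The synthetic-study generator: determinism, conservation, planted truth."""

import math

import numpy as np
import pandas as pd
import pytest

from poolai import simgen
from poolai.annotate import load_lncrnas, load_transcripts
from poolai.imbalance import imbalance_score, pool_group_frequencies


def tiny(**kw):
    defaults = dict(seed=3, n_sites=200, n_genes=12, n_lncrnas=3)
    defaults.update(kw)
    return simgen.SimConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_sites", 0),
            ("n_families", -1),
            ("frac_imbalanced", 1.5),
            ("frac_monoallelic", -0.1),
            ("planted_ratio", 0.5),
        ],
    )
    def test_invalid_values_rejected(self, field, value):
        with pytest.raises(ValueError):
            tiny(**{field: value})

    def test_groups_cannot_exceed_families(self):
        with pytest.raises(ValueError, match="exceeds"):
            tiny(n_families=6, n_high=4, n_low=4)


class TestReference:
    def test_gene_and_chromosome_counts(self):
        ref = simgen.generate_reference(tiny(n_genes=10, n_chromosomes=2))
        assert len(ref.genome) == 2
        assert len(ref.transcripts) == 10
        assert len({t.chrom for t in ref.transcripts}) == 2

    def test_no_lncrnas_gives_empty_gtf(self, tmp_path):
        ref = simgen.generate_reference(tiny(n_lncrnas=0))
        paths = ref.write(tmp_path)
        assert paths["gtf"].read_text() == ""
        assert load_lncrnas(paths["gtf"]) == []

    def test_cds_lengths_multiple_of_three_after_reparse(self, tmp_path):
        ref = simgen.generate_reference(tiny())
        paths = ref.write(tmp_path)
        reparsed = load_transcripts(paths["gff3"])
        assert len(reparsed) == len(ref.transcripts)
        for tx in reparsed:
            assert tx.cds, tx.transcript_id
            assert tx.cds_length % 3 == 0

    def test_both_strands_and_multiexon_genes_present(self):
        ref = simgen.generate_reference(tiny())
        strands = {t.strand for t in ref.transcripts}
        assert strands == {"+", "-"}
        assert any(len(t.exons) > 1 for t in ref.transcripts)

    def test_lncrnas_do_not_overlap_mrnas(self):
        ref = simgen.generate_reference(tiny())
        for ln in ref.lncrnas:
            for tx in ref.transcripts:
                if tx.chrom == ln.chrom:
                    assert ln.end < tx.start or ln.start > tx.end

    def test_too_small_chromosomes_raise_sizing_error(self):
        with pytest.raises(simgen.SizingError):
            simgen.generate_reference(tiny(chrom_length=30_000, n_genes=20))


class TestPools:
    def test_record_count_conservation(self, small_study):
        cfg = small_study.config
        assert len(small_study.pools.sites) == cfg.n_sites
        assert small_study.pools.ref_reads.shape == (cfg.n_sites, cfg.n_families)
        for trait in cfg.traits:
            assert small_study.pools.truth[f"class_{trait}"].notna().all()

    def test_same_seed_gives_byte_identical_vcfs(self, tmp_path):
        cfg = tiny()
        for run in ("a", "b"):
            ref = simgen.generate_reference(cfg)
            pools = simgen.generate_family_pools(cfg, ref)
            pools.write_vcfs(tmp_path / run, ref.chrom_lengths)
        fam = cfg.families[0]
        assert (tmp_path / "a" / f"{fam}.vcf").read_bytes() == (
            tmp_path / "b" / f"{fam}.vcf"
        ).read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        refs = {}
        for s in (1, 2):
            cfg = tiny(seed=s)
            ref = simgen.generate_reference(cfg)
            pools = simgen.generate_family_pools(cfg, ref)
            pools.write_vcfs(tmp_path / str(s), ref.chrom_lengths)
            refs[s] = cfg.families[0]
        assert (tmp_path / "1" / "F01.vcf").read_bytes() != (
            tmp_path / "2" / "F01.vcf"
        ).read_bytes()

    def test_no_planting_gives_all_null_truth(self):
        cfg = tiny(frac_imbalanced=0.0, frac_exclusive=0.0)
        ref = simgen.generate_reference(cfg)
        pools = simgen.generate_family_pools(cfg, ref)
        for trait in cfg.traits:
            assert (pools.truth[f"class_{trait}"] == simgen.NULL).all()

    def test_null_scores_symmetric_on_log_scale(self):
        # with planted_ratio=1 every site is effectively null: mean log
        # score over >=1000 sites should sit within 3 SE of zero
        cfg = simgen.SimConfig(
            seed=9, n_sites=1500, planted_ratio=1.0, frac_exclusive=0.0,
            n_genes=12, n_lncrnas=2,
        )
        ref = simgen.generate_reference(cfg)
        pools = simgen.generate_family_pools(cfg, ref)
        designs = simgen.generate_trait_designs(cfg)
        design = designs[cfg.traits[0]]
        by_site = pools.to_pooled_counts()
        logs = []
        for key, counts in by_site.items():
            try:
                s = imbalance_score(pool_group_frequencies(counts, design))
            except ValueError:
                continue
            if isinstance(s, float) and s > 0:
                logs.append(math.log(s))
        logs = np.array(logs)
        assert len(logs) >= 1000
        se = logs.std(ddof=1) / math.sqrt(len(logs))
        assert abs(logs.mean()) < 3 * se

    def test_exclusive_sites_have_zero_alt_in_one_group(self, small_study):
        truth = small_study.pools.truth
        designs = small_study.designs
        fam_idx = {f: j for j, f in enumerate(small_study.pools.families)}
        checked = 0
        for trait, d in designs.items():
            sel = truth[f"class_{trait}"].isin([simgen.EXC_HIGH, simgen.EXC_LOW])
            for i in truth.index[sel]:
                cls = truth.at[i, f"class_{trait}"]
                absent = d.low_families if cls == simgen.EXC_HIGH else d.high_families
                cols = [fam_idx[f] for f in absent]
                assert small_study.pools.alt_reads[i, cols].sum() == 0
                checked += 1
        assert checked > 0


class TestPanel:
    def test_no_events_when_rate_zero(self):
        cfg = tiny(frac_monoallelic=0.0)
        ref = simgen.generate_reference(cfg)
        pools = simgen.generate_family_pools(cfg, ref)
        p = simgen.generate_genotype_panel(cfg, pools)
        assert p.dna.equals(p.cdna) and p.events.empty

    def test_events_are_het_dna_hom_cdna(self, small_study):
        for _, e in small_study.panel.events.iterrows():
            dna = small_study.panel.dna.at[e["fish"], e["snp"]]
            cdna = small_study.panel.cdna.at[e["fish"], e["snp"]]
            a, b = dna.split("/")
            x, y = cdna.split("/")
            assert a != b and x == y and x in (a, b)

    def test_event_fraction_near_configured_rate(self):
        cfg = tiny(seed=21, frac_monoallelic=0.1, n_panel_snps=150,
                   n_panel_fish=60, n_sites=300)
        ref = simgen.generate_reference(cfg)
        pools = simgen.generate_family_pools(cfg, ref)
        p = simgen.generate_genotype_panel(cfg, pools)
        n_het = sum(
            len(set(str(g).split("/"))) == 2
            for g in p.dna.to_numpy().ravel()
        )
        rate = len(p.events) / n_het
        # binomial 3-sigma band around 0.1
        sigma = math.sqrt(0.1 * 0.9 / n_het)
        assert abs(rate - 0.1) < 3 * sigma


class TestPhenotypes:
    def test_group_means_near_targets(self, small_study):
        # planted WBW groups should recover the target means within 2 SEM
        from poolai.phenotools import group_summary

        d = small_study.designs["WBW"]
        s = group_summary(d, small_study.phenotypes["WBW"])
        (mu_hi, sd_hi), (mu_lo, sd_lo) = simgen.PHENOTYPE_TARGETS["WBW"]
        assert abs(s.mean_high - mu_hi) < 2 * sd_hi / math.sqrt(s.n_high)
        assert abs(s.mean_low - mu_lo) < 2 * sd_lo / math.sqrt(s.n_low)

    def test_whiteness_consistent_with_lab_triplets(self, small_study):
        from poolai.phenotools import whiteness_index

        df = small_study.phenotypes
        for _, row in df.iterrows():
            assert row["whiteness"] == pytest.approx(
                whiteness_index(row["L"], row["a"], row["b"])
            )

    def test_zero_separation_equalises_groups_in_expectation(self):
        cfg = tiny(phenotype_separation=0.0, n_families=40, seed=17)
        designs = simgen.generate_trait_designs(cfg)
        df = simgen.generate_phenotypes(cfg, designs)
        d = designs["WBW"]
        hi = df.loc[list(d.high_families), "WBW"].mean()
        lo = df.loc[list(d.low_families), "WBW"].mean()
        (mu_hi, sd_hi), (mu_lo, sd_lo) = simgen.PHENOTYPE_TARGETS["WBW"]
        pooled_se = math.sqrt(sd_hi**2 / 4 + sd_lo**2 / 4)
        assert abs(hi - lo) < 4 * pooled_se
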