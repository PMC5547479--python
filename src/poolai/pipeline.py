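"""End-to-end orchestration: filter -> score -> merge, plus the run-all
driver with its manifest.

``run_ai_analysis`` is the core per-site loop shared by the CLI, the
analysis scripts and the tests: apply hard and pool filters once per
site, then score every trait contrast on the surviving sites.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from poolai import annotate as ann
from poolai import genomedist, simgen
from poolai.imbalance import (
    ClassifyThresholds,
    ImbalanceResult,
    TraitDesign,
    ZeroCoverageError,
    benjamini_hochberg,
    merge_traits,
    score_site,
)
from poolai.validation import genotype_concordance
from poolai.variant_io import (
    HardFilterThresholds,
    PooledSiteCount,
    PoolFilterThresholds,
    SnpKey,
    apply_hard_filters,
    apply_pool_filters,
)


@dataclass
class FilterSummary:
    n_input: int = 0
    n_hard_fail: int = 0
    n_pool_fail: int = 0
    n_dropped: int = 0  # monomorphic / zero coverage
    n_pass: int = 0


def filter_sites(
    counts_by_site: Mapping[SnpKey, Sequence[PooledSiteCount]],
    hard: HardFilterThresholds = HardFilterThresholds(),
    pool: PoolFilterThresholds = PoolFilterThresholds(),
) -> tuple[dict[SnpKey, Sequence[PooledSiteCount]], FilterSummary]:
    """Apply hard then pool filters; order does not affect the outcome."""
    summary = FilterSummary(n_input=len(counts_by_site))
    kept: dict[SnpKey, Sequence[PooledSiteCount]] = {}
    for key, counts in counts_by_site.items():
        if not apply_hard_filters(counts[0].quality, hard):
            summary.n_hard_fail += 1
            continue
        if not apply_pool_filters(counts, pool):
            summary.n_pool_fail += 1
            continue
        kept[key] = counts
        summary.n_pass += 1
    return kept, summary


def run_ai_analysis(
    counts_by_site: Mapping[SnpKey, Sequence[PooledSiteCount]],
    designs: Mapping[str, TraitDesign],
    hard: HardFilterThresholds = HardFilterThresholds(),
    pool: PoolFilterThresholds = PoolFilterThresholds(),
    classify: ClassifyThresholds = ClassifyThresholds(),
    alpha: float = 0.05,
) -> tuple[dict[str, list[ImbalanceResult]], FilterSummary]:
    """Filter once, then score every site for every trait contrast.

    Sites that are monomorphic within a trait's family groups, or have
    zero coverage in a group, are dropped for that trait only.
    """
    kept, summary = filter_sites(counts_by_site, hard, pool)
    results: dict[str, list[ImbalanceResult]] = {t: [] for t in designs}
    for key in sorted(kept):
        counts = kept[key]
        for trait, design in designs.items():
            try:
                results[trait].append(score_site(counts, design, classify, alpha))
            except (ZeroCoverageError, ValueError):
                continue
    return results, summary


def results_to_frame(results: Sequence[ImbalanceResult]) -> pd.DataFrame:
    """Tidy per-trait result table with a BH q-value column appended."""
    rows = []
    for r in results:
        g = r.frequencies
        rows.append(
            {
                "site": str(r.snp),
                "chrom": r.snp.chrom,
                "pos": r.snp.pos,
                "ref": r.snp.ref,
                "alt": r.snp.alt,
                "trait": r.trait,
                "count_a_high": g.count_a_high,
                "count_b_high": g.count_b_high,
                "count_a_low": g.count_a_low,
                "count_b_low": g.count_b_low,
                "fa_high": g.fa_high,
                "fa_low": g.fa_low,
                "score": math.nan if r.score is None else r.score,
                "class": r.imbalance_class.value,
                "chi2": r.chi2,
                "p_value": r.p_value,
                "significant": r.significant,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q_bh"] = benjamini_hochberg(df["p_value"].to_numpy())
    return df


def tally_results(
    results_by_trait: Mapping[str, Sequence[ImbalanceResult]]
) -> dict:
    """Summary tally in the style of a per-trait imbalance count table:
    putative sites, ratio-class (0.5/2.0) calls and exclusive (0.0/1.0)
    calls per trait, plus the non-redundant merged counts."""
    per_trait = {}
    for trait, results in results_by_trait.items():
        ratio = sum(
            r.imbalance_class.value in ("amplification", "loss_of_heterozygosity")
            for r in results
        )
        exclusive = sum(
            r.imbalance_class.value in ("exclusive_high", "exclusive_low")
            for r in results
        )
        per_trait[trait] = {
            "putative": len(results),
            "ratio_class": ratio,
            "exclusive_class": exclusive,
            "significant": sum(r.significant for r in results),
        }
    merged = merge_traits(results_by_trait)
    return {
        "per_trait": per_trait,
        "nonredundant_imbalanced": len(merged.membership),
        "sharing_histogram": merged.sharing_histogram,
        "multiallelic_positions": len(merged.multiallelic_positions),
    }


def planted_recovery(
    study: "simgen.SimulatedStudy",
    results_by_trait: Mapping[str, Sequence[ImbalanceResult]],
) -> dict:
    """Measure detection of planted imbalances against the truth table.

    A site/trait call counts as detected when the ratio (or exclusive)
    criterion fires and the chi-square gate agrees: ratio-class calls
    must be significant at p < 0.05; exclusive calls have an undefined
    chi-square (a zero marginal) and stand on the ratio criterion alone.

    * sensitivity: fraction of sites planted imbalanced (odds-ratio
      class, any trait) detected in at least one of their planted traits.
    * false_positive_rate: fraction of (site, trait) tests at globally
      null sites (null for every trait, so free of cross-trait family
      overlap effects) that are falsely called.
    * exclusive_recovery: same as sensitivity, for planted exclusive sites.
    """
    truth = study.pools.truth
    traits = list(study.config.traits)
    cls_cols = [f"class_{t}" for t in traits]
    imb = {simgen.IMB_HIGH, simgen.IMB_LOW}
    exc = {simgen.EXC_HIGH, simgen.EXC_LOW}
    site_of = dict(zip(truth["site"], truth.index))

    def fires(r: ImbalanceResult) -> bool:
        if not r.imbalance_class.is_imbalanced:
            return False
        return r.significant if r.chi2_defined else True

    detected: dict[str, set[str]] = {}
    for trait, results in results_by_trait.items():
        for r in results:
            if fires(r):
                detected.setdefault(str(r.snp), set()).add(trait)

    def recovered(classes: set[str]) -> tuple[int, int]:
        hit = n = 0
        for _, row in truth.iterrows():
            planted = [t for t in traits if row[f"class_{t}"] in classes]
            if not planted:
                continue
            n += 1
            if set(planted) & detected.get(row["site"], set()):
                hit += 1
        return hit, n

    hit_imb, n_imb = recovered(imb)
    hit_exc, n_exc = recovered(exc)
    null_sites = set(truth.loc[(truth[cls_cols] == simgen.NULL).all(axis=1), "site"])
    fp = n_tests = 0
    for trait, results in results_by_trait.items():
        for r in results:
            if str(r.snp) in null_sites:
                n_tests += 1
                if fires(r):
                    fp += 1
    return {
        "n_planted_imbalanced": n_imb,
        "sensitivity": hit_imb / n_imb if n_imb else math.nan,
        "n_planted_exclusive": n_exc,
        "exclusive_recovery": hit_exc / n_exc if n_exc else math.nan,
        "n_null_tests": n_tests,
        "false_positive_rate": fp / n_tests if n_tests else math.nan,
    }


# ---------------------------------------------------------------------------
# run-all


@dataclass
class RunConfig:
    """One config for the whole simulate-to-validate run."""

    outdir: str = "poolai_run"
    seed: int = 0
    sim: simgen.SimConfig = field(default_factory=simgen.SimConfig)
    hard: HardFilterThresholds = field(default_factory=HardFilterThresholds)
    pool: PoolFilterThresholds = field(default_factory=PoolFilterThresholds)
    classify: ClassifyThresholds = field(default_factory=ClassifyThresholds)
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        seed = raw.get("seed", 0)
        sim_raw.setdefault("seed", seed)
        return cls(
            outdir=raw.get("outdir", "poolai_run"),
            seed=seed,
            sim=simgen.SimConfig(**sim_raw),
            hard=HardFilterThresholds(**raw.get("hard_filters", {})),
            pool=PoolFilterThresholds(**raw.get("pool_filters", {})),
            classify=ClassifyThresholds(**raw.get("classify", {})),
            alpha=raw.get("alpha", 0.05),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Simulate a study and run every analysis stage over it.

    Writes all stage outputs under ``config.outdir`` and a manifest with
    a sha256 per output, so a rerun with the same config is verifiably
    byte-identical.  Returns the manifest dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.sim, seed=config.seed)
    study = simgen.simulate_study(sim)
    study.write(outdir / "sim")

    results, summary = run_ai_analysis(
        study.pools.to_pooled_counts(),
        study.designs,
        config.hard,
        config.pool,
        config.classify,
        config.alpha,
    )
    score_dir = outdir / "score"
    score_dir.mkdir(exist_ok=True)
    for trait, rr in results.items():
        results_to_frame(rr).to_csv(score_dir / f"{trait}.tsv", sep="\t", index=False)
    tally = tally_results(results)
    (score_dir / "tally.json").write_text(json.dumps(tally, indent=2) + "\n")

    merged = merge_traits(results)
    index = ann.GenomeAnnotationIndex(
        study.reference.transcripts,
        study.reference.lncrnas,
        study.reference.chrom_lengths,
    )
    annotations = ann.annotate_snps(sorted(merged.snps), index, study.reference.genome)
    ann_dir = outdir / "annotate"
    ann_dir.mkdir(exist_ok=True)
    ann.summarize_classes(annotations).to_csv(
        ann_dir / "class_summary.tsv", sep="\t", index=False
    )

    density = genomedist.chromosome_density(
        merged.snps, study.reference.chrom_lengths
    )
    density.to_csv(outdir / "density.tsv", sep="\t", index=False)

    conc = genotype_concordance(study.panel.dna, study.panel.cdna)
    validation = {
        "concordance_rate": conc.concordance_rate,
        "monoallelic_rate_het_dna": conc.monoallelic_rate("het_dna"),
        "n_events": len(conc.events),
    }
    (outdir / "validation.json").write_text(json.dumps(validation, indent=2) + "\n")

    manifest = {
        "config": {
            "seed": config.seed,
            "alpha": config.alpha,
            "sim": dataclasses.asdict(sim),
            "hard_filters": dataclasses.asdict(config.hard),
            "pool_filters": dataclasses.asdict(config.pool),
        },
        "filter_summary": dataclasses.asdict(summary),
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
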