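"""End-to-end pipeline driver and the published-map summary harness."""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import hetstats, io as hio, landscape, mapbuild, qc, simulate
from .core import GenomeSpec


@dataclass
class PipelineConfig:
    """All tunables of the simulate -> qc -> map -> landscape -> stats run."""

    seed: int = 0
    # genome / panel / genes
    markers_per_chrom: int = 1000
    gene_density_macro: float = 8.0
    micro_density_factor: float = 2.5
    unnamed_fraction: float = 0.2
    # crossover model
    male_ratio: float = 1.157
    female_end_weight: float = 0.0
    male_end_weight: float = 0.7
    end_shape: float = 0.5
    obligate: bool = False
    # pedigree
    n_families: int = 36
    offspring_per_family: int = 2
    fraction_with_grandparents: float = 0.25
    genotyping_error_rate: float = 0.002
    missing_rate: float = 0.02
    # qc
    mind: float = 0.10
    geno: float = 0.10
    maf: float = 0.05
    hwe_p: float = 0.05
    mendel_per_trio: float = 1.0
    mendel_per_variant: float = 0.10
    # mapping
    n_min: int = 5
    min_snps: int = 70
    r_cap: float = 0.49
    # landscape
    interval_width: int = 1_000_000
    span_snps: int = 50
    # outlier fences
    fence: float = 1.5
    extreme_fence: float = 3.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """One seeded RNG stream per stage, derived from the master seed by
    stage name, so stages rerun independently and reproducibly."""
    return np.random.default_rng([master_seed, zlib.crc32(stage.encode())])


@dataclass
class RunManifest:
    config: dict
    seed: int
    versions: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)

    def record_file(self, path) -> None:
        path = Path(path)
        self.checksums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def run_pipeline(
    config: PipelineConfig | None = None,
    out_dir=None,
    genome: GenomeSpec | None = None,
) -> dict:
    """simulate -> qc -> map -> landscape -> stats, returning all artifacts."""
    cfg = config or PipelineConfig()
    if genome is None:
        genome = simulate.default_genome()

    genome, panel, genes = simulate.simulate_genome(
        genome,
        markers_per_chrom=cfg.markers_per_chrom,
        gene_density_macro=cfg.gene_density_macro,
        micro_density_factor=cfg.micro_density_factor,
        unnamed_fraction=cfg.unnamed_fraction,
        rng=stage_rng(cfg.seed, "genome"),
    )
    model = simulate.default_crossover_model(
        genome,
        male_ratio=cfg.male_ratio,
        female_end_weight=cfg.female_end_weight,
        male_end_weight=cfg.male_end_weight,
        end_shape=cfg.end_shape,
        obligate=cfg.obligate,
    )
    pedspec = simulate.PedigreeSpec(
        n_families=cfg.n_families,
        offspring_per_family=cfg.offspring_per_family,
        fraction_with_grandparents=cfg.fraction_with_grandparents,
        genotyping_error_rate=cfg.genotyping_error_rate,
        missing_rate=cfg.missing_rate,
    )
    gd, truth = simulate.simulate_pedigree_genotypes(
        genome, panel, model, pedspec, rng=stage_rng(cfg.seed, "pedigree")
    )

    qcfg = qc.QCConfig(
        mind=cfg.mind,
        geno=cfg.geno,
        maf=cfg.maf,
        hwe_p=cfg.hwe_p,
        mendel_per_trio=cfg.mendel_per_trio,
        mendel_per_variant=cfg.mendel_per_variant,
    )
    gd_qc, qc_report = qc.run_qc(gd, qcfg)

    sexmap = mapbuild.build_sex_map(
        gd_qc, n_min=cfg.n_min, min_snps=cfg.min_snps, r_cap=cfg.r_cap
    )
    per_chrom, totals = landscape.chromosome_summary(sexmap, genome)
    intervals = landscape.build_interval_table(
        sexmap, genome, genes, width=cfg.interval_width
    )
    marey = landscape.marey_curve(sexmap, span_snps=cfg.span_snps)
    stats_report = hetstats.association_suite(
        intervals, fence=cfg.fence, extreme_fence=cfg.extreme_fence
    )

    results = {
        "config": cfg,
        "genome": genome,
        "panel": panel,
        "genes": genes,
        "genotypes": gd,
        "truth": truth,
        "qc_genotypes": gd_qc,
        "qc_report": qc_report,
        "sexmap": sexmap,
        "chrom_summary": per_chrom,
        "totals": totals,
        "intervals": intervals,
        "marey": marey,
        "stats": stats_report,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = RunManifest(config=asdict(cfg), seed=cfg.seed)
        simulate.write_dataset(out_dir, gd, genome, genes, truth, asdict(cfg))
        hio.write_ped_map(gd_qc, out_dir / "genotypes_qc")
        qc_report.to_frame().to_csv(out_dir / "qc_report.tsv", sep="\t", index=False)
        hio.write_sexmap_tsv(sexmap, out_dir / "sexmap.tsv")
        per_chrom.to_csv(out_dir / "chrom_summary.tsv", sep="\t", index=False)
        hio.write_intervals_tsv(intervals, out_dir / "intervals.tsv")
        hio.write_intervals_bed(intervals, out_dir / "intervals.bed")
        marey.to_csv(out_dir / "marey.tsv", sep="\t", index=False)
        stats_report["spearman"].to_csv(
            out_dir / "spearman.tsv", sep="\t", index=False
        )
        for name in ("outliers", "extreme"):
            calls = stats_report[name]["calls"]
            calls.to_csv(out_dir / f"{name}_intervals.tsv", sep="\t", index=False)
        for f in sorted(out_dir.iterdir()):
            if f.is_file() and f.name != "manifest.json":
                manifest.record_file(f)
        manifest.write(out_dir / "manifest.json")
        results["manifest"] = manifest
    return results


# --------------------------------------------------------------------------
# published-map summary arithmetic


def load_published_map_summary() -> pd.DataFrame:
    """The bundled per-chromosome map summary of the hihi study
    (physical size, SNP count and sex-specific map lengths), used as an
    input to re-derive all published summary statistics."""
    ref = importlib.resources.files("hetmap.data") / "hihi_map_summary.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def summarize_published_maps(df: pd.DataFrame | None = None) -> tuple[pd.DataFrame, dict]:
    """Recompute every derived column and total from per-chromosome
    lengths: rates (cM/Mb), heterochiasmy index (F - M)/A, autosomal
    totals, the mean autosomal rates, genome-wide index, percent male
    map excess and the count of female-longer chromosomes.

    The input needs columns chrom, size_mb, cm_female, cm_male, cm_avg;
    a sex chromosome row may carry a single map length (its rate is
    computed from whichever length is present).
    """
    if df is None:
        df = load_published_map_summary()
    if (df["size_mb"] <= 0).any():
        raise ValueError("chromosome sizes must be > 0")
    out = df.copy()
    is_auto = ~out["chrom"].str.upper().isin(["Z", "W"])
    out["is_autosome"] = is_auto
    for src, dst in (
        ("cm_avg", "rate_avg"),
        ("cm_female", "rate_female"),
        ("cm_male", "rate_male"),
    ):
        out[dst] = out[src] / out["size_mb"]
    out["hi"] = np.where(
        out["cm_avg"] > 0,
        (out["cm_female"] - out["cm_male"]) / out["cm_avg"],
        np.nan,
    )
    # a sex-chromosome row's rate comes from its single available length
    single = out["cm_avg"].isna() & out["cm_male"].notna()
    out.loc[single, "rate_avg"] = out.loc[single, "cm_male"] / out.loc[single, "size_mb"]

    auto = out[is_auto]
    tot_f = float(auto["cm_female"].sum())
    tot_m = float(auto["cm_male"].sum())
    tot_a = float(auto["cm_avg"].sum())
    tot_size = float(auto["size_mb"].sum())
    totals = {
        "total_cM_female": tot_f,
        "total_cM_male": tot_m,
        "total_cM_avg": tot_a,
        "total_size_mb": tot_size,
        "total_n_snps": int(auto["n_snps"].sum()) if "n_snps" in auto else None,
        "mean_rate_avg": tot_a / tot_size,
        "mean_rate_female": tot_f / tot_size,
        "mean_rate_male": tot_m / tot_size,
        "genome_hi": (tot_f - tot_m) / tot_a,
        "pct_male_excess": 100.0 * (tot_m - tot_f) / tot_f,
        "n_female_longer": int((auto["cm_female"] > auto["cm_male"]).sum()),
    }
    return out, totals
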