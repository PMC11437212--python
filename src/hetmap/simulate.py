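"""Synthetic genomes, pedigrees and genotypes under sex-specific crossover models.

The generator emulates a full-sib-family SNP-array study design in a
passerine-like karyotype: a few large macro-chromosomes plus many small,
gene-dense micro-chromosomes and a Z; dense biallelic markers on a known
physical order; crossovers drawn per gamete from a sex-specific Poisson
process whose positional density can be concentrated near chromosome
ends (male-like) or uniform (female-like).  Ground truth — expected
genetic positions and realized switch points — is retained so estimators
can be scored against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import (
    MISSING,
    Chromosome,
    GeneAnnotation,
    GenomeSpec,
    GenotypeData,
    MarkerPanel,
)

# Chromosome sizes (Mb) of a hihi-like passerine karyotype: 28 scaffolded
# autosomes plus Z.  Macro = 1-7 and 1A.
HIHI_LIKE_SIZES_MB = {
    "1": 99.26, "1A": 68.01, "2": 143.74, "3": 111.67, "4": 70.22,
    "4A": 20.10, "5": 61.39, "6": 34.87, "7": 38.89, "8": 26.64,
    "9": 25.15, "10": 20.90, "11": 21.17, "12": 21.11, "13": 18.28,
    "14": 16.57, "15": 14.26, "17": 10.98, "18": 11.36, "19": 11.02,
    "20": 15.23, "21": 7.69, "22": 4.68, "23": 6.87, "24": 6.77,
    "26": 6.07, "27": 5.64, "28": 5.29, "Z": 73.43,
}


def default_genome() -> GenomeSpec:
    """Hihi-like karyotype: 28 autosomes + Z, macro = chromosomes 1-7 & 1A."""
    return GenomeSpec.from_lengths(
        {name: int(round(mb * 1e6)) for name, mb in HIHI_LIKE_SIZES_MB.items()}
    )


@dataclass(frozen=True)
class ChromosomeCrossover:
    """Crossover process for one chromosome in one sex.

    lambda_morgans : expected switch points per gamete (the chromosome's
        genetic length in Morgans).
    end_weight : mixture weight on the U-shaped positional component;
        0 gives a uniform crossover landscape, 1 a fully telomere-
        concentrated one.
    end_shape : shape of the symmetric Beta(b, b) end component; b < 1
        is U-shaped.
    obligate : if True, draw from a zero-truncated Poisson whose rate is
        solved numerically so the expected count still equals
        lambda_morgans (requires lambda_morgans > 1).
    """

    lambda_morgans: float
    end_weight: float = 0.0
    end_shape: float = 0.5
    obligate: bool = False

    def __post_init__(self) -> None:
        if self.lambda_morgans < 0:
            raise ValueError("lambda_morgans must be >= 0")
        if not 0.0 <= self.end_weight <= 1.0:
            raise ValueError("end_weight must be in [0, 1]")
        if self.end_shape <= 0:
            raise ValueError("end_shape must be > 0")

    def truncated_rate(self) -> float:
        """Rate mu of the zero-truncated Poisson with mean lambda_morgans."""
        lam = self.lambda_morgans
        if lam <= 1.0:
            raise ValueError("obligate crossover requires lambda_morgans > 1")
        return optimize.brentq(
            lambda mu: mu / (1.0 - math.exp(-mu)) - lam, 1e-9, max(4 * lam, 10.0)
        )

    def position_cdf(self, frac: np.ndarray) -> np.ndarray:
        """CDF of the crossover position density on [0, 1] of chromosome span."""
        frac = np.asarray(frac, dtype=float)
        beta_part = stats.beta.cdf(frac, self.end_shape, self.end_shape)
        return self.end_weight * beta_part + (1.0 - self.end_weight) * frac

    def expected_cm(self, pos_bp: np.ndarray, length_bp: int) -> np.ndarray:
        """Expected cumulative genetic position (cM) at physical positions."""
        return 100.0 * self.lambda_morgans * self.position_cdf(
            np.asarray(pos_bp, dtype=float) / length_bp
        )


class CrossoverModel:
    """Per-sex, per-chromosome crossover processes."""

    def __init__(self, per_sex: dict[str, dict[str, ChromosomeCrossover]]):
        if set(per_sex) != {"F", "M"}:
            raise ValueError("model must define sexes 'F' and 'M'")
        self.per_sex = per_sex

    def __getitem__(self, key: tuple[str, str]) -> ChromosomeCrossover:
        sex, chrom = key
        return self.per_sex[sex][chrom]

    def chromosomes(self) -> list[str]:
        return list(self.per_sex["F"])

    def total_cm(self, sex: str, autosomes_of: GenomeSpec | None = None) -> float:
        items = self.per_sex[sex].items()
        if autosomes_of is not None:
            items = [(c, m) for c, m in items if autosomes_of.is_autosome(c)]
        return sum(100.0 * m.lambda_morgans for _, m in items)


def default_crossover_model(
    genome: GenomeSpec,
    female_cm: dict[str, float] | None = None,
    male_ratio: float = 1.157,
    female_end_weight: float = 0.0,
    male_end_weight: float = 0.7,
    end_shape: float = 0.5,
    obligate: bool = False,
) -> CrossoverModel:
    """Sex-specific model defaults mirroring the study system.

    Female genetic lengths default to an avian-like size scaling,
    45 + 0.55 * size_Mb cM per autosome; male lengths are
    ``male_ratio`` times the female ones (default 15.7% longer) with
    crossovers concentrated near chromosome ends.  On Z only males
    recombine (females are the heterogametic ZW sex).
    """
    female, male = {}, {}
    for c in genome:
        if female_cm is not None:
            f_cm = female_cm[c.name]
        elif genome.is_autosome(c.name):
            f_cm = 45.0 + 0.55 * c.length_mb
        else:
            f_cm = 0.0
        if genome.is_autosome(c.name):
            m_cm = male_ratio * f_cm
        else:
            # Z recombines in ZZ males only; give it the autosome-like scaling
            m_cm = 45.0 + 0.55 * c.length_mb
        female[c.name] = ChromosomeCrossover(
            f_cm / 100.0, female_end_weight, end_shape, obligate and f_cm > 100
        )
        male[c.name] = ChromosomeCrossover(
            m_cm / 100.0, male_end_weight, end_shape, obligate and m_cm > 100
        )
    return CrossoverModel({"F": female, "M": male})


@dataclass
class PedigreeSpec:
    """Full-sib family study design.

    Defaults follow the study scale: 36 two-offspring full-sib families
    (144 genotyped individuals), a quarter with genotyped grandparents,
    SNP-array-like error and missingness.
    """

    n_families: int = 36
    offspring_per_family: int | tuple[int, int] = 2
    fraction_with_grandparents: float = 0.25
    genotyping_error_rate: float = 0.002
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        rng_lo = (
            self.offspring_per_family
            if isinstance(self.offspring_per_family, int)
            else self.offspring_per_family[0]
        )
        if rng_lo < 1:
            raise ValueError("offspring_per_family must be >= 1")
        if not 0 <= self.fraction_with_grandparents <= 1:
            raise ValueError("fraction_with_grandparents must be in [0, 1]")
        if not 0 <= self.genotyping_error_rate < 1:
            raise ValueError("genotyping_error_rate must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class TruthTable:
    """Generative ground truth retained for estimator recovery tests.

    map_cm : per-marker expected cumulative genetic position per sex.
    lengths_cm : per chromosome and sex, the true genetic length
        (exactly 100 * lambda_morgans).
    switches : realized crossover positions per transmitted gamete.
    """

    map_cm: pd.DataFrame
    lengths_cm: pd.DataFrame
    switches: pd.DataFrame

    def length(self, sex: str, chrom: str) -> float:
        sub = self.lengths_cm
        row = sub[(sub["sex"] == sex) & (sub["chrom"] == chrom)]
        return float(row["cM"].iloc[0])


# ---------------------------------------------------------------------------
# genome / panel / gene simulation


def simulate_genome(
    genome: GenomeSpec | None = None,
    markers_per_chrom: int | dict[str, int] = 1000,
    gene_density_macro: float = 8.0,
    micro_density_factor: float = 2.5,
    unnamed_fraction: float = 0.2,
    maf_range: tuple[float, float] = (0.1, 0.5),
    mean_gene_length_bp: float = 15_000.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenomeSpec, MarkerPanel, GeneAnnotation]:
    """Draw a marker panel and gene annotation on a genome.

    Marker positions are uniform (then sorted and deduplicated); gene
    density is ``micro_density_factor`` times higher on
    micro-chromosomes; a fraction of genes carries no recognised name.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if genome is None:
        genome = default_genome()
    if not genome.chromosomes:
        raise ValueError("genome must contain at least one chromosome")
    if gene_density_macro < 0 or micro_density_factor <= 0:
        raise ValueError("gene densities must be positive")

    marker_rows = []
    for c in genome:
        n = (
            markers_per_chrom[c.name]
            if isinstance(markers_per_chrom, dict)
            else markers_per_chrom
        )
        if n < 0:
            raise ValueError("marker count must be >= 0")
        if n > c.length_bp:
            raise ValueError(f"more markers than bases on {c.name}")
        pos = np.unique(rng.integers(1, c.length_bp + 1, size=n))
        while len(pos) < n:  # top up rare collisions
            extra = rng.integers(1, c.length_bp + 1, size=n - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        freqs = rng.uniform(*maf_range, size=n)
        for j, (p, f) in enumerate(zip(pos, freqs)):
            marker_rows.append((f"snp_{c.name}_{j:05d}", c.name, int(p), float(f)))
    panel = MarkerPanel(
        pd.DataFrame(marker_rows, columns=MarkerPanel.COLUMNS), genome
    )

    gene_rows = []
    for c in genome:
        density = gene_density_macro * (1.0 if c.is_macro else micro_density_factor)
        n_genes = rng.poisson(density * c.length_mb)
        if n_genes == 0:
            continue
        lengths = np.minimum(
            rng.lognormal(math.log(mean_gene_length_bp), 0.8, size=n_genes),
            c.length_bp / 4,
        ).astype(int)
        lengths = np.maximum(lengths, 200)
        starts = rng.integers(0, np.maximum(c.length_bp - lengths, 1))
        named = rng.random(n_genes) >= unnamed_fraction
        for j in range(n_genes):
            gene_rows.append(
                (
                    f"gene_{c.name}_{j:05d}",
                    c.name,
                    int(starts[j]),
                    int(starts[j] + lengths[j]),
                    bool(named[j]),
                )
            )
    genes = GeneAnnotation(
        pd.DataFrame(gene_rows, columns=GeneAnnotation.COLUMNS), genome
    )
    return genome, panel, genes


# ---------------------------------------------------------------------------
# gamete simulation


def draw_switch_positions(
    model: ChromosomeCrossover, length_bp: int, rng: np.random.Generator
) -> np.ndarray:
    """Realized crossover (switch point) positions in bp for one gamete."""
    if model.obligate:
        mu = model.truncated_rate()
        k = 0
        while k == 0:
            k = rng.poisson(mu)
    else:
        k = rng.poisson(model.lambda_morgans)
    if k == 0:
        return np.empty(0)
    is_end = rng.random(k) < model.end_weight
    frac = np.where(
        is_end,
        rng.beta(model.end_shape, model.end_shape, size=k),
        rng.random(k),
    )
    return np.sort(frac * length_bp)


def simulate_gamete(
    parent_haplotypes: np.ndarray,
    model: ChromosomeCrossover,
    positions_bp: np.ndarray,
    length_bp: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete from a pair of parental haplotypes on one chromosome.

    Returns the gamete allele vector and the realized switch positions
    (bp).  The starting haplotype is chosen with probability 1/2 and the
    copy alternates between parental haplotypes at each switch point.
    """
    haps = np.asarray(parent_haplotypes)
    positions_bp = np.asarray(positions_bp)
    if haps.shape != (2, len(positions_bp)):
        raise ValueError("parent haplotypes must be a 2 x n_markers array")
    switches = draw_switch_positions(model, length_bp, rng)
    origin = gamete_origins_at(positions_bp, switches, int(rng.integers(2)))
    return haps[origin, np.arange(len(positions_bp))], switches


def gamete_origins_at(
    positions_bp: np.ndarray, switches_bp: np.ndarray, start: int
) -> np.ndarray:
    """Haplotype-of-origin (0/1) at each marker given switch points."""
    counts = np.searchsorted(switches_bp, positions_bp, side="left")
    return (start + counts) % 2


def simulate_gamete_origins(
    n_gametes: int,
    model: ChromosomeCrossover,
    positions_bp: np.ndarray,
    length_bp: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Haplotype-of-origin matrix (n_gametes x n_markers) for bulk draws.

    Useful for estimator checks where the parent is treated as phased
    and heterozygous at every marker.
    """
    positions_bp = np.asarray(positions_bp)
    out = np.empty((n_gametes, len(positions_bp)), dtype=np.int8)
    for i in range(n_gametes):
        switches = draw_switch_positions(model, length_bp, rng)
        out[i] = gamete_origins_at(positions_bp, switches, int(rng.integers(2)))
    return out


# ---------------------------------------------------------------------------
# pedigree genotype simulation


def _chrom_blocks(panel: MarkerPanel, genome: GenomeSpec):
    blocks = []
    for c in genome:
        idx = panel.chrom_index(c.name)
        if len(idx):
            blocks.append((c.name, idx, panel.df["pos_bp"].to_numpy()[idx], c.length_bp))
    return blocks


def _founder_haplotypes(freqs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return (rng.random((2, len(freqs))) < freqs).astype(np.int8)


def simulate_pedigree_genotypes(
    genome: GenomeSpec,
    panel: MarkerPanel,
    model: CrossoverModel,
    pedspec: PedigreeSpec,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeData, TruthTable]:
    """Genotype full-sib families under the sex-specific crossover model.

    Founders are drawn in Hardy-Weinberg proportions from the panel
    allele frequencies.  Each offspring receives one maternal gamete
    (female model) and one paternal gamete (male model).  For the
    configured fraction of families all four grandparents are genotyped
    and the parents are themselves simulated as their offspring, so the
    parents' phase is recoverable downstream.  Genotyping errors flip a
    single allele; missingness is applied independently.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    freqs = panel.df["allele_freq"].to_numpy()
    blocks = _chrom_blocks(panel, genome)
    M = len(panel)

    haplos: dict[str, np.ndarray] = {}
    rows = []  # fid iid father mother sex
    switch_rows = []

    def make_child(fid, iid, sex, sire, dam, record_switches=True):
        child = np.empty((2, M), dtype=np.int8)
        for parent, hap_row, psex in ((sire, 0, "M"), (dam, 1, "F")):
            for chrom, idx, pos, L in blocks:
                cmodel = model[psex, chrom]
                gam, sw = simulate_gamete(
                    haplos[parent][:, idx], cmodel, pos, L, rng
                )
                child[hap_row, idx] = gam
                if record_switches:
                    for s in sw:
                        switch_rows.append((parent, iid, psex, chrom, float(s)))
        haplos[iid] = child
        rows.append((fid, iid, sire, dam, sex))

    n_gp = int(round(pedspec.fraction_with_grandparents * pedspec.n_families))
    gp_families = set(rng.choice(pedspec.n_families, size=n_gp, replace=False))

    for f in range(pedspec.n_families):
        fid = f"F{f + 1:03d}"
        sire, dam = f"{fid}_sire", f"{fid}_dam"
        if f in gp_families:
            for gp_pair, parent, parent_sex in (
                (("pgf", "pgm"), sire, "M"),
                (("mgf", "mgm"), dam, "F"),
            ):
                gf, gm = (f"{fid}_{g}" for g in gp_pair)
                haplos[gf] = _founder_haplotypes(freqs, rng)
                haplos[gm] = _founder_haplotypes(freqs, rng)
                rows.append((fid, gf, "0", "0", "M"))
                rows.append((fid, gm, "0", "0", "F"))
                make_child(fid, parent, parent_sex, gf, gm, record_switches=False)
        else:
            haplos[sire] = _founder_haplotypes(freqs, rng)
            haplos[dam] = _founder_haplotypes(freqs, rng)
            rows.append((fid, sire, "0", "0", "M"))
            rows.append((fid, dam, "0", "0", "F"))
        if isinstance(pedspec.offspring_per_family, int):
            n_off = pedspec.offspring_per_family
        else:
            lo, hi = pedspec.offspring_per_family
            n_off = int(rng.integers(lo, hi + 1))
        for o in range(n_off):
            make_child(
                fid,
                f"{fid}_o{o + 1:02d}",
                "M" if rng.random() < 0.5 else "F",
                sire,
                dam,
            )

    samples = pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex"])
    genotypes = np.empty((len(samples), M), dtype=np.int8)
    for i, iid in enumerate(samples["iid"]):
        genotypes[i] = haplos[iid].sum(axis=0)

    # single-allele genotyping errors, then missingness
    if pedspec.genotyping_error_rate > 0:
        err = rng.random(genotypes.shape) < pedspec.genotyping_error_rate
        up = rng.random(genotypes.shape) < 0.5
        g = genotypes
        new = np.where(g == 0, 1, np.where(g == 2, 1, np.where(up, 2, 0)))
        genotypes = np.where(err, new, g).astype(np.int8)
    if pedspec.missing_rate > 0:
        miss = rng.random(genotypes.shape) < pedspec.missing_rate
        genotypes = np.where(miss, MISSING, genotypes).astype(np.int8)

    # ground truth
    map_rows = []
    length_rows = []
    for chrom, idx, pos, L in blocks:
        fcm = model["F", chrom].expected_cm(pos, L)
        mcm = model["M", chrom].expected_cm(pos, L)
        sub = panel.df.iloc[idx]
        for mid, p, fc, mc in zip(sub["id"], pos, fcm, mcm):
            map_rows.append((chrom, mid, int(p), float(fc), float(mc)))
        for sex in ("F", "M"):
            length_rows.append(
                (chrom, sex, 100.0 * model[sex, chrom].lambda_morgans)
            )
    truth = TruthTable(
        map_cm=pd.DataFrame(
            map_rows, columns=["chrom", "marker", "pos_bp", "cM_female", "cM_male"]
        ),
        lengths_cm=pd.DataFrame(length_rows, columns=["chrom", "sex", "cM"]),
        switches=pd.DataFrame(
            switch_rows, columns=["parent", "offspring", "sex", "chrom", "pos_bp"]
        ),
    )
    gd = GenotypeData(genotypes, samples, panel.df[["id", "chrom", "pos_bp"]].copy())
    return gd, truth


def write_dataset(
    directory,
    gd: GenotypeData,
    genome: GenomeSpec,
    genes: GeneAnnotation,
    truth: TruthTable | None = None,
    config: dict | None = None,
) -> None:
    """Write a simulated dataset as plain-text files (PED/MAP, TSV, BED)."""
    from . import io as hio
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    hio.write_ped_map(gd, directory / "genotypes")
    hio.write_pedigree_tsv(gd.samples, directory / "pedigree.tsv")
    hio.write_genes_bed(genes, directory / "genes.bed")
    hio.write_genome_tsv(genome, directory / "genome.tsv")
    if truth is not None:
        truth.map_cm.to_csv(directory / "truth_map.tsv", sep="\t", index=False)
        truth.lengths_cm.to_csv(directory / "truth_lengths.tsv", sep="\t", index=False)
        truth.switches.to_csv(directory / "truth_switches.tsv", sep="\t", index=False)
    if config is not None:
        import yaml

        with open(directory / "config.yaml", "w") as fh:
            yaml.safe_dump(config, fh, sort_keys=False)
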