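"""PLINK-style genotype quality control for pedigreed SNP data.

Filter chain (fixed order): sample/marker missingness -> founder MAF ->
Hardy-Weinberg exact test and Mendelian-error filtering on autosomes
only (Z-linked markers bypass both, since they would be wrongly flagged
under an autosomal model in a ZW system) -> merge Z back -> duplicate
position resolution.  Removal thresholds are strict inequalities,
matching PLINK: a marker is removed iff missingness > geno, iff
MAF < maf, iff HWE p < hwe_p, iff Mendel-error fraction > per_variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeData


@dataclass
class QCConfig:
    mind: float = 0.10
    geno: float = 0.10
    maf: float = 0.05
    hwe_p: float = 0.05
    mendel_per_trio: float = 1.0
    mendel_per_variant: float = 0.10
    sex_chroms: tuple[str, ...] = ("Z", "W")

    def __post_init__(self) -> None:
        for name in ("mind", "geno", "maf", "hwe_p", "mendel_per_trio", "mendel_per_variant"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class QCReport:
    """Per-filter removal counts, in application order."""

    steps: list[dict] = field(default_factory=list)
    notes: list[str] = field(
        default_factory=lambda: [
            "MAF and HWE computed on founders only (PLINK default)",
            "HWE exact conditional test, no mid-p correction",
            "removal thresholds are strict inequalities (PLINK behaviour)",
        ]
    )

    def add(self, step: str, samples_removed: int, markers_removed: int) -> None:
        self.steps.append(
            {
                "step": step,
                "samples_removed": int(samples_removed),
                "markers_removed": int(markers_removed),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def _marker_missingness(g: np.ndarray) -> np.ndarray:
    return (g == MISSING).mean(axis=0) if g.size else np.zeros(g.shape[1])


def filter_missingness(
    gd: GenotypeData, mind: float = 0.10, geno: float = 0.10
) -> tuple[GenotypeData, QCReport]:
    """Drop samples with missing fraction > mind, then markers > geno.

    Marker missingness is recomputed after sample removal.
    """
    if gd.n_samples == 0 or gd.n_markers == 0:
        raise ValueError("empty genotype matrix")
    report = QCReport()
    miss_s = (gd.genotypes == MISSING).mean(axis=1)
    keep_s = miss_s <= mind
    gd2 = gd.subset(sample_mask=keep_s)
    miss_m = _marker_missingness(gd2.genotypes)
    keep_m = miss_m <= geno
    out = gd2.subset(marker_mask=keep_m)
    report.add("missingness", (~keep_s).sum(), (~keep_m).sum())
    return out, report


def founder_maf(gd: GenotypeData) -> np.ndarray:
    """Minor allele frequency per marker, computed on founders only."""
    g = gd.genotypes[gd.is_founder(), :].astype(float)
    g[g == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        p = np.nanmean(g, axis=0) / 2.0
    p = np.nan_to_num(p, nan=0.0)
    return np.minimum(p, 1.0 - p)


def filter_maf(gd: GenotypeData, maf: float = 0.05) -> tuple[GenotypeData, int]:
    """Remove markers with founder MAF strictly below the threshold."""
    keep = founder_maf(gd) >= maf
    return gd.subset(marker_mask=keep), int((~keep).sum())


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities
    of all heterozygote counts (which share the parity of the rare
    allele count) no more probable than the observed one.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("zero genotypes")
    n_a = 2 * n_aa + n_ab
    n_rare = min(n_a, 2 * n - n_a)
    lg = math.lgamma

    def log_prob(h: int) -> float:
        hom_rare = (n_rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            lg(n + 1) - lg(hom_rare + 1) - lg(h + 1) - lg(hom_common + 1)
            + h * math.log(2)
            + lg(n_rare + 1) + lg(2 * n - n_rare + 1) - lg(2 * n + 1)
        )

    h_values = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    logs = np.array([log_prob(int(h)) for h in h_values])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(h_values, n_ab)]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def hwe_filter(gd: GenotypeData, hwe_p: float = 0.05) -> tuple[GenotypeData, int]:
    """Remove markers whose founder HWE exact-test p-value is < hwe_p."""
    founders = gd.genotypes[gd.is_founder(), :]
    keep = np.ones(gd.n_markers, dtype=bool)
    for j in range(gd.n_markers):
        col = founders[:, j]
        counts = (
            int((col == 0).sum()),
            int((col == 1).sum()),
            int((col == 2).sum()),
        )
        if sum(counts) == 0:
            continue
        keep[j] = hwe_exact_test(*counts) >= hwe_p
    return gd.subset(marker_mask=keep), int((~keep).sum())


# offspring dosage d is Mendelian-consistent with parents (f, m) iff
# d can be written as a+b with a transmittable by f and b by m
_TRANSMIT = {0: {0}, 1: {0, 1}, 2: {1}}
_CONSISTENT = np.zeros((3, 3, 3), dtype=bool)
for _f in range(3):
    for _m in range(3):
        for _a in _TRANSMIT[_f]:
            for _b in _TRANSMIT[_m]:
                _CONSISTENT[_f, _m, _a + _b] = True


def mendel_errors(gd: GenotypeData) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-variant Mendel error and trio-tested counts across all trios.

    Returns (n_errors, n_tested) arrays over markers plus the offspring
    ids of the trios scanned.  Only trios with both parents in the
    dataset are scanned; a marker enters a trio's test only when all
    three genotypes are non-missing.
    """
    idx = gd.sample_index()
    g = gd.genotypes
    n_err = np.zeros(gd.n_markers, dtype=np.int64)
    n_test = np.zeros(gd.n_markers, dtype=np.int64)
    trio_ids = []
    for _, row in gd.samples.iterrows():
        fa, mo = row["father"], row["mother"]
        if fa not in idx or mo not in idx:
            continue
        trio_ids.append(row["iid"])
        go = g[idx[row["iid"]]]
        gf = g[idx[fa]]
        gm = g[idx[mo]]
        complete = (go != MISSING) & (gf != MISSING) & (gm != MISSING)
        err = np.zeros(gd.n_markers, dtype=bool)
        c = complete
        err[c] = ~_CONSISTENT[gf[c], gm[c], go[c]]
        n_err += err
        n_test += complete
    return n_err, n_test, trio_ids


def mendel_filter(
    gd: GenotypeData,
    per_trio: float = 1.0,
    per_variant: float = 0.10,
) -> tuple[GenotypeData, QCReport]:
    """Remove variants whose trio Mendel-error fraction exceeds per_variant.

    With the default per_trio = 1.0 no sample is ever removed (a trio's
    error fraction cannot exceed 1).
    """
    report = QCReport()
    n_err, n_test, _ = mendel_errors(gd)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_test > 0, n_err / np.maximum(n_test, 1), 0.0)
    keep_m = frac <= per_variant

    keep_s = np.ones(gd.n_samples, dtype=bool)
    if per_trio < 1.0:
        idx = gd.sample_index()
        g = gd.genotypes
        for i, row in gd.samples.iterrows():
            fa, mo = row["father"], row["mother"]
            if fa not in idx or mo not in idx:
                continue
            go, gf, gm = g[i], g[idx[fa]], g[idx[mo]]
            c = (go != MISSING) & (gf != MISSING) & (gm != MISSING)
            if c.sum() == 0:
                continue
            rate = (~_CONSISTENT[gf[c], gm[c], go[c]]).mean()
            if rate > per_trio:
                keep_s[i] = False
    out = gd.subset(sample_mask=keep_s, marker_mask=keep_m)
    report.add("mendel", (~keep_s).sum(), (~keep_m).sum())
    return out, report


def dedupe_markers(gd: GenotypeData) -> tuple[GenotypeData, int]:
    """Resolve markers sharing (chrom, pos_bp).

    The copy with lower missingness is retained; on a tie the
    later-listed copy is retained.
    """
    miss = _marker_missingness(gd.genotypes)
    keep = np.ones(gd.n_markers, dtype=bool)
    grouped = gd.markers.groupby(["chrom", "pos_bp"], sort=False).indices
    for _, idx in grouped.items():
        if len(idx) < 2:
            continue
        m = miss[idx]
        # stable pick: lowest missingness, ties -> last listed
        best = idx[np.flatnonzero(m == m.min())[-1]]
        for j in idx:
            if j != best:
                keep[j] = False
    return gd.subset(marker_mask=keep), int((~keep).sum())


def exempt_sex_chromosome(
    gd: GenotypeData, sex_chroms: tuple[str, ...] = ("Z", "W")
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (autosomal, sex-linked) partitioning the markers."""
    is_sex = gd.markers["chrom"].str.upper().isin([c.upper() for c in sex_chroms])
    return (~is_sex).to_numpy(), is_sex.to_numpy()


def run_qc(gd: GenotypeData, config: QCConfig | None = None) -> tuple[GenotypeData, QCReport]:
    """Full filter chain; idempotent on its own output."""
    cfg = config or QCConfig()
    report = QCReport()

    gd, rep = filter_missingness(gd, cfg.mind, cfg.geno)
    report.steps += rep.steps

    gd, n = filter_maf(gd, cfg.maf)
    report.add("maf", 0, n)

    auto_mask, sex_mask = exempt_sex_chromosome(gd, cfg.sex_chroms)
    auto = gd.subset(marker_mask=auto_mask)
    sexg = gd.subset(marker_mask=sex_mask)

    auto, n = hwe_filter(auto, cfg.hwe_p)
    report.add("hwe (autosomes)", 0, n)

    auto, rep = mendel_filter(auto, cfg.mendel_per_trio, cfg.mendel_per_variant)
    for s in rep.steps:
        s["step"] = "mendel (autosomes)"
    report.steps += rep.steps

    merged_markers = pd.concat([auto.markers, sexg.markers], ignore_index=True)
    merged_geno = np.concatenate([auto.genotypes, sexg.genotypes], axis=1)
    # restore panel order (chrom blocks as in the input marker table)
    order = np.argsort(
        merged_markers["id"].map(
            {mid: i for i, mid in enumerate(gd.markers["id"])}
        ).to_numpy(),
        kind="stable",
    )
    merged = GenotypeData(
        merged_geno[:, order],
        auto.samples,
        merged_markers.iloc[order].reset_index(drop=True),
    )

    merged, n = dedupe_markers(merged)
    report.add("dedupe", 0, n)
    return merged, report
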