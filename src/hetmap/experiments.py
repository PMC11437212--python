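"""Simulation studies validating the estimators against retained truth.

These are the package's built-in recovery experiments: they generate
data under known sex-specific crossover models, run the full inference
path, and report how well the configured quantities are recovered.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import hetstats, landscape, mapbuild, simulate
from .core import GenomeSpec, SEXMAP_COLUMNS
from .mapbuild import MeiosisRecord

RECOVERY_GENOME_MB = {"1": 80.0, "2": 40.0, "3": 20.0, "4": 10.0}


def recovery_study(
    seed: int,
    n_replicates: int = 12,
    n_families: int = 36,
    offspring_per_family: int = 6,
    markers_per_chrom: int = 500,
    male_ratio: float = 1.157,
) -> dict:
    """Map-length recovery under the full-sib study design.

    Simulates replicate datasets on a four-chromosome toy genome with
    uniform crossover landscapes in both sexes (the configured total
    length is then identifiable within the marker span), estimates the
    sex-specific maps and compares replicate-averaged lengths and the
    male:female total-length ratio against the generative truth.
    """
    genome = GenomeSpec.from_lengths(
        {k: int(v * 1e6) for k, v in RECOVERY_GENOME_MB.items()},
        macro_names={"1", "2"},
    )
    genome, panel, _ = simulate.simulate_genome(
        genome, markers_per_chrom=markers_per_chrom,
        rng=np.random.default_rng([seed, 101]),
    )
    model = simulate.default_crossover_model(
        genome, male_ratio=male_ratio, female_end_weight=0.0, male_end_weight=0.0
    )
    pedspec = simulate.PedigreeSpec(
        n_families=n_families,
        offspring_per_family=offspring_per_family,
        fraction_with_grandparents=0.25,
        genotyping_error_rate=0.0,
        missing_rate=0.0,
    )
    est: dict[tuple[str, str], list[float]] = {}
    ratios = []
    truth = None
    for rep in range(n_replicates):
        gd, truth = simulate.simulate_pedigree_genotypes(
            genome, panel, model, pedspec, rng=np.random.default_rng([seed, rep])
        )
        sexmap = mapbuild.build_sex_map(gd)
        lengths = mapbuild.map_lengths(sexmap).set_index("chrom")
        for chrom in lengths.index:
            for sex, col in (("F", "cM_female"), ("M", "cM_male")):
                est.setdefault((chrom, sex), []).append(float(lengths.loc[chrom, col]))
        ratios.append(
            float(lengths["cM_male"].sum() / lengths["cM_female"].sum())
        )
    per_chrom = {
        key: {
            "estimated_cM": float(np.mean(v)),
            "true_cM": truth.length(key[1], key[0]),
            "rel_error": float(np.mean(v)) / truth.length(key[1], key[0]) - 1.0,
        }
        for key, v in est.items()
    }
    return {
        "configured_ratio": male_ratio,
        "recovered_ratio": float(np.mean(ratios)),
        "ratio_sd": float(np.std(ratios)),
        "per_chrom": per_chrom,
        "n_replicates": n_replicates,
        "n_meioses_per_sex": n_families * offspring_per_family,
    }


def haldane_consistency(seed: int, n_gametes: int = 20_000) -> dict:
    """Monte-Carlo recombinant fraction across a 1 Morgan interval.

    Under independent crossovers the closed form is (1 - e^-2) / 2.
    """
    rng = np.random.default_rng([seed, 303])
    L = 10_000_000
    pos = np.array([1, L])
    orig = simulate.simulate_gamete_origins(
        n_gametes, simulate.ChromosomeCrossover(1.0), pos, L, rng
    )
    p_hat = float((orig[:, 0] != orig[:, 1]).mean())
    p_true = (1 - math.exp(-2)) / 2
    return {
        "mc_recombinant_fraction": p_hat,
        "closed_form": p_true,
        "binomial_se": math.sqrt(p_true * (1 - p_true) / n_gametes),
        "n_gametes": n_gametes,
    }


def zoib_calibration(
    seed: int,
    n: int = 5000,
    n_replicates: int = 100,
    beta0: float = -1.0,
    beta1: float = 0.8,
    phi: float = 10.0,
    zoi: float = 0.3,
    coi: float = 0.4,
) -> dict:
    """Recovery and interval calibration of the zoib regression.

    One large fit reports the point estimate; replicate fits report the
    95%-interval coverage of the true coefficient, and permutation-null
    fits the coverage of zero.
    """
    rng = np.random.default_rng([seed, 404])
    y, x = hetstats.simulate_zoib(n, beta0, beta1, phi, zoi, coi, rng=rng)
    point = hetstats.zoib_fit(y, x, standardize=False, n_starts=3)

    covered = 0
    null_covered = 0
    for rep in range(n_replicates):
        rng_rep = np.random.default_rng([seed, 405, rep])
        y, x = hetstats.simulate_zoib(n, beta0, beta1, phi, zoi, coi, rng=rng_rep)
        fit = hetstats.zoib_fit(y, x, standardize=False, n_starts=2)
        lo, hi = fit.ci_beta1
        covered += lo <= beta1 <= hi
        fit0 = hetstats.zoib_fit(y, rng_rep.permutation(x), standardize=False, n_starts=2)
        lo0, hi0 = fit0.ci_beta1
        null_covered += lo0 <= 0.0 <= hi0
    return {
        "beta1_true": beta1,
        "beta1_hat": point.beta1,
        "coverage_true": covered / n_replicates,
        "coverage_null": null_covered / n_replicates,
        "n": n,
        "n_replicates": n_replicates,
    }


def directional_landscape_study(
    seed: int,
    n_gametes: int = 50_000,
    markers_per_chrom: int = 250,
    male_end_weight: float = 0.7,
) -> dict:
    """Male-telomeric crossover bias propagated to interval statistics.

    Gametes are drawn under a uniform female and end-concentrated male
    landscape; sex maps are estimated from the (phase-known) gametes and
    summarized into the 1 Mb interval table.  Reports the mean |diff|
    near chromosome ends versus centrally and the zoib regression of the
    rescaled heterochiasmy index on relative distance to chromosome end.
    """
    genome = GenomeSpec.from_lengths(
        {"1": 60_000_000, "2": 50_000_000, "3": 40_000_000, "4": 30_000_000},
        macro_names={"1", "2"},
    )
    genome, panel, genes = simulate.simulate_genome(
        genome, markers_per_chrom=markers_per_chrom,
        rng=np.random.default_rng([seed, 606]),
    )
    model = simulate.default_crossover_model(
        genome, female_end_weight=0.0, male_end_weight=male_end_weight
    )
    rng = np.random.default_rng([seed, 607])
    rows = []
    batch = 1000
    for c in genome:
        pos = panel.positions(c.name)
        maps = {}
        sex_records = {}
        for sex in ("F", "M"):
            orig = simulate.simulate_gamete_origins(
                n_gametes, model[sex, c.name], pos, c.length_bp, rng
            )
            recs = [
                MeiosisRecord(
                    f"{sex}{i}", sex, [], orig[i : i + batch],
                    phase=np.zeros(len(pos), dtype=np.int8),
                )
                for i in range(0, n_gametes, batch)
            ]
            sex_records[sex] = recs
            maps[sex] = mapbuild.build_chrom_map(recs, pos)
        pooled = mapbuild.build_chrom_map(
            sex_records["F"] + sex_records["M"], pos
        )
        for i in range(len(pos)):
            rows.append(
                (c.name, f"m{i}", int(pos[i]), pooled[i], maps["F"][i], maps["M"][i])
            )
    sexmap = pd.DataFrame(rows, columns=SEXMAP_COLUMNS)
    table = landscape.build_interval_table(sexmap, genome, genes)
    ok = table.dropna(subset=["diff"])
    near = ok[ok["dist_rel"] < 0.1]["diff"].abs().mean()
    central = ok[ok["dist_rel"] > 0.4]["diff"].abs().mean()
    fit = hetstats.zoib_fit(ok["hi_rescaled"], ok["dist_rel"], seed=seed)
    return {
        "mean_absdiff_near_ends": float(near),
        "mean_absdiff_central": float(central),
        "end_to_centre_ratio": float(near / central),
        "zoib_dist_beta1": fit.beta1,
        "zoib_dist_ci": fit.ci_beta1,
        "n_intervals": len(ok),
        "n_gametes": n_gametes,
    }
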