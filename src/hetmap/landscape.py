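"""Recombination and heterochiasmy landscapes.

Per-chromosome rates are map length (cM) over physical size (Mb); the
mean autosomal rate is total autosomal map length over total autosomal
size, not the mean of per-chromosome rates.  The heterochiasmy index is
(female - male) / sex-averaged length at the chromosome scale, and
(rate_f - rate_m) / mean(rate_f, rate_m) within 1 Mb intervals — the
denominator that yields the stated bounds of -2 (no female
recombination) and +2 (no male recombination).  Intervals where neither
sex recombines get an index of 0: there is no sex difference to score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import GeneAnnotation, GenomeSpec
from .mapbuild import map_lengths

MB = 1_000_000


def chromosome_summary(
    sexmap: pd.DataFrame, genome: GenomeSpec
) -> tuple[pd.DataFrame, dict]:
    """Per-chromosome lengths, rates, heterochiasmy index, plus autosomal totals."""
    lengths = map_lengths(sexmap)
    rows = []
    for _, r in lengths.iterrows():
        chrom = r["chrom"]
        size_mb = genome[chrom].length_mb
        F, M, A = r["cM_female"], r["cM_male"], r["cM_avg"]
        if A == 0 and F != M:
            raise ValueError(f"{chrom}: sex-averaged length 0 with F != M")
        rows.append(
            {
                "chrom": chrom,
                "size_mb": size_mb,
                "n_snps": int(r["n_snps"]),
                "cM_female": F,
                "cM_male": M,
                "cM_avg": A,
                "hi": (F - M) / A if A > 0 else 0.0,
                "rate_avg": A / size_mb,
                "rate_female": F / size_mb,
                "rate_male": M / size_mb,
                "class": "macro" if genome[chrom].is_macro else "micro",
                "is_autosome": genome.is_autosome(chrom),
            }
        )
    per_chrom = pd.DataFrame(rows)
    auto = per_chrom[per_chrom["is_autosome"]]
    tot_f = float(auto["cM_female"].sum())
    tot_m = float(auto["cM_male"].sum())
    tot_a = float(auto["cM_avg"].sum())
    tot_size = float(auto["size_mb"].sum())
    totals = {
        "total_cM_female": tot_f,
        "total_cM_male": tot_m,
        "total_cM_avg": tot_a,
        "total_size_mb": tot_size,
        "mean_rate_avg": tot_a / tot_size if tot_size else float("nan"),
        "mean_rate_female": tot_f / tot_size if tot_size else float("nan"),
        "mean_rate_male": tot_m / tot_size if tot_size else float("nan"),
        "genome_hi": (tot_f - tot_m) / tot_a if tot_a else 0.0,
        "pct_male_excess": 100.0 * (tot_m - tot_f) / tot_f if tot_f else float("nan"),
        "n_female_longer": int((auto["cM_female"] > auto["cM_male"]).sum()),
    }
    return per_chrom, totals


def interval_rates(
    sexmap: pd.DataFrame, genome: GenomeSpec, width: int = MB
) -> pd.DataFrame:
    """Sex-specific cM/Mb per non-overlapping window of ``width`` bp.

    Windows tile [0, L) anchored at 0 (0-based half-open); the trailing
    partial window is retained.  A window's rate is the genetic distance
    between its first and last marker over their physical separation;
    windows with fewer than two markers (or coincident first/last bp)
    are reported with NaN rates and excluded downstream.
    """
    rows = []
    for chrom, sub in sexmap.groupby("chrom", sort=False):
        L = genome[chrom].length_bp
        pos = sub["pos_bp"].to_numpy(dtype=float) - 1  # to 0-based
        edges = np.arange(0, L, width)
        for start in edges:
            end = min(start + width, L)
            in_win = (pos >= start) & (pos < end)
            rec = {
                "chrom": chrom,
                "start_bp": int(start),
                "end_bp": int(end),
                "n_snps": int(in_win.sum()),
                "class": "macro" if genome[chrom].is_macro else "micro",
            }
            if in_win.sum() >= 2:
                first, last = np.flatnonzero(in_win)[[0, -1]]
                span_mb = (pos[last] - pos[first]) / MB
                if span_mb > 0:
                    for col, name in (
                        ("cM_female", "rate_f"),
                        ("cM_male", "rate_m"),
                        ("cM_avg", "rate_avg"),
                    ):
                        cm = sub[col].to_numpy(dtype=float)
                        rec[name] = (cm[last] - cm[first]) / span_mb
            for name in ("rate_f", "rate_m", "rate_avg"):
                rec.setdefault(name, np.nan)
            rows.append(rec)
    return pd.DataFrame(rows)


def interval_heterochiasmy(rate_f, rate_m) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(diff, HI, |HI|/2) from per-interval sex-specific rates.

    HI = (rate_f - rate_m) / mean(rate_f, rate_m), set to 0 where both
    rates are 0; NaN propagates where either rate is unavailable.
    """
    f = np.asarray(rate_f, dtype=float)
    m = np.asarray(rate_m, dtype=float)
    if np.any(f[np.isfinite(f)] < 0) or np.any(m[np.isfinite(m)] < 0):
        raise ValueError("rates must be >= 0")
    diff = f - m
    denom = (f + m) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        hi = np.where(denom > 0, diff / denom, 0.0)
    hi = np.where(np.isnan(diff), np.nan, hi)
    return diff, hi, np.abs(hi) / 2.0


def gene_density(genes: GeneAnnotation, intervals: pd.DataFrame) -> np.ndarray:
    """Count named genes strictly contained in each interval.

    Containment is on 0-based half-open coordinates: gene start >=
    interval start and gene end <= interval end.  Boundary-spanning
    genes count in neither interval; unnamed annotations never count.
    """
    named = genes.df[genes.df["named"]]
    counts = np.zeros(len(intervals), dtype=np.int64)
    for chrom, sub in named.groupby("chrom", sort=False):
        mask = (intervals["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        g_start = sub["start_bp"].to_numpy()
        g_end = sub["end_bp"].to_numpy()
        for row_i in np.flatnonzero(mask):
            s = intervals["start_bp"].iloc[row_i]
            e = intervals["end_bp"].iloc[row_i]
            counts[row_i] = int(((g_start >= s) & (g_end <= e)).sum())
    return counts


def distance_to_end(intervals: pd.DataFrame, genome: GenomeSpec) -> tuple[np.ndarray, np.ndarray]:
    """Actual (bp) and relative (0-0.5) distance of interval midpoints to
    the nearest chromosome end; 0 is an end, 0.5 the centre."""
    dist_bp = np.empty(len(intervals), dtype=float)
    dist_rel = np.empty(len(intervals), dtype=float)
    for i, (_, r) in enumerate(intervals.iterrows()):
        L = genome[r["chrom"]].length_bp
        mid = (r["start_bp"] + r["end_bp"]) / 2.0
        d = min(mid, L - mid)
        dist_bp[i] = d
        dist_rel[i] = d / L
    return dist_bp, dist_rel


def build_interval_table(
    sexmap: pd.DataFrame,
    genome: GenomeSpec,
    genes: GeneAnnotation | None = None,
    width: int = MB,
) -> pd.DataFrame:
    """Full per-interval table: rates, heterochiasmy, genes, distances."""
    tab = interval_rates(sexmap, genome, width)
    diff, hi, hi_rescaled = interval_heterochiasmy(tab["rate_f"], tab["rate_m"])
    tab["diff"] = diff
    tab["hi"] = hi
    tab["hi_rescaled"] = hi_rescaled
    if genes is not None:
        tab["gene_count"] = gene_density(genes, tab)
    dist_bp, dist_rel = distance_to_end(tab, genome)
    tab["dist_bp"] = dist_bp
    tab["dist_rel"] = dist_rel
    return tab


def marey_curve(
    sexmap: pd.DataFrame, span_snps: int = 50, min_markers: int = 10
) -> pd.DataFrame:
    """Marey curves: proportional genetic position against bp, LOESS-smoothed.

    Genetic positions are scaled to [0, 1] per sex and chromosome so
    landscapes are comparable across sexes.  LOESS uses tricube weights,
    local degree 1, no robustness iterations, with span
    min(1, span_snps / n_markers); chromosomes with fewer than
    ``min_markers`` markers get raw points only.
    """
    rows = []
    for chrom, sub in sexmap.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy(dtype=float)
        n = len(pos)
        span = min(1.0, span_snps / n) if n else 1.0
        for sex, col in (("F", "cM_female"), ("M", "cM_male")):
            cm = sub[col].to_numpy(dtype=float)
            total = cm[-1]
            if total <= 0:
                continue
            prop = cm / total
            if n >= min_markers:
                smooth = lowess(
                    prop, pos, frac=span, it=0, return_sorted=False
                )
            else:
                smooth = np.full(n, np.nan)
            for p, raw, sm in zip(pos, prop, smooth):
                rows.append(
                    {
                        "chrom": chrom,
                        "sex": sex,
                        "pos_bp": p,
                        "prop_cm": raw,
                        "smoothed": sm,
                        "span": span,
                    }
                )
    return pd.DataFrame(rows)
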