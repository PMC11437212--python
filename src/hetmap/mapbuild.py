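"""Sex-specific linkage map estimation on a fixed physical marker order.

Meioses are traced through full-sib trios (with grandparents resolving
parental phase where genotyped); recombination fractions between
physically adjacent markers are estimated per parent sex and converted
to centiMorgans with the Haldane mapping function, which assumes
independent crossovers.  The sex-averaged map is re-estimated from the
pooled male + female meioses, not averaged from the two sex maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, GenotypeData, SEXMAP_COLUMNS, validate_sexmap

R_CAP_DEFAULT = 0.49


# --------------------------------------------------------------------------
# Haldane mapping function


def haldane_cm(r, r_cap: float = R_CAP_DEFAULT):
    """Map distance d = -50 ln(1 - 2r) in cM; r at or above r_cap is capped."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("recombination fraction must be >= 0")
    if np.any(r >= r_cap):
        warnings.warn(
            f"recombination fraction >= {r_cap} capped before Haldane transform",
            stacklevel=2,
        )
    r_eff = np.minimum(r, r_cap)
    d = -50.0 * np.log1p(-2.0 * r_eff)
    return float(d) if d.ndim == 0 else d


def haldane_r(d_cm):
    """Inverse Haldane: r = (1 - exp(-2 d / 100)) / 2."""
    d = np.asarray(d_cm, dtype=float)
    r = 0.5 * (1.0 - np.exp(-d / 50.0))
    return float(r) if r.ndim == 0 else r


# --------------------------------------------------------------------------
# transmission inference


@dataclass
class MeiosisRecord:
    """Traced transmissions of one parent's gametes to its offspring.

    transmissions : (n_offspring, n_markers) int8, transmitted allele
        index 0/1 where the parent is heterozygous and the trio resolves
        it uniquely, else -1.
    phase : parent's paternal (grandfather-derived) allele at each
        heterozygous marker (0/1), -1 unknown; present only when the
        parent's own parents were genotyped.
    """

    parent: str
    sex: str
    offspring: list[str]
    transmissions: np.ndarray
    phase: np.ndarray | None = None

    def slice_markers(self, idx: np.ndarray) -> "MeiosisRecord":
        return MeiosisRecord(
            self.parent,
            self.sex,
            self.offspring,
            self.transmissions[:, idx],
            None if self.phase is None else self.phase[idx],
        )


# transmitted-allele lookup over (other-parent dosage + 1, offspring dosage + 1);
# applies only where the focal parent is heterozygous
_TRANS_LUT = np.full((4, 4), -1, dtype=np.int8)
for _o, _g, _t in [
    # other parent missing: offspring homozygote forces the focal allele
    (MISSING, 0, 0), (MISSING, 2, 1),
    (0, 0, 0), (0, 1, 1),            # other AA: offspring dosage = focal allele
    (2, 1, 0), (2, 2, 1),            # other aa
    (1, 0, 0), (1, 2, 1),            # other Aa: only homozygous offspring resolve
]:
    _TRANS_LUT[_o + 1, _g + 1] = _t


def _transmitted(parent: np.ndarray, other: np.ndarray, child: np.ndarray) -> np.ndarray:
    """Transmitted allele (0/1, -1 unresolved) from `parent` at every marker."""
    t = _TRANS_LUT[other + 1, child + 1]
    return np.where(parent == 1, t, -1).astype(np.int8)


def _phase_from_grandparents(
    parent_g: np.ndarray, gf_g: np.ndarray, gm_g: np.ndarray
) -> np.ndarray:
    """Paternal allele of the parent at its heterozygous markers (-1 unknown)."""
    pat = np.full(parent_g.shape, -1, dtype=np.int8)
    pat[gf_g == 0] = 0
    pat[gf_g == 2] = 1
    t_gf = _transmitted(gf_g, gm_g, parent_g)
    pat = np.where((pat == -1) & (t_gf >= 0), t_gf, pat)
    # resolve via the grandmother: at a heterozygous marker the paternal
    # allele is the complement of the maternal one
    mat = np.full(parent_g.shape, -1, dtype=np.int8)
    mat[gm_g == 0] = 0
    mat[gm_g == 2] = 1
    t_gm = _transmitted(gm_g, gf_g, parent_g)
    mat = np.where((mat == -1) & (t_gm >= 0), t_gm, mat)
    pat = np.where((pat == -1) & (mat >= 0), 1 - mat, pat)
    return np.where(parent_g == 1, pat, -1).astype(np.int8)


def infer_transmissions(gd: GenotypeData) -> list[MeiosisRecord]:
    """Trace parent-offspring transmissions for every full-sib family.

    Offspring are grouped by (father, mother) pairs present in the
    dataset; each parent of a pair yields one record.  Mendelian-
    inconsistent trio calls come out unresolved, not as exceptions.
    """
    idx = gd.sample_index()
    g = gd.genotypes
    fam = gd.samples[
        gd.samples["father"].isin(idx) & gd.samples["mother"].isin(idx)
    ]
    records: list[MeiosisRecord] = []
    for (fa, mo), sub in fam.groupby(["father", "mother"], sort=False):
        kids = list(sub["iid"])
        father_g = g[idx[fa]]
        mother_g = g[idx[mo]]
        child_g = np.stack([g[idx[k]] for k in kids])
        for parent, pg, og, sex in (
            (fa, father_g, mother_g, "M"),
            (mo, mother_g, father_g, "F"),
        ):
            trans = np.stack([_transmitted(pg, og, cg) for cg in child_g])
            prow = gd.samples.loc[gd.samples["iid"] == parent].iloc[0]
            phase = None
            if prow["father"] in idx and prow["mother"] in idx:
                phase = _phase_from_grandparents(
                    pg, g[idx[prow["father"]]], g[idx[prow["mother"]]]
                )
            records.append(MeiosisRecord(parent, sex, kids, trans, phase))
    return records


# --------------------------------------------------------------------------
# recombination-fraction estimation


@dataclass
class IntervalEstimate:
    """Two-point estimate between markers i and j (panel indices)."""

    i: int
    j: int
    n: int
    k: int
    r_hat: float
    d_cM: float
    capped: bool = False


def _pair_counts(rec: MeiosisRecord, i: int, j: int) -> tuple[int, int]:
    """(n, contribution) of one parent for marker pair (i, j).

    Grandparent-phased parents contribute the direct recombinant count;
    phase-unknown parents contribute min(k, n-k), the two-point ML count
    under r < 0.5.
    """
    ti = rec.transmissions[:, i]
    tj = rec.transmissions[:, j]
    mask = (ti >= 0) & (tj >= 0)
    n = int(mask.sum())
    if n == 0:
        return 0, 0
    if rec.phase is not None and rec.phase[i] >= 0 and rec.phase[j] >= 0:
        hi = ti[mask] != rec.phase[i]
        hj = tj[mask] != rec.phase[j]
        return n, int((hi != hj).sum())
    if n < 2:  # min(k, n-k) is identically 0 at n=1: uninformative, not a zero
        return 0, 0
    k = int((ti[mask] != tj[mask]).sum())
    return n, min(k, n - k)


def estimate_r(
    records: list[MeiosisRecord],
    i: int,
    j: int,
    r_cap: float = R_CAP_DEFAULT,
) -> IntervalEstimate:
    """Pooled two-point recombination fraction across parents."""
    N = K = 0
    for rec in records:
        n, c = _pair_counts(rec, i, j)
        N += n
        K += c
    if N == 0:
        return IntervalEstimate(i, j, 0, 0, float("nan"), float("nan"))
    r = K / N
    capped = r >= r_cap
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = haldane_cm(min(r, r_cap), r_cap=r_cap)
    return IntervalEstimate(i, j, N, K, r, float(d), capped)


def _link_stats(Ti: np.ndarray, ph: np.ndarray | None):
    """Per-link voter counts, folded switch counts, phase chain and breaks.

    ``Ti`` holds transmitted alleles at a parent's informative markers
    (-1 unresolved); ``ph`` the grandparent-derived paternal allele at
    those markers, or None.  The min-fold per link is orientation-free,
    so a tied vote still counts its recombinant without knowing the
    phase; ties are chain breaks because mis-resolving one would flip
    every other meiosis crossing the link.
    """
    res_i = Ti >= 0
    both = res_i[:, :-1] & res_i[:, 1:]
    m = both.sum(axis=0)
    e = ((Ti[:, :-1] != Ti[:, 1:]) & both).sum(axis=0)
    delta = (e > m - e).astype(np.int8)
    k_link = np.minimum(e, m - e).astype(float)
    n_link = np.where(m >= 2, m, 0).astype(float)
    broken = (m < 2) | (e * 2 == m)
    if ph is not None:
        anchored = (ph[:-1] >= 0) & (ph[1:] >= 0)
        delta_gp = (ph[:-1] != ph[1:]).astype(np.int8)
        delta = np.where(anchored, delta_gp, delta)
        # an allele change across an anchored link is a switch only when
        # the phase labelling is constant across it
        k_gp = np.where(delta_gp == 1, m - e, e).astype(float)
        k_link = np.where(anchored, k_gp, k_link)
        n_link = np.where(anchored, m.astype(float), n_link)
        broken = broken & ~anchored
    psi = np.zeros(Ti.shape[1], dtype=np.int8)
    psi[1:] = np.cumsum(np.where(broken, 0, delta), dtype=np.int64) % 2
    break_before = np.zeros(Ti.shape[1], dtype=np.int64)
    break_before[1:] = np.cumsum(broken)
    return res_i, k_link, n_link, broken, psi, break_before


def _mask_singleton_flips(Ti: np.ndarray, ph: np.ndarray | None) -> None:
    """Mask in place lone origin flips flanked by agreeing neighbours.

    A call implying a crossover immediately followed by another within a
    few marker intervals is overwhelmingly a genotyping error, which
    would otherwise inflate the map.  The test phases each meiosis
    against the other meioses of the same parent (leave-one-out link
    majorities, so the tested meiosis cannot poison its own reference),
    with grandparent anchors overriding where available.
    """
    res_i = Ti >= 0
    both = res_i[:, :-1] & res_i[:, 1:]
    chg = (Ti[:, :-1] != Ti[:, 1:]) & both
    m = both.sum(axis=0)
    e = chg.sum(axis=0)
    anchored = None
    delta_gp = None
    if ph is not None:
        anchored = (ph[:-1] >= 0) & (ph[1:] >= 0)
        delta_gp = (ph[:-1] != ph[1:]).astype(np.int8)
    for o in range(Ti.shape[0]):
        ridx = np.flatnonzero(res_i[o])
        if len(ridx) < 3:
            continue
        m_lo = m - both[o]
        e_lo = e - chg[o]
        delta = (2 * e_lo > m_lo).astype(np.int8)
        valid = (m_lo >= 1) & (2 * e_lo != m_lo)
        if anchored is not None:
            delta = np.where(anchored, delta_gp, delta)
            valid = valid | anchored
        delta_cum = np.concatenate([[0], np.cumsum(delta, dtype=np.int64)])
        invalid_cum = np.concatenate([[0], np.cumsum(~valid, dtype=np.int64)])
        a, j, b = ridx[:-2], ridx[1:-1], ridx[2:]
        path_ok = invalid_cum[b] == invalid_cum[a]
        d1 = (delta_cum[j] - delta_cum[a]) % 2  # phase flip along a -> j
        d2 = (delta_cum[b] - delta_cum[j]) % 2
        c1 = (Ti[o, a] != Ti[o, j]) != (d1 == 1)
        c2 = (Ti[o, j] != Ti[o, b]) != (d2 == 1)
        singleton = path_ok & c1 & c2
        Ti[o, j[singleton]] = -1


def _chain_counts(
    records: list[MeiosisRecord], positions_bp: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-atomic-interval meiosis coverage (n) and switch mass (k).

    Each parent is phased along the chromosome by chaining: grandparent-
    derived phase anchors links where available; otherwise the relative
    phase between consecutive informative markers is set by majority
    vote over the offspring resolved at both (the per-link analogue of
    min(k, n-k), exact for tightly linked markers).  Links with fewer
    than two informative meioses and no grandparent anchor are phase
    breaks: spans crossing them contribute nothing, so they cost
    coverage, never bias.  Isolated single-marker origin flips are
    treated as genotyping errors and masked (a true double crossover
    within a few marker intervals is orders of magnitude rarer than a
    miscalled genotype), then counting is repeated on the cleaned calls.
    Each meiosis contributes one Bernoulli observation per consecutive-
    resolved-marker span; a switch is spread over the span's atomic
    intervals proportionally to physical length.
    """
    M = len(positions_bp)
    pos = positions_bp.astype(float)
    seg_len = np.diff(pos)
    # accumulate coverage and switch densities with difference arrays
    n_diff = np.zeros(M, dtype=float)
    kdens_diff = np.zeros(M, dtype=float)
    for rec in records:
        T = rec.transmissions
        resolved_any = (T >= 0).any(axis=0)
        if rec.phase is not None:
            informative = resolved_any | (rec.phase >= 0)
        else:
            informative = resolved_any
        inf = np.flatnonzero(informative)
        if len(inf) < 2:
            continue
        Ti = T[:, inf].copy()
        ph = rec.phase[inf] if rec.phase is not None else None

        _mask_singleton_flips(Ti, ph)
        res_i, k_link, n_link, broken, psi, break_before = _link_stats(Ti, ph)

        span_bp = pos[inf[1:]] - pos[inf[:-1]]
        active = n_link > 0
        np.add.at(n_diff, inf[:-1][active], n_link[active])
        np.add.at(n_diff, inf[1:][active], -n_link[active])
        kd = k_link[active] / span_bp[active]
        np.add.at(kdens_diff, inf[:-1][active], kd)
        np.add.at(kdens_diff, inf[1:][active], -kd)

        origins = (Ti != psi[None, :]) & res_i
        for o in range(Ti.shape[0]):
            ridx = np.flatnonzero(res_i[o])
            if len(ridx) < 2:
                continue
            a_idx = ridx[:-1]
            b_idx = ridx[1:]
            multi = b_idx - a_idx > 1  # unit links were already counted
            ok = multi & (break_before[b_idx] == break_before[a_idx])
            if not ok.any():
                continue
            switch = origins[o, a_idx] != origins[o, b_idx]
            for ai, bi, sw in zip(a_idx[ok], b_idx[ok], switch[ok]):
                am, bm = inf[ai], inf[bi]
                n_diff[am] += 1.0
                n_diff[bm] -= 1.0
                if sw:
                    dens = 1.0 / (pos[bm] - pos[am])
                    kdens_diff[am] += dens
                    kdens_diff[bm] -= dens
    n = np.maximum(np.cumsum(n_diff[:-1]), 0.0)
    k = np.maximum(np.cumsum(kdens_diff[:-1]), 0.0) * seg_len
    return n, k


def build_chrom_map(
    records: list[MeiosisRecord],
    positions_bp: np.ndarray,
    n_min: int = 5,
    r_cap: float = R_CAP_DEFAULT,
) -> np.ndarray:
    """Cumulative cM positions for one chromosome's markers.

    Atomic adjacent intervals with fewer than ``n_min`` covering meioses
    are merged rightward until the coverage is reached; within a merged
    span the estimated distance is spread linearly in physical position.
    """
    M = len(positions_bp)
    cm = np.zeros(M, dtype=float)
    if M < 2 or not records:
        return cm
    positions_bp = np.asarray(positions_bp)
    n, k = _chain_counts(records, positions_bp)
    seg_len = np.diff(positions_bp.astype(float))
    spans: list[tuple[int, int, float]] = []
    a = 0
    while a < M - 1:
        b = a + 1
        # merge rightward until the span's length-weighted coverage reaches n_min
        while b < M:
            w = seg_len[a:b]
            n_bar = float(np.sum(n[a:b] * w) / np.sum(w))
            if n_bar >= n_min:
                break
            b += 1
        if b == M:  # unfinished right tail: fold into the previous span
            if spans:
                pa, _, _ = spans.pop()
                a = pa
            b = M - 1
            w = seg_len[a:b]
            n_bar = float(np.sum(n[a:b] * w) / np.sum(w))
        r = float(np.sum(k[a:b]) / n_bar) if n_bar > 0 else 0.0
        spans.append((a, b, r))
        a = b
    for a, b, r in spans:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = haldane_cm(min(r, r_cap), r_cap=r_cap)
        seg = positions_bp[a : b + 1].astype(float)
        frac = (seg - seg[0]) / (seg[-1] - seg[0])
        cm[a : b + 1] = cm[a] + d * frac
    return cm


def build_sex_map(
    gd: GenotypeData,
    records: list[MeiosisRecord] | None = None,
    n_min: int = 5,
    min_snps: int = 70,
    r_cap: float = R_CAP_DEFAULT,
) -> pd.DataFrame:
    """Female, male and pooled sex-averaged maps on the physical order.

    Chromosomes with ``min_snps`` or fewer markers are dropped (map
    retention requires > min_snps markers).
    """
    if records is None:
        records = infer_transmissions(gd)
    rows = []
    markers = gd.markers
    for chrom in markers["chrom"].unique():
        idx = np.flatnonzero((markers["chrom"] == chrom).to_numpy())
        if len(idx) <= min_snps:
            continue
        pos = markers["pos_bp"].to_numpy()[idx]
        sliced = [rec.slice_markers(idx) for rec in records]
        f_rec = [r for r in sliced if r.sex == "F"]
        m_rec = [r for r in sliced if r.sex == "M"]
        cm_f = build_chrom_map(f_rec, pos, n_min, r_cap)
        cm_m = build_chrom_map(m_rec, pos, n_min, r_cap)
        cm_a = build_chrom_map(sliced, pos, n_min, r_cap)
        sub = markers.iloc[idx]
        for mid, p, ca, cf, cmm in zip(sub["id"], pos, cm_a, cm_f, cm_m):
            rows.append((chrom, mid, int(p), float(ca), float(cf), float(cmm)))
    df = pd.DataFrame(rows, columns=SEXMAP_COLUMNS)
    if len(df):
        validate_sexmap(df)
    return df


def map_lengths(sexmap: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome map lengths (cM of the last marker) per sex."""
    out = []
    for chrom, sub in sexmap.groupby("chrom", sort=False):
        out.append(
            {
                "chrom": chrom,
                "n_snps": len(sub),
                "cM_avg": float(sub["cM_avg"].iloc[-1]),
                "cM_female": float(sub["cM_female"].iloc[-1]),
                "cM_male": float(sub["cM_male"].iloc[-1]),
            }
        )
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# contig ordering and end-artifact flagging


def order_contigs_by_map(
    df: pd.DataFrame, min_markers: int = 3
) -> pd.DataFrame:
    """Order contigs along a chromosome by mean genetic position.

    ``df`` needs columns contig, pos_bp (within-contig), cm.  Contigs
    with fewer than ``min_markers`` markers are removed.  Orientation is
    the sign of the within-contig rank correlation of bp against cM;
    an undefined or zero correlation yields '+' with an ambiguity flag.
    """
    rows = []
    for contig, sub in df.groupby("contig", sort=False):
        if len(sub) < min_markers:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = stats.spearmanr(sub["pos_bp"], sub["cm"]).statistic
        ambiguous = not np.isfinite(rho) or rho == 0
        rows.append(
            {
                "contig": contig,
                "mean_cm": float(sub["cm"].mean()),
                "min_cm": float(sub["cm"].min()),
                "max_cm": float(sub["cm"].max()),
                "length_bp": int(sub["pos_bp"].max()),
                "orientation": "+" if (ambiguous or rho > 0) else "-",
                "orientation_ambiguous": bool(ambiguous),
            }
        )
    out = pd.DataFrame(rows).sort_values("mean_cm", kind="stable").reset_index(drop=True)
    if len(out) > 1:
        overlap = (out["min_cm"].to_numpy()[1:] < out["max_cm"].to_numpy()[:-1])
        if overlap.any():
            warnings.warn(
                "contig genetic spans overlap; ordering by mean cM", stacklevel=2
            )
    return out


def flag_end_artifacts(
    sexmap: pd.DataFrame,
    cm_per_marker: float = 2.0,
    max_span_bp: int = 100_000,
    columns: tuple[str, ...] = ("cM_avg", "cM_female", "cM_male"),
) -> pd.DataFrame:
    """Flag steep terminal marker runs suggesting phasing/mapping errors.

    A maximal run of consecutive terminal intervals each gaining more
    than ``cm_per_marker`` cM within a physical span under
    ``max_span_bp`` is reported for manual truncation; nothing is
    removed automatically.
    """
    flags = []
    for chrom, sub in sexmap.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy(dtype=float)
        for col in columns:
            cm = sub[col].to_numpy(dtype=float)
            inc = np.diff(cm)
            if len(inc) == 0:
                continue
            for end, order in (("right", slice(None, None, -1)), ("left", slice(None))):
                run = 0
                seq = inc[order]
                for v in seq:
                    if v > cm_per_marker:
                        run += 1
                    else:
                        break
                if run == 0:
                    continue
                if end == "right":
                    span = pos[-1] - pos[-(run + 1)]
                    markers = list(sub["marker"].iloc[-run:])
                else:
                    span = pos[run] - pos[0]
                    markers = list(sub["marker"].iloc[:run])
                if span < max_span_bp:
                    flags.append(
                        {
                            "chrom": chrom,
                            "column": col,
                            "end": end,
                            "n_markers": run,
                            "cm_gain": float(seq[:run].sum()),
                            "span_bp": float(span),
                            "markers": ",".join(markers),
                        }
                    )
    return pd.DataFrame(
        flags,
        columns=["chrom", "column", "end", "n_markers", "cm_gain", "span_bp", "markers"],
    )
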