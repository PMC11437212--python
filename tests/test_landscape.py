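import numpy as np
import pandas as pd
import pytest

import hetmap as hm
from hetmap import landscape
from hetmap.core import GeneAnnotation


def _sexmap(chrom, pos, cm_f, cm_m, cm_a=None):
    cm_a = cm_a if cm_a is not None else (np.asarray(cm_f) + np.asarray(cm_m)) / 2
    return pd.DataFrame(
        {
            "chrom": chrom,
            "marker": [f"m{i}" for i in range(len(pos))],
            "pos_bp": pos,
            "cM_avg": cm_a,
            "cM_female": cm_f,
            "cM_male": cm_m,
        }
    )


@pytest.fixture
def genome():
    return hm.GenomeSpec.from_lengths({"1": 10_000_000, "2": 4_000_000}, macro_names={"1"})


class TestChromosomeSummary:
    def test_heterochiasmy_index_and_rates(self, genome):
        pos = np.linspace(1, 10_000_000, 80).astype(int)
        sm = _sexmap("1", pos, np.linspace(0, 97.51, 80), np.linspace(0, 121.82, 80),
                     np.linspace(0, 108.97, 80))
        per, totals = landscape.chromosome_summary(sm, genome)
        row = per.iloc[0]
        assert row["hi"] == pytest.approx((97.51 - 121.82) / 108.97)
        assert row["rate_avg"] == pytest.approx(108.97 / 10.0)
        assert totals["pct_male_excess"] == pytest.approx(
            100 * (121.82 - 97.51) / 97.51
        )

    def test_equal_sexes_zero_index(self, genome):
        pos = np.linspace(1, 10_000_000, 80).astype(int)
        cm = np.linspace(0, 50, 80)
        per, totals = landscape.chromosome_summary(_sexmap("1", pos, cm, cm, cm), genome)
        assert per["hi"].iloc[0] == 0
        assert totals["genome_hi"] == 0


class TestIntervalRates:
    def test_rate_arithmetic(self, genome):
        # two markers 0.75 Mb apart, 1.5 cM apart -> 2 cM/Mb
        sm = _sexmap("1", [100_001, 850_001], [0, 1.5], [0, 1.5])
        tab = landscape.interval_rates(sm, genome)
        first = tab.iloc[0]
        assert first["rate_f"] == pytest.approx(2.0)
        assert first["n_snps"] == 2

    def test_single_marker_interval_unavailable(self, genome):
        sm = _sexmap("1", [100_001, 1_500_001, 1_600_001], [0, 1, 2], [0, 1, 2])
        tab = landscape.interval_rates(sm, genome)
        assert np.isnan(tab.iloc[0]["rate_f"])

    def test_uniform_map_gives_homogeneous_rates(self, genome):
        pos = (np.arange(100) * 100_000 + 50_000).astype(int)
        cm = (pos - pos[0]) / 1e6 * 3.0  # 3 cM/Mb everywhere
        tab = landscape.interval_rates(_sexmap("1", pos, cm, cm), genome)
        ok = tab.dropna(subset=["rate_f"])
        assert np.allclose(ok["rate_f"], 3.0)

    def test_tiling_anchored_at_zero_with_partial_tail(self, genome):
        sm = _sexmap("2", [1, 3_900_000], [0, 5], [0, 5])
        tab = landscape.interval_rates(sm, genome)
        assert tab["start_bp"].tolist() == [0, 1_000_000, 2_000_000, 3_000_000]
        assert tab["end_bp"].iloc[-1] == 4_000_000


class TestIntervalHeterochiasmy:
    @pytest.mark.parametrize(
        "f,m,diff,hi,resc",
        [
            (1.0, 0.0, 1.0, 2.0, 1.0),
            (0.0, 0.0, 0.0, 0.0, 0.0),
            (3.0, 1.0, 2.0, 1.0, 0.5),
            (0.0, 1.0, -1.0, -2.0, 1.0),
        ],
    )
    def test_index_conventions(self, f, m, diff, hi, resc):
        d, h, r = landscape.interval_heterochiasmy([f], [m])
        assert d[0] == pytest.approx(diff)
        assert h[0] == pytest.approx(hi)
        assert r[0] == pytest.approx(resc)

    def test_unavailable_propagates(self):
        d, h, r = landscape.interval_heterochiasmy([np.nan], [1.0])
        assert np.isnan(d[0]) and np.isnan(h[0]) and np.isnan(r[0])

    def test_bounds_hold_for_random_rates(self):
        rng = np.random.default_rng(0)
        f = rng.exponential(2, 500)
        m = rng.exponential(2, 500)
        d, h, r = landscape.interval_heterochiasmy(f, m)
        assert np.all(h >= -2) and np.all(h <= 2)
        assert np.all(r >= 0) and np.all(r <= 1)
        nz = d != 0
        assert np.all(np.sign(h[nz]) == np.sign(d[nz]))


class TestGeneDensity:
    def _intervals(self, genome):
        sm = _sexmap("1", (np.arange(100) * 100_000 + 1).astype(int),
                     np.linspace(0, 10, 100), np.linspace(0, 10, 100))
        return landscape.interval_rates(sm, genome)

    def test_containment_rules(self, genome):
        tab = self._intervals(genome)
        genes = GeneAnnotation(
            pd.DataFrame(
                {
                    "id": ["in", "spanning", "unnamed"],
                    "chrom": "1",
                    "start_bp": [1_200_000, 900_000, 1_300_000],
                    "end_bp": [1_800_000, 1_100_000, 1_400_000],
                    "named": [True, True, False],
                }
            )
        )
        counts = landscape.gene_density(genes, tab)
        assert counts[1] == 1  # only the strictly contained named gene
        assert counts[0] == 0  # the boundary-spanning gene counts nowhere

    def test_matches_bruteforce_scan(self, genome):
        rng = np.random.default_rng(2)
        n = 2000
        start = rng.integers(0, 9_900_000, n)
        length = rng.integers(1, 300_000, n)
        genes = GeneAnnotation(
            pd.DataFrame(
                {
                    "id": [f"g{i}" for i in range(n)],
                    "chrom": "1",
                    "start_bp": start,
                    "end_bp": np.minimum(start + length, 10_000_000),
                    "named": rng.random(n) < 0.8,
                }
            )
        )
        tab = self._intervals(genome)
        counts = landscape.gene_density(genes, tab)
        named = genes.df[genes.df["named"]]
        for i, (_, iv) in enumerate(tab.iterrows()):
            brute = sum(
                1
                for _, g in named.iterrows()
                if g["start_bp"] >= iv["start_bp"] and g["end_bp"] <= iv["end_bp"]
            )
            assert counts[i] == brute


class TestDistanceToEnd:
    def test_midpoint_conventions(self, genome):
        tab = pd.DataFrame(
            {
                "chrom": ["1", "1", "1"],
                "start_bp": [4_500_000, 0, 2_000_000],
                "end_bp": [5_500_000, 0, 3_000_000],
            }
        )
        dist_bp, dist_rel = landscape.distance_to_end(tab, genome)
        assert dist_rel[0] == pytest.approx(0.5)
        assert dist_rel[1] == pytest.approx(0.0)
        assert dist_rel[2] == pytest.approx(0.25)
        assert dist_bp[2] == pytest.approx(2_500_000)


class TestMareyCurve:
    def test_linear_map_smoothed_exactly(self):
        pos = np.linspace(1, 5_000_000, 200)
        cm = np.linspace(0, 80, 200)
        curve = landscape.marey_curve(_sexmap("1", pos.astype(int), cm, cm))
        f = curve[curve["sex"] == "F"]
        assert np.allclose(f["smoothed"], f["prop_cm"], atol=1e-6)
        assert f["prop_cm"].iloc[0] == 0 and f["prop_cm"].iloc[-1] == 1

    def test_span_formula_and_small_maps(self):
        pos = np.linspace(1, 5_000_000, 5000)
        cm = np.linspace(0, 80, 5000)
        curve = landscape.marey_curve(_sexmap("1", pos.astype(int), cm, cm))
        assert curve["span"].iloc[0] == pytest.approx(0.01)
        tiny = landscape.marey_curve(
            _sexmap("1", [1, 10, 100, 1000], [0, 1, 2, 3], [0, 1, 2, 3])
        )
        assert tiny["smoothed"].isna().all()


def test_interval_cm_sums_bounded_by_map_length(toy_dataset, toy_genome):
    # sum of within-interval genetic spans never exceeds the map length
    *_, gd, _ = toy_dataset
    sexmap = hm.build_sex_map(gd, min_snps=70)
    for chrom, sub in sexmap.groupby("chrom"):
        pos0 = sub["pos_bp"].to_numpy() - 1
        cm = sub["cM_female"].to_numpy()
        total = 0.0
        for start in range(0, toy_genome[chrom].length_bp, 1_000_000):
            inside = (pos0 >= start) & (pos0 < start + 1_000_000)
            if inside.sum() >= 2:
                total += cm[inside].max() - cm[inside].min()
        assert total <= cm[-1] + 1e-9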