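import math

import numpy as np
import pandas as pd
import pytest

import hetmap as hm
from hetmap import mapbuild, simulate
from hetmap.core import GenotypeData
from hetmap.mapbuild import MeiosisRecord


def _trio_gd(parent, other, children, chrom="1"):
    """One family: father = `parent`, mother = `other` (dosage vectors)."""
    rows = [("F1", "dad", "0", "0", "M"), ("F1", "mum", "0", "0", "F")]
    g = [parent, other]
    for i, c in enumerate(children):
        rows.append(("F1", f"kid{i}", "dad", "mum", "M"))
        g.append(c)
    m = len(parent)
    samples = pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex"])
    markers = pd.DataFrame(
        {"id": [f"m{j}" for j in range(m)], "chrom": chrom, "pos_bp": range(1, m + 1)}
    )
    return GenotypeData(np.asarray(g, dtype=np.int8), samples, markers)


class TestTransmissions:
    @pytest.mark.parametrize(
        "parent,other,child,expected",
        [
            (1, 0, 1, 1),   # Aa x AA, offspring Aa -> parent gave alt
            (1, 1, 1, -1),  # double het, het offspring unresolved
            (1, 2, 2, 1),   # Aa x aa, offspring aa -> parent gave alt
            (1, 2, 1, 0),
            (1, 1, 0, 0),
            (1, 1, 2, 1),
            (0, 0, 0, -1),  # parent homozygous: uninformative
        ],
    )
    def test_forced_and_unresolved_cases(self, parent, other, child, expected):
        gd = _trio_gd([parent], [other], [[child]])
        recs = mapbuild.infer_transmissions(gd)
        dad = next(r for r in recs if r.parent == "dad")
        assert dad.transmissions[0, 0] == expected

    def test_mendelian_inconsistent_call_goes_missing(self):
        gd = _trio_gd([1], [0], [[2]])  # offspring aa impossible from Aa x AA
        recs = mapbuild.infer_transmissions(gd)
        for rec in recs:
            assert rec.transmissions[0, 0] == -1


class TestEstimateR:
    def test_phased_parent_direct_count(self):
        trans = np.zeros((10, 2), dtype=np.int8)
        trans[:2, 1] = 1  # 2 switches in 10 meioses
        rec = MeiosisRecord("p", "F", [], trans, phase=np.zeros(2, dtype=np.int8))
        est = mapbuild.estimate_r([rec], 0, 1)
        assert est.r_hat == pytest.approx(0.2)
        assert est.n == 10 and est.k == 2

    def test_unphased_parent_min_fold(self):
        trans = np.zeros((10, 2), dtype=np.int8)
        trans[:8, 1] = 1  # 8 apparent switches -> min(8, 2)/10
        rec = MeiosisRecord("p", "F", [], trans, phase=None)
        est = mapbuild.estimate_r([rec], 0, 1)
        assert est.r_hat == pytest.approx(0.2)

    def test_monte_carlo_binomial_recovery(self):
        # true r = 0.1 between two markers, 2000 phased meioses
        rng = np.random.default_rng(8)
        lam = -0.5 * math.log(1 - 2 * 0.1)  # Haldane inverse, Morgans
        pos = np.array([1, 1_000_000])
        orig = simulate.simulate_gamete_origins(
            2000, simulate.ChromosomeCrossover(lam), pos, 1_000_000, rng
        )
        rec = MeiosisRecord("p", "F", [], orig, phase=np.zeros(2, dtype=np.int8))
        est = mapbuild.estimate_r([rec], 0, 1)
        assert abs(est.r_hat - 0.1) <= 3 * math.sqrt(0.1 * 0.9 / 2000)


class TestHaldane:
    def test_identity_and_closed_form(self):
        assert mapbuild.haldane_cm(0.0) == 0.0
        assert mapbuild.haldane_cm(0.2) == pytest.approx(-50 * math.log(0.6))

    def test_round_trip_exact(self):
        r = np.arange(0.01, 0.46, 0.01)
        back = mapbuild.haldane_r(mapbuild.haldane_cm(r))
        assert np.allclose(back, r, atol=1e-12)

    def test_cap_warns(self):
        with pytest.warns(UserWarning):
            d = mapbuild.haldane_cm(0.499)
        assert d == pytest.approx(mapbuild.haldane_cm(0.4899999), abs=1e-3)
        with pytest.raises(ValueError):
            mapbuild.haldane_cm(-0.1)


class TestSexMap:
    def test_symmetric_sexes_give_equal_maps(self):
        rng = np.random.default_rng(1)
        pos = np.sort(rng.choice(10_000_000, 100, replace=False)) + 1
        orig = simulate.simulate_gamete_origins(
            200, simulate.ChromosomeCrossover(0.8), pos, 10_000_000, rng
        )
        phase = np.zeros(100, dtype=np.int8)
        recs = [
            MeiosisRecord("pf", "F", [], orig[:100], phase),
            MeiosisRecord("pm", "M", [], orig[:100], phase),
        ]
        cm_f = mapbuild.build_chrom_map([recs[0]], pos)
        cm_m = mapbuild.build_chrom_map([recs[1]], pos)
        cm_a = mapbuild.build_chrom_map(recs, pos)
        assert np.allclose(cm_f, cm_m)
        assert np.allclose(cm_f, cm_a)

    def test_min_snps_rule_drops_small_maps(self, toy_panel):
        genome, panel, _ = toy_panel
        model = simulate.default_crossover_model(genome)
        gd, _ = simulate.simulate_pedigree_genotypes(
            genome, panel, model,
            simulate.PedigreeSpec(6, 3, 0.0, 0.0, 0.0), seed=2,
        )
        sexmap = hm.build_sex_map(gd, min_snps=300)
        assert sexmap.empty  # every chromosome has exactly 300 markers
        sexmap = hm.build_sex_map(gd, min_snps=299)
        assert set(sexmap["chrom"]) == set(genome.names)

    def test_monotone_and_pooled_between_sexes(self, toy_dataset):
        *_, gd, truth = toy_dataset
        sexmap = hm.build_sex_map(gd, min_snps=70)
        assert not sexmap.empty
        for chrom, sub in sexmap.groupby("chrom"):
            for col in ("cM_avg", "cM_female", "cM_male"):
                assert sub[col].iloc[0] == 0
                assert (np.diff(sub[col]) >= -1e-9).all()
            F, M, A = (
                sub["cM_female"].iloc[-1],
                sub["cM_male"].iloc[-1],
                sub["cM_avg"].iloc[-1],
            )
            assert min(F, M) - 1e-9 <= A <= max(F, M) + 1e-9


class TestContigOrder:
    def test_sorted_by_mean_cm_with_orientation(self):
        df = pd.DataFrame(
            {
                "contig": ["c1"] * 3 + ["c2"] * 3 + ["c3"] * 3 + ["c4"] * 2,
                "pos_bp": [10, 20, 30] * 3 + [10, 20],
                "cm": [39, 40, 41, 4, 5, 6, 23, 22, 21, 0, 1],
            }
        )
        order = mapbuild.order_contigs_by_map(df, min_markers=3)
        assert list(order["contig"]) == ["c2", "c3", "c1"]  # 2-marker c4 excluded
        assert list(order["orientation"]) == ["+", "-", "+"]


class TestEndArtifacts:
    def _map_df(self, cm, pos):
        return pd.DataFrame(
            {
                "chrom": "1",
                "marker": [f"m{i}" for i in range(len(cm))],
                "pos_bp": pos,
                "cM_avg": cm,
                "cM_female": cm,
                "cM_male": cm,
            }
        )

    def test_clean_map_unflagged(self):
        pos = np.arange(1, 101) * 100_000
        cm = np.linspace(0, 50, 100)
        flags = mapbuild.flag_end_artifacts(self._map_df(cm, pos))
        assert flags.empty

    def test_steep_terminal_run_flagged(self):
        pos = list(np.arange(1, 96) * 100_000) + [9_510_000 + i * 10_000 for i in range(5)]
        cm = list(np.linspace(0, 20, 95)) + [22.5, 25, 27.5, 30, 32.5]
        flags = mapbuild.flag_end_artifacts(self._map_df(np.array(cm), np.array(pos)))
        right = flags[(flags["end"] == "right") & (flags["column"] == "cM_avg")]
        assert len(right) == 1
        assert right["n_markers"].iloc[0] == 5

    def test_infinite_threshold_never_flags(self):
        pos = np.arange(1, 11) * 1000
        cm = np.linspace(0, 100, 10)
        flags = mapbuild.flag_end_artifacts(
            self._map_df(cm, pos), cm_per_marker=np.inf
        )
        assert flags.empty
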