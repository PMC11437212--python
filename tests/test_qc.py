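import math

import numpy as np
import pandas as pd
import pytest

from hetmap.core import MISSING, GenotypeData
from hetmap import qc


def _gd(genotypes, fathers=None, mothers=None, chroms=None, positions=None):
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    samples = pd.DataFrame(
        {
            "fid": ["F1"] * n,
            "iid": [f"s{i}" for i in range(n)],
            "father": fathers or ["0"] * n,
            "mother": mothers or ["0"] * n,
            "sex": ["M", "F"] * (n // 2) + ["M"] * (n % 2),
        }
    )
    markers = pd.DataFrame(
        {
            "id": [f"m{j}" for j in range(m)],
            "chrom": chroms or ["1"] * m,
            "pos_bp": positions or list(range(1, m + 1)),
        }
    )
    return GenotypeData(g, samples, markers)


class TestMissingness:
    def test_sample_above_threshold_removed(self):
        g = np.zeros((4, 20), dtype=np.int8)
        g[0, :3] = MISSING  # 15% missing
        out, report = qc.filter_missingness(_gd(g), mind=0.10, geno=0.10)
        assert out.n_samples == 3
        assert "s0" not in set(out.samples["iid"])

    def test_marker_at_exact_threshold_kept(self):
        g = np.zeros((10, 5), dtype=np.int8)
        g[0, 0] = MISSING  # exactly 10% of retained samples
        out, _ = qc.filter_missingness(_gd(g), mind=0.5, geno=0.10)
        assert out.n_markers == 5

    def test_complete_matrix_unchanged(self):
        g = np.ones((4, 6), dtype=np.int8)
        out, report = qc.filter_missingness(_gd(g))
        assert out.n_samples == 4 and out.n_markers == 6

    def test_empty_matrix_rejected(self):
        with pytest.raises(Exception):
            qc.filter_missingness(
                GenotypeData(
                    np.empty((0, 0), dtype=np.int8),
                    pd.DataFrame(columns=["fid", "iid", "father", "mother", "sex"]),
                    pd.DataFrame(columns=["id", "chrom", "pos_bp"]),
                )
            )


class TestMaf:
    def test_monomorphic_removed_and_boundaries(self):
        # 100 founders; three markers: MAF 0, exactly 0.05, 0.045
        g = np.zeros((100, 3), dtype=np.int8)
        g[:10, 1] = 1  # 10 heterozygotes -> MAF 0.05
        g[:9, 2] = 1  # MAF 0.045
        out, n_removed = qc.filter_maf(_gd(g), maf=0.05)
        assert n_removed == 2
        assert list(out.markers["id"]) == ["m1"]

    def test_maf_uses_founders_only(self):
        # founders monomorphic; offspring (non-founders) carry alternates
        g = np.zeros((4, 1), dtype=np.int8)
        g[2:, 0] = 1
        gd = _gd(g, fathers=["0", "0", "s0", "s0"], mothers=["0", "0", "s1", "s1"])
        out, n_removed = qc.filter_maf(gd, maf=0.05)
        assert n_removed == 1


class TestHweExact:
    def test_extreme_heterozygote_excess(self):
        assert qc.hwe_exact_test(0, 100, 0) < 1e-6

    def test_modal_configuration_has_large_p(self):
        assert qc.hwe_exact_test(25, 50, 25) >= 0.5

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            qc.hwe_exact_test(0, 0, 0)

    def test_z_exempt_partition(self):
        g = np.zeros((4, 3), dtype=np.int8)
        gd = _gd(g, chroms=["1", "Z", "2"])
        auto, sex = qc.exempt_sex_chromosome(gd)
        assert list(auto) == [True, False, True]
        assert list(sex) == [False, True, False]


class TestMendel:
    def test_impossible_transmission_counted(self):
        # parents AA x AA (dosage 0), offspring Aa (dosage 1)
        g = np.array([[0], [0], [1]], dtype=np.int8)
        gd = _gd(g, fathers=["0", "0", "s0"], mothers=["0", "0", "s1"])
        n_err, n_test, trios = qc.mendel_errors(gd)
        assert n_err[0] == 1 and n_test[0] == 1

    def test_variant_above_fraction_removed(self):
        # 10 trios; marker 0 errs in 2 trios (0.2 > 0.1), marker 1 in none
        rows = []
        g = []
        for t in range(10):
            g += [[0, 0], [0, 0], [1 if t < 2 else 0, 0]]
            rows += [
                (f"f{t}a", "0", "0"),
                (f"f{t}b", "0", "0"),
                (f"f{t}o", f"f{t}a", f"f{t}b"),
            ]
        samples = pd.DataFrame(
            [(iid, fa, mo) for iid, fa, mo in rows],
            columns=["iid", "father", "mother"],
        ).assign(fid="F", sex="M")
        gd = GenotypeData(
            np.asarray(g, dtype=np.int8),
            samples[["fid", "iid", "father", "mother", "sex"]],
            pd.DataFrame({"id": ["m0", "m1"], "chrom": "1", "pos_bp": [1, 2]}),
        )
        out, _ = qc.mendel_filter(gd, per_trio=1.0, per_variant=0.10)
        assert list(out.markers["id"]) == ["m1"]
        assert out.n_samples == 30  # per_trio = 1.0 never removes samples

    def test_error_free_data_untouched(self, toy_dataset):
        *_, gd, _ = toy_dataset
        out, report = qc.mendel_filter(gd)
        assert out.n_markers == gd.n_markers and out.n_samples == gd.n_samples


class TestDedupe:
    def test_lower_missingness_kept(self):
        g = np.zeros((10, 2), dtype=np.int8)
        g[:5, 1] = MISSING
        gd = _gd(g, positions=[100, 100])
        out, n = qc.dedupe_markers(gd)
        assert n == 1 and list(out.markers["id"]) == ["m0"]

    def test_tie_keeps_later_listed(self):
        g = np.zeros((10, 2), dtype=np.int8)
        gd = _gd(g, positions=[100, 100])
        out, _ = qc.dedupe_markers(gd)
        assert list(out.markers["id"]) == ["m1"]

    def test_no_duplicates_identity(self):
        g = np.zeros((4, 3), dtype=np.int8)
        out, n = qc.dedupe_markers(_gd(g))
        assert n == 0 and out.n_markers == 3


def test_full_chain_exempts_z_and_is_idempotent():
    rng = np.random.default_rng(0)
    n = 60
    # marker 0: autosomal, all het (HWE violation); marker 1: Z, all het;
    # marker 2: well-behaved autosomal
    g = np.empty((n, 3), dtype=np.int8)
    g[:, 0] = 1
    g[:, 1] = 1
    g[:, 2] = rng.binomial(2, 0.4, size=n)
    gd = _gd(g.astype(np.int8), chroms=["1", "Z", "2"], positions=[10, 20, 30])
    out, report = qc.run_qc(gd)
    assert "m0" not in set(out.markers["id"])  # autosomal HWE violation removed
    assert "m1" in set(out.markers["id"])  # Z exempt from HWE
    out2, _ = qc.run_qc(out)
    assert out2.n_markers == out.n_markers and out2.n_samples == out.n_samples
    assert np.array_equal(out2.genotypes, out.genotypes)
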