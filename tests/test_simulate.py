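import numpy as np
import pytest
from scipy.stats import kstest

from vtet.core import fisher_exact
from vtet.simulate import (
    NoiseModel,
    SimulationConfig,
    case_frequency,
    estimate_power,
    ideal_test,
    place_cnv,
    simulate_genotypes,
    simulate_intensities,
    simulate_study,
)


class TestCaseFrequency:
    def test_null_odds_ratio(self):
        assert case_frequency(0.01, 1.0) == pytest.approx(0.01)

    def test_printed_formula_arithmetic(self):
        assert case_frequency(0.01, 3.0) == pytest.approx(0.03 / 1.02)

    def test_zero_frequency(self):
        assert case_frequency(0.0, 5.0) == 0.0

    def test_enrichment_iff_or_above_one(self):
        assert case_frequency(0.05, 2.0) > 0.05
        assert case_frequency(0.05, 0.5) < 0.05


class TestPlacement:
    def test_forced_placement(self, rng):
        assert place_cnv(5, 5, "random", rng) == (1, 5)
        assert place_cnv(5, 5, "recurrent", rng) == (1, 5)

    def test_random_starts_uniform(self, rng):
        starts = np.array(
            [place_cnv(20, 5, "random", rng)[0] for _ in range(100_000)]
        )
        counts = np.bincount(starts, minlength=17)[1:]
        freqs = counts / 100_000
        assert np.all(np.abs(freqs - 1 / 16) < 0.005)

    def test_recurrent_shared_boundaries(self, rng):
        ivs = {place_cnv(20, 5, "recurrent", rng) for _ in range(50)}
        assert len(ivs) == 1

    def test_recurrent_in_study_all_carriers_identical(self):
        cfg = SimulationConfig(m=100, n=100, T=20, cnv_len=5, f=0.3,
                               placement="recurrent", seed=4)
        _, _, truth = simulate_study(cfg)
        ivs = {tuple(iv) for iv in truth.interval[truth.carrier]}
        assert len(ivs) == 1


class TestGenotypes:
    def test_zero_maf_all_reference(self, rng):
        hap = simulate_genotypes(100, 0.0, rng)
        assert not hap.any()

    def test_hwe_heterozygote_rate(self, rng):
        hap = simulate_genotypes(100_000, 0.5, rng)
        het = np.mean(hap[0] != hap[1])
        assert het == pytest.approx(0.5, abs=0.01)

    def test_seed_determinism(self):
        h1 = simulate_genotypes(50, 0.3, np.random.default_rng(8))
        h2 = simulate_genotypes(50, 0.3, np.random.default_rng(8))
        np.testing.assert_array_equal(h1, h2)


class TestIntensities:
    """Self-consistency of the conditional LRR/BAF distributions."""

    N = 10_000

    @pytest.fixture()
    def noise(self):
        return NoiseModel()

    def _probes(self, rng, c, maf=0.4):
        hap = np.vstack([rng.random(self.N) < maf, rng.random(self.N) < maf])
        return simulate_intensities(np.full(self.N, c), hap, 0, NoiseModel(), rng)

    def test_cn2_standardized_lrr_standard_normal(self, rng, noise):
        lrr, _ = self._probes(rng, 2)
        x = (lrr - noise.mu[2]) / noise.sigma[2]
        assert kstest(x, "norm").pvalue > 0.01

    def test_cn1_mean_standardized_shift(self, rng, noise):
        lrr, _ = self._probes(rng, 1)
        x = (lrr - noise.mu[2]) / noise.sigma[2]
        expected = (noise.mu[1] - noise.mu[2]) / noise.sigma[2]  # -2.8125
        assert x.mean() == pytest.approx(expected, abs=0.06)
        assert expected == pytest.approx(-2.8125)

    def test_cn3_mean_standardized_shift(self, rng, noise):
        lrr, _ = self._probes(rng, 3)
        x = (lrr - noise.mu[2]) / noise.sigma[2]
        assert x.mean() == pytest.approx(noise.mu[3] / noise.sigma[2], abs=0.06)

    def test_cn0_baf_uniform(self, rng):
        _, baf = self._probes(rng, 0)
        assert kstest(baf, "uniform").pvalue > 0.01

    def test_heterozygote_baf_centers(self, rng, noise):
        """AB ~ N(1/2, eta2); AAB mean ~ 1/3; ABB mean ~ 2/3."""
        hap_a = np.zeros(self.N, dtype=bool)
        hap_b = np.ones(self.N, dtype=bool)
        hap = np.vstack([hap_a, hap_b])
        _, baf2 = simulate_intensities(np.full(self.N, 2), hap, 0, noise, rng)
        assert kstest((baf2 - 0.5) / noise.eta2, "norm").pvalue > 0.01
        # duplicating the A haplotype -> AAB; the B haplotype -> ABB
        _, baf_aab = simulate_intensities(np.full(self.N, 3), hap, 0, noise, rng)
        _, baf_abb = simulate_intensities(np.full(self.N, 3), hap, 1, noise, rng)
        assert baf_aab.mean() == pytest.approx(1 / 3, abs=0.005)
        assert baf_abb.mean() == pytest.approx(2 / 3, abs=0.005)

    def test_homozygote_baf_point_mass_and_fold(self, rng, noise):
        hap = np.zeros((2, self.N), dtype=bool)  # AA
        _, baf = simulate_intensities(np.full(self.N, 2), hap, 0, noise, rng)
        at_zero = np.mean(baf == 0.0)
        assert at_zero == pytest.approx(0.5, abs=0.02)
        tail = baf[baf > 0]
        # continuous part is |N(0, eta1)| (clipping at 1 never binds)
        assert kstest(tail / noise.eta1, _halfnorm_cdf).pvalue > 0.01

    def test_cn1_retained_haplotype_is_homozygous(self, rng, noise):
        hap = np.vstack([np.zeros(self.N, bool), np.ones(self.N, bool)])
        _, baf = simulate_intensities(np.full(self.N, 1), hap, 0, noise, rng)
        assert np.mean(baf < 0.1) > 0.95  # retained A haplotype


def _halfnorm_cdf(x):
    from scipy.stats import halfnorm

    return halfnorm.cdf(x)


class TestSimulateStudy:
    def test_null_design_equal_rates(self):
        cfg = SimulationConfig(m=5000, n=5000, T=10, cnv_len=3, f=0.05, OR=1.0,
                               seed=13)
        _, pheno, truth = simulate_study(cfg)
        case = pheno.label == "case"
        r_case = truth.carrier[case].mean()
        r_ctrl = truth.carrier[~case].mean()
        assert abs(r_case - r_ctrl) < 0.015

    def test_zero_frequency_all_diploid(self):
        cfg = SimulationConfig(m=50, n=50, T=10, cnv_len=3, f=0.0, seed=1)
        _, _, truth = simulate_study(cfg)
        assert not truth.carrier.any()
        assert np.all(truth.copy_number == 2)

    def test_expected_carrier_counts(self):
        """m = n = 1000, f = 0.01, OR = 3 -> ~29.4 case, 10 control carriers."""
        cases, ctrls = 0, 0
        reps = 50
        for s in range(reps):
            cfg = SimulationConfig(m=1000, n=1000, T=10, cnv_len=3, f=0.01,
                                   OR=3.0, seed=1000 + s)
            _, pheno, truth = simulate_study(cfg)
            case = pheno.label == "case"
            cases += truth.carrier[case].sum()
            ctrls += truth.carrier[~case].sum()
        assert cases / reps == pytest.approx(1000 * case_frequency(0.01, 3.0), rel=0.15)
        assert ctrls / reps == pytest.approx(10.0, rel=0.15)

    def test_carrier_intervals_cover_cnv_len(self):
        cfg = SimulationConfig(m=100, n=100, T=20, cnv_len=6, f=0.3, seed=3)
        _, _, truth = simulate_study(cfg)
        for i in np.flatnonzero(truth.carrier):
            a, b = truth.interval[i]
            assert b - a + 1 == 6
            assert np.all(truth.copy_number[i, a - 1 : b] != 2)

    def test_round_trips_through_io(self, tmp_path):
        from vtet.io import read_intensity, write_intensity

        cfg = SimulationConfig(m=5, n=5, T=8, cnv_len=3, f=0.3, seed=2)
        matrix, _, _ = simulate_study(cfg)
        write_intensity(matrix, tmp_path / "l.tsv", tmp_path / "b.tsv",
                        tmp_path / "p.tsv")
        back = read_intensity(tmp_path / "l.tsv", tmp_path / "b.tsv",
                              tmp_path / "p.tsv")
        np.testing.assert_array_equal(back.lrr, matrix.lrr)
        np.testing.assert_array_equal(back.baf, matrix.baf)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            SimulationConfig(cnv_len=2, L=3)
        with pytest.raises(ValueError):
            SimulationConfig(f=1.5)


class TestIdealTest:
    def test_no_carriers_p_one(self):
        cfg = SimulationConfig(m=20, n=20, T=10, cnv_len=3, f=0.0, seed=0)
        _, pheno, truth = simulate_study(cfg)
        assert ideal_test(truth, pheno) == 1.0

    def test_equals_fisher_on_true_counts(self):
        cfg = SimulationConfig(m=200, n=200, T=10, cnv_len=3, f=0.1, OR=3.0,
                               seed=5)
        _, pheno, truth = simulate_study(cfg)
        case = pheno.label == "case"
        a = int((truth.carrier & case).sum())
        b = int((truth.carrier & ~case).sum())
        assert ideal_test(truth, pheno) == fisher_exact(a, b, 200, 200)


class TestEstimatePower:
    def test_null_size_near_alpha_for_ideal(self):
        cfg = SimulationConfig(m=200, n=200, T=10, cnv_len=3, f=0.05, OR=1.0)
        out = estimate_power(cfg, 200, alpha=0.05, methods=("ideal",), seed=21)
        power, se = out["ideal"]
        # Fisher is conservative on discrete tables: size <= alpha + MC noise
        assert power <= 0.05 + 3 * max(se, 0.02)

    def test_power_increases_with_odds_ratio(self):
        powers = []
        for OR in (1.0, 5.0):
            cfg = SimulationConfig(m=500, n=500, T=20, cnv_len=5, f=0.01, OR=OR,
                                   cnv_type="CN1")
            powers.append(
                estimate_power(cfg, 60, alpha=0.01, methods=("vtet",), seed=31)[
                    "vtet"
                ][0]
            )
        assert powers[1] > powers[0] + 0.3


class TestHaplotypePool:
    def test_pool_haplotypes_are_used(self):
        pool = np.zeros((4, 10), dtype=bool)
        pool[:, 0] = True  # fixed B allele at probe 0 in every haplotype
        cfg = SimulationConfig(m=50, n=50, T=10, cnv_len=3, f=0.0,
                               haplotype_pool=pool, seed=6)
        matrix, _, _ = simulate_study(cfg)
        # BB homozygote at probe 0 for everyone: BAF clusters at 1
        assert np.mean(matrix.baf[:, 0] > 0.9) > 0.99

    def test_load_round_trip(self, tmp_path):
        from vtet.simulate import load_haplotype_pool

        path = tmp_path / "pool.tsv"
        np.savetxt(path, np.eye(4, dtype=int), fmt="%d", delimiter="\t")
        pool = load_haplotype_pool(path)
        np.testing.assert_array_equal(pool, np.eye(4, dtype=bool))

    def test_bad_pool_shape_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(T=10, haplotype_pool=np.zeros((2, 5), dtype=bool))
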