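"""Simulator: determinism, Poisson consistency, and the linkage mechanism."""

import math

import numpy as np
import pytest
from scipy import stats

import ddcnv
from ddcnv.pipeline import simulate_and_quantify
from ddcnv.sim import NtcConfig, SimConfig, simulate_well_arrays


class TestSimulateWell:
    def test_cn_zero_gives_no_target_positives(self):
        cfg = SimConfig(n_droplets=5000, true_cn=0.0, seed=3)
        fam, hex_, truth = simulate_well_arrays(cfg)
        assert truth.n_target_positive == 0
        # all FAM amplitudes from the negative cluster (< midpoint)
        assert fam.max() < (cfg.fam_model.negative_mean + cfg.fam_model.positive_mean) / 2

    def test_negative_fraction_matches_poisson_zero_probability(self):
        # lambda_target = 0.5 * 6 / 2 = 1.5; P(negative) = exp(-1.5).
        cfg = SimConfig(n_droplets=20000, lambda_ref=0.5, true_cn=6.0, seed=12345)
        _, _, truth = simulate_well_arrays(cfg)
        p = math.exp(-1.5)
        # 99.9% binomial band around the expected negative fraction
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 20000, p)
        n_negative = cfg.n_droplets - truth.n_target_positive
        assert lo <= n_negative <= hi

    def test_determinism_same_seed_identical_output(self):
        cfg = SimConfig(n_droplets=3000, seed=99)
        fam1, hex1, t1 = simulate_well_arrays(cfg)
        fam2, hex2, t2 = simulate_well_arrays(cfg)
        np.testing.assert_array_equal(fam1, fam2)
        np.testing.assert_array_equal(hex1, hex2)
        assert t1 == t2

    def test_invalid_config_rejected_before_sampling(self):
        with pytest.raises(ValueError):
            SimConfig(n_droplets=0)
        with pytest.raises(ValueError):
            SimConfig(rain_fraction=1.0)
        with pytest.raises(ValueError):
            SimConfig(linkage_fraction=1.5)
        with pytest.raises(ValueError):
            SimConfig(lambda_ref=0.0)

    def test_rain_droplets_fall_between_cluster_means(self):
        cfg = SimConfig(n_droplets=20000, rain_fraction=0.2, seed=5)
        fam, _, truth = simulate_well_arrays(cfg)
        assert truth.n_rain_fam > 0
        # Rain count ~ Binomial(n, 0.2); check a generous band.
        assert abs(truth.n_rain_fam / cfg.n_droplets - 0.2) < 0.02


class TestPoissonConsistency:
    def test_observed_negative_fraction_converges_to_exp_minus_lambda(self):
        """Over >= 1e6 droplets the negative fraction matches exp(-lambda)
        within 4 standard errors on both channels."""
        n_wells, n_droplets = 50, 20000
        cfg0 = SimConfig(n_droplets=n_droplets, lambda_ref=0.5, true_cn=6.0)
        lam_t, lam_r = cfg0.lambda_target_effective, cfg0.lambda_ref
        neg_t = neg_r = 0
        total = n_wells * n_droplets
        for seed in ddcnv.spawn_seeds(2024, n_wells):
            _, _, truth = simulate_well_arrays(
                SimConfig(n_droplets=n_droplets, lambda_ref=0.5, true_cn=6.0, seed=seed)
            )
            neg_t += n_droplets - truth.n_target_positive
            neg_r += n_droplets - truth.n_ref_positive
        for lam, neg in ((lam_t, neg_t), (lam_r, neg_r)):
            p = math.exp(-lam)
            se = math.sqrt(p * (1 - p) / total)
            assert abs(neg / total - p) < 4 * se


class TestLinkage:
    def test_effective_rate_under_full_linkage(self):
        cfg = SimConfig(lambda_ref=0.5, true_cn=6.0, linkage_fraction=1.0)
        assert cfg.lambda_target_effective == pytest.approx(cfg.lambda_ref)

    def test_mean_estimate_non_increasing_in_linkage(self):
        """Undigested tandem copies co-partition, so the CN estimate can
        only fall as the linked fraction grows."""
        means = []
        for L in (0.0, 0.5, 1.0):
            ests = [
                simulate_and_quantify(
                    SimConfig(n_droplets=10000, true_cn=6.0,
                              linkage_fraction=L, seed=s)
                ).cn_estimate
                for s in ddcnv.spawn_seeds(int(L * 10) + 17, 20)
            ]
            means.append(np.mean(ests))
        assert means[0] > means[1] > means[2]
        assert means[0] == pytest.approx(6.0, rel=0.05)


class TestSimulatePlate:
    def test_plate_includes_ntc_with_zero_positives(self):
        configs = {"A01": SimConfig(n_droplets=2000, seed=1),
                   "A02": SimConfig(n_droplets=2000, seed=2)}
        amplitudes, plate, truths = ddcnv.simulate_plate(
            configs, include_ntc=True, ntc_config=NtcConfig(n_droplets=2000, seed=3)
        )
        assert set(amplitudes) == {"A01", "A02", "H12"}
        assert plate["H12"].is_ntc
        assert set(truths) == {"A01", "A02"}
        t = ddcnv.default_sim_thresholds(configs["A01"])
        counts = ddcnv.assign_clusters(amplitudes["H12"], t)
        assert counts.n_nn == 2000  # no false positives by default

    def test_duplicate_well_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ddcnv.simulate_plate({"A01": SimConfig(seed=1), "A1": SimConfig(seed=2)})

    def test_same_seed_twice_bit_identical(self):
        configs = {"A01": SimConfig(n_droplets=1000, seed=42)}
        a1, _, _ = ddcnv.simulate_plate(configs, include_ntc=False)
        a2, _, _ = ddcnv.simulate_plate(configs, include_ntc=False)
        assert a1 == a2
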