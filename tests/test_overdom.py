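"""Overdominance trajectories, structured coalescent and statistics."""

import numpy as np
import pytest
from scipy import stats

from paleodel import overdom as od


class TestFitness:
    def test_overdominant_parameterization(self):
        assert od.genotype_fitness(0.005, 10) == (1.0, 1.05, 1.005)

    def test_codominance_halves_the_benefit(self):
        w = od.genotype_fitness(0.005, 0.5)
        assert w[1] == pytest.approx(1.0025)
        assert not od.FitnessModel(s=0.005, h=0.5).is_overdominant

    def test_neutrality(self):
        assert od.genotype_fitness(0.0, 10) == (1.0, 1.0, 1.0)

    def test_equilibrium_formula(self):
        assert od.FitnessModel(s=0.005, h=10).equilibrium \
            == pytest.approx(10 / 19)
        assert np.isnan(od.FitnessModel(s=0.01, h=0.5).equilibrium)


class TestTrajectories:
    def test_seeded_reproducibility(self):
        fit = od.FitnessModel(s=0.005, h=10)
        a = od.simulate_trajectory(1000, fit, 500, seed=5)
        b = od.simulate_trajectory(1000, fit, 500, seed=5)
        assert np.array_equal(a.freqs, b.freqs)
        assert a.attempts == b.attempts

    def test_conditioned_path_stays_interior(self):
        traj = od.simulate_trajectory(500, od.FitnessModel(), 400, seed=2)
        assert traj.freqs[0] == pytest.approx(1 / 1000)
        assert (traj.freqs > 0).all() and (traj.freqs < 1).all()
        assert traj.age_gens == 400

    def test_overdominant_equilibrium_reached(self):
        fit = od.FitnessModel(s=0.005, h=10)
        trajs = od.sample_trajectories(15, 10_000, fit, 4000, seed=9)
        late = np.mean([t.freqs[-500:].mean() for t in trajs])
        assert late == pytest.approx(10 / 19, abs=0.06)

    def test_neutral_wf_step_is_mean_preserving(self):
        rng = np.random.default_rng(3)
        p = np.full(40_000, 0.3)
        stepped = od._wf_step(p, od.genotype_fitness(0.0, 0.0), 2000, rng)
        t = stats.ttest_1samp(stepped - p, 0.0)
        assert t.pvalue > 0.01

    def test_budget_exhaustion_reports_acceptance(self):
        with pytest.raises(od.RejectionBudgetError, match="acceptance rate"):
            od.simulate_trajectory(500, od.FitnessModel(s=-0.5, h=0.0),
                                   2000, seed=1, max_attempts=200)

    def test_final_band_filter(self):
        fit = od.FitnessModel(s=0.005, h=10)
        traj = od.simulate_trajectory(1000, fit, 2000, seed=4,
                                      final_freq_band=(0.44, 0.56))
        assert 0.44 <= traj.freqs[-1] <= 0.56


class TestTrajectoryVariability:
    def test_constant_trajectory_zero(self):
        traj = od.Trajectory(freqs=np.full(500, 0.5), n_diploid=1000,
                             fitness=od.FitnessModel())
        assert od.trajectory_variability([traj], window=100)[0] == 0.0

    def test_nonnegative_and_window_guard(self):
        traj = od.simulate_trajectory(500, od.FitnessModel(s=0.005, h=10),
                                      300, seed=1)
        assert od.trajectory_variability([traj], window=100)[0] >= 0
        with pytest.raises(ValueError):
            od.trajectory_variability([traj], window=1000)

    def test_overdominant_more_stable_than_neutral(self):
        # matched present-day frequency band; the balanced allele sits at
        # its equilibrium while neutral alleles keep drifting
        band = (0.4, 0.6)
        ov = od.sample_trajectories(30, 400, od.FitnessModel(s=0.005, h=10),
                                    1200, seed=31, final_freq_band=band)
        ne = od.sample_trajectories(30, 400, od.FitnessModel(), 1200,
                                    seed=32, final_freq_band=band)
        var_o = od.trajectory_variability(ov, window=400)
        var_n = od.trajectory_variability(ne, window=400)
        assert np.median(var_o) < np.median(var_n)
        assert stats.mannwhitneyu(var_o, var_n).pvalue < 0.01


class TestStructuredCoalescent:
    def test_neutral_limit_recovers_theta(self):
        n_dip = 10_000
        traj = od.Trajectory(freqs=np.full(20 * 2 * n_dip + 1,
                                           1 - 1 / (2 * n_dip)),
                             n_diploid=n_dip, fitness=od.FitnessModel())
        pis = []
        for i in range(200):
            s = od.structured_coalescent_sample(traj, n=20, theta=5.0,
                                                rho=0.0, seed=i, n_derived=20)
            pis.append(od.summary_stats(s).pi)
        se = np.std(pis) / np.sqrt(len(pis))
        assert abs(np.mean(pis) - 5.0) < 2 * se + 0.05

    def test_no_recombination_keeps_classes_separate(self):
        # with rho=0 a site is either inside one allelic class or
        # contains the whole derived class (mutations above the origin)
        traj = od.Trajectory(freqs=np.full(8001, 0.5), n_diploid=500,
                             fitness=od.FitnessModel())
        sample = od.structured_coalescent_sample(traj, n=24, theta=8.0,
                                                 rho=0.0, seed=42,
                                                 n_derived=12)
        focal = sample.matrix[:, sample.focal_index].astype(bool)
        for j in range(sample.n_sites):
            carriers = sample.matrix[:, j].astype(bool)
            inside_derived = not np.any(carriers & ~focal)
            inside_ancestral = not np.any(carriers & focal)
            contains_derived = bool(np.all(carriers[focal]))
            assert inside_derived or inside_ancestral or contains_derived

    def test_seeded_reproducibility(self):
        traj = od.Trajectory(freqs=np.linspace(1 / 1000, 0.5, 2001),
                             n_diploid=500, fitness=od.FitnessModel())
        a = od.structured_coalescent_sample(traj, 12, 5.0, 2.0, seed=3)
        b = od.structured_coalescent_sample(traj, 12, 5.0, 2.0, seed=3)
        assert np.array_equal(a.matrix, b.matrix)
        assert a.focal_index == b.focal_index

    def test_malformed_trajectory_rejected(self):
        freqs = np.linspace(1 / 1000, 0.5, 101)
        freqs[50] = 0.0
        traj = od.Trajectory(freqs=freqs, n_diploid=500,
                             fitness=od.FitnessModel())
        with pytest.raises(ValueError, match="malformed trajectory"):
            od.structured_coalescent_sample(traj, 12, 5.0, 0.0, seed=1)


class TestPseCoal:
    def test_focal_site_in_requested_count_range(self):
        for seed in range(5):
            sample = od.psecoal_sample(n=50, count_range=(22, 28),
                                       theta=10.0, seed=seed)
            count = sample.derived_counts[sample.focal_index]
            assert 22 <= count <= 28
            assert 0.44 <= count / 50 <= 0.56

    def test_wide_range_accepts_immediately(self):
        sample = od.psecoal_sample(n=20, count_range=(1, 19), theta=8.0,
                                   seed=1)
        assert sample.focal_index is not None

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            od.psecoal_sample(n=10, count_range=(0, 5), theta=1.0, seed=1)

    def test_seeded_reproducibility(self):
        a = od.psecoal_sample(n=30, theta=6.0, seed=11, count_range=(10, 20))
        b = od.psecoal_sample(n=30, theta=6.0, seed=11, count_range=(10, 20))
        assert np.array_equal(a.matrix, b.matrix)

    def test_fay_wu_h_centred_under_neutrality(self):
        hs = []
        for seed in range(400):
            sample = od.psecoal_sample(n=20, theta=3.0, seed=seed,
                                       condition=False)
            h = od.summary_stats(sample).fay_wu_h
            if not np.isnan(h):
                hs.append(h)
        se = np.std(hs) / np.sqrt(len(hs))
        assert abs(np.mean(hs)) < 2 * se + 0.02


from _oracles import brute_force_stats as _brute_force_stats  # noqa: E402


class TestSummaryStats:
    def test_matches_brute_force_on_random_samples(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = int(rng.integers(4, 9))
            s = int(rng.integers(1, 11))
            mat = rng.integers(0, 2, size=(n, s)).astype(np.uint8)
            got = od.summary_stats(od.HaplotypeSample(matrix=mat))
            s_bf, tw, pi, h, k, dvh, zns = _brute_force_stats(mat)
            assert got.s == s_bf
            assert got.dvk == k
            assert got.theta_w == pytest.approx(tw, abs=1e-12)
            assert got.pi == pytest.approx(pi, abs=1e-12)
            assert got.fay_wu_h == pytest.approx(h, abs=1e-12)
            assert got.dvh == pytest.approx(dvh, abs=1e-12)
            if zns is not None:
                assert got.zns == pytest.approx(zns, abs=1e-12)

    def test_single_singleton_site(self):
        n = 10
        mat = np.zeros((n, 1), dtype=np.uint8)
        mat[0, 0] = 1
        got = od.summary_stats(od.HaplotypeSample(matrix=mat))
        assert got.pi == pytest.approx(2 / n * (n - 1) / (n - 1))
        assert got.tajimas_d < 0

    def test_perfectly_correlated_sites_zns_one(self):
        mat = np.array([[1, 1], [1, 1], [0, 0], [0, 0]], dtype=np.uint8)
        assert od.summary_stats(od.HaplotypeSample(matrix=mat)).zns \
            == pytest.approx(1.0)
        comp = mat.copy()
        comp[:, 1] = 1 - comp[:, 1]
        assert od.summary_stats(od.HaplotypeSample(matrix=comp)).zns \
            == pytest.approx(1.0)

    def test_monomorphic_sample_markers(self):
        got = od.summary_stats(od.HaplotypeSample(
            matrix=np.zeros((6, 0), dtype=np.uint8)))
        assert got.s == 0 and got.pi == 0.0
        assert np.isnan(got.tajimas_d) and np.isnan(got.zns)
        assert got.dvk == 1 and got.dvh == 0.0


class TestPcaSeparation:
    @staticmethod
    def _panel(seed, shift=0.0, n=40):
        rng = np.random.default_rng(seed)
        import pandas as pd
        return pd.DataFrame({
            "S": rng.poisson(20, n) + shift,
            "pi": rng.gamma(5, 1, n) + shift,
            "tajimas_d": rng.normal(0, 1, n) + shift,
            "zns": rng.beta(2, 5, n),
        })

    def test_identical_scenarios_do_not_separate(self):
        report = od.pca_separation({"a": self._panel(1), "b": self._panel(2)})
        assert not report.any_statistic_separates(alpha=0.05)
        assert report.pc_overlap["PC1"] > 0.8

    def test_shifted_scenario_detected(self):
        report = od.pca_separation({"a": self._panel(1),
                                    "b": self._panel(2, shift=3.0)})
        assert report.any_statistic_separates(alpha=0.05)

    def test_report_serializable_and_reproducible(self):
        rep1 = od.pca_separation({"a": self._panel(1), "b": self._panel(2)})
        rep2 = od.pca_separation({"a": self._panel(1), "b": self._panel(2)})
        assert rep1.to_dict() == rep2.to_dict()
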