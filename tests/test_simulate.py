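import numpy as np
import pytest
from scipy import stats

from mmcoal.genealogy import SamplingSchedule, sufficient_stats
from mmcoal.measures import (
    KingmanMeasure,
    RateTable,
    StarMeasure,
    beta_measure,
    block_size_pmf,
)
from mmcoal.simulate import (
    PiecewiseNe,
    SimulationSpec,
    average_block_size,
    simulate,
    study_schedule,
    trajectory,
)


class TestPiecewiseNe:
    def test_constant_hazard_inversion(self):
        ne = PiecewiseNe.constant(10.0)
        # rate * (t - t0) / Ne = target  =>  t = t0 + target * Ne / rate
        assert ne.solve_hazard(1.0, 2.0, 0.6) == pytest.approx(1.0 + 0.6 * 10.0 / 2.0)

    def test_piecewise_inversion_crosses_cells(self):
        ne = PiecewiseNe(np.array([0.0, 1.0, 2.0]), np.array([1.0, 2.0]))
        # hazard 1 on [0,1), 0.5 on [1,2): target 1.25 at rate 1 -> t = 1.5
        assert ne.solve_hazard(0.0, 1.0, 1.25) == pytest.approx(1.5)

    def test_callable_extension(self):
        ne = PiecewiseNe.from_callable(lambda t: 10.0, horizon=1.0, cells=4)
        t = ne.solve_hazard(0.0, 1.0, 0.5)  # needs integration far past horizon
        assert t == pytest.approx(5.0, rel=1e-6)

    def test_cumulative_matches_solve(self):
        ne, _ = trajectory("boombust")
        t = ne.solve_hazard(0.3, 2.5, 1.7)
        assert 2.5 * ne.cumulative_inverse(0.3, t) == pytest.approx(1.7, rel=1e-9)


class TestSimulate:
    def test_deterministic_under_seed(self):
        spec = lambda: SimulationSpec(
            beta_measure(1.3), PiecewiseNe.constant(5.0),
            SamplingSchedule.isochronous(12), seed=7,
        )
        _, d1 = simulate(spec())
        _, d2 = simulate(spec())
        assert np.array_equal(d1.t, d2.t)
        assert np.array_equal(d1.m, d2.m)

    def test_kingman_pair_mean_tmrca(self):
        c = 4.0
        times = []
        sched = SamplingSchedule.isochronous(2)
        rt = RateTable(KingmanMeasure(), 2)
        for r in range(3000):
            _, d = simulate(
                SimulationSpec(KingmanMeasure(), PiecewiseNe.constant(c), sched, r),
                rate_table=rt,
            )
            times.append(d.tmrca)
        se = np.std(times) / np.sqrt(len(times))
        assert abs(np.mean(times) - c) < 3 * se

    def test_star_single_event_mean_one(self):
        waits = []
        sched = SamplingSchedule.isochronous(8)
        rt = RateTable(StarMeasure(), 8)
        for r in range(2000):
            _, d = simulate(
                SimulationSpec(StarMeasure(), PiecewiseNe.constant(1.0), sched, r),
                rate_table=rt,
            )
            assert d.K == 1
            assert d.m[0] == 8
            waits.append(d.t[0])
        se = np.std(waits) / np.sqrt(len(waits))
        assert abs(np.mean(waits) - 1.0) < 3 * se

    def test_near_kingman_rarely_multifurcates(self):
        meas = beta_measure(1.999)
        rt = RateTable(meas, 50)
        sched = SamplingSchedule.isochronous(50)
        sizes = []
        for r in range(30):
            _, d = simulate(
                SimulationSpec(meas, PiecewiseNe.constant(1.0), sched, r), rate_table=rt
            )
            sizes.extend(d.m.tolist())
        assert np.mean(np.asarray(sizes) > 2) <= 0.01

    def test_heterochronous_tree_matches_stats(self):
        meas = beta_measure(1.5)
        sched = study_schedule("split4", 40)
        tree, data = simulate(SimulationSpec(meas, PiecewiseNe.constant(20.0), sched, 5))
        extracted = sufficient_stats(tree)
        assert np.allclose(extracted.t, data.t)
        assert np.array_equal(extracted.m, data.m)
        assert np.array_equal(extracted.schedule.n, sched.n)

    def test_hazard_transformed_waits_are_unit_exponential(self):
        # inhomogeneous-time inversion check under a varying trajectory
        meas = beta_measure(1.5)
        rt = RateTable(meas, 6)
        sched = SamplingSchedule.isochronous(6)
        pulls = []
        for r in range(2000):
            ne, _ = trajectory("exponential")
            _, d = simulate(SimulationSpec(meas, ne, sched, r), rate_table=rt)
            prev = 0.0
            a = 6
            for t, m in zip(d.t, d.m):
                lam = rt.total_rate(a)
                pulls.append(lam * ne.cumulative_inverse(prev, t))
                prev = t
                a -= m - 1
        assert stats.kstest(pulls, "expon").pvalue > 0.01

    def test_block_sizes_follow_conditional_pmf(self):
        meas = beta_measure(1.2)
        rt = RateTable(meas, 7)
        sched = SamplingSchedule.isochronous(7)
        first = []
        for r in range(4000):
            _, d = simulate(
                SimulationSpec(meas, PiecewiseNe.constant(1.0), sched, r), rate_table=rt
            )
            first.append(d.m[0])  # block size of the first event (A = 7)
        observed = np.bincount(first, minlength=8)[2:8]
        expected = block_size_pmf(meas, 7) * len(first)
        assert stats.chisquare(observed, expected).pvalue > 0.01

    def test_tmrca_stochastically_longer_for_small_alpha(self):
        # smaller alpha -> smaller total coalescent rate -> longer branches.
        # The effect on the TMRCA is weak (the final pair merges at rate 1
        # for every alpha), so it needs n = 50 and many replicates to show.
        sched = SamplingSchedule.isochronous(50)
        samples = {}
        for alpha in (1.0, 1.5, 1.8):
            meas = beta_measure(alpha)
            rt = RateTable(meas, 50)
            tm = []
            for r in range(1500):
                ne = PiecewiseNe.constant(1.0)
                _, d = simulate(
                    SimulationSpec(meas, ne, sched, int(alpha * 1e6) + r),
                    rate_table=rt,
                )
                tm.append(d.tmrca)
            samples[alpha] = tm
        assert (
            stats.mannwhitneyu(samples[1.0], samples[1.8], alternative="greater").pvalue
            < 0.05
        )
        assert np.mean(samples[1.0]) > np.mean(samples[1.5]) > np.mean(samples[1.8])


class TestAverageBlockSize:
    def test_kingman_exactly_two(self):
        assert average_block_size(KingmanMeasure(), 10, replicates=20) == 2.0

    def test_decreases_towards_two_with_alpha(self):
        low = average_block_size(beta_measure(1.1), 100, replicates=40, seed=1)
        high = average_block_size(beta_measure(1.9), 100, replicates=40, seed=1)
        assert high < low
        assert high < 2.5

    def test_grows_with_n(self):
        # trees with more tips support larger merger blocks, so the average
        # block size grows with n at fixed alpha
        small = average_block_size(beta_measure(1.5), 20, replicates=300, seed=2)
        large = average_block_size(beta_measure(1.5), 100, replicates=300, seed=2)
        assert large > small


class TestStudySchedules:
    def test_iso(self):
        s = study_schedule("iso", 50)
        assert s.L == 1
        assert s.total == 50

    def test_split2_counts(self):
        s = study_schedule("split2", 50)
        assert s.n.tolist() == [25, 25]
        assert s.s == pytest.approx([0.0, 0.2])

    def test_split4_counts(self):
        s = study_schedule("split4", 100)
        assert s.n.tolist() == [50, 30, 10, 10]
        assert s.s == pytest.approx([0.0, 0.2, 0.4, 0.6])

    def test_total_preserved_after_rounding(self):
        for n in (20, 23, 50, 99):
            assert study_schedule("split4", n).total == n
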