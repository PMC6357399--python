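"""Life-table machinery: oracle exactness, microsimulation agreement,
credit conventions and the end-of-life sensitivity adjustment."""

import numpy as np
import pytest

from cohortmslt.mslt import (BaselineDistribution, LifeTableEstimate,
                             end_of_life_adjustment, microsimulate,
                             occupancy_oracle)
from cohortmslt.ppo import TransitionMatrixSet

from conftest import constant_mortality_matrices, random_matrix_set

CLOSED_FORM_Q01 = (1 - 0.05) * (1 - 0.9 ** 10) / 0.1   # 6.187554819


def _nd_baseline():
    w = np.zeros((8, 2))
    w[0, 0] = 1.0
    return BaselineDistribution(weights=w)


def _uniform_baseline(disabled_share=0.2):
    w = np.full((8, 2), 1.0)
    w[:, 1] = disabled_share / (1 - disabled_share)
    return BaselineDistribution(weights=w)


class TestOracle:
    def test_frozen_cohort_spends_whole_window_alive(self):
        M = constant_mortality_matrices(q=0.0)
        est = occupancy_oracle(M, _nd_baseline(), (80, 89))
        assert est.total_le == pytest.approx(10.0, abs=1e-12)
        assert est.dfle == pytest.approx(10.0, abs=1e-12)

    def test_constant_mortality_closed_form_exact(self):
        M = constant_mortality_matrices(q=0.1)
        est = occupancy_oracle(M, _nd_baseline(), (80, 89))
        assert est.total_le == pytest.approx(6.187554819, abs=1e-9)
        assert est.total_le == pytest.approx(CLOSED_FORM_Q01, rel=1e-12)

    def test_death_credit_flag_shifts_occupancy(self):
        M = constant_mortality_matrices(q=0.1)
        full = occupancy_oracle(M, _nd_baseline(), (80, 89), death_credit=1.0)
        none = occupancy_oracle(M, _nd_baseline(), (80, 89), death_credit=0.0)
        half = occupancy_oracle(M, _nd_baseline(), (80, 89), death_credit=0.5)
        assert none.total_le < half.total_le < full.total_le
        assert half.total_le == pytest.approx((none.total_le + full.total_le) / 2,
                                              abs=1e-12)

    def test_profile_permutation_symmetry(self):
        """Permuting profile labels consistently in matrices and baseline
        leaves the estimates unchanged."""
        rng = np.random.default_rng(3)
        M = random_matrix_set(rng)
        w = rng.dirichlet(np.ones(16)).reshape(8, 2)
        base = BaselineDistribution(weights=w)
        est = occupancy_oracle(M, base, (80, 89))
        perm = rng.permutation(8)
        M2 = TransitionMatrixSet(ages=M.ages, probs=M.probs[:, perm])
        base2 = BaselineDistribution(weights=w[perm])
        est2 = occupancy_oracle(M2, base2, (80, 89))
        assert est2.total_le == pytest.approx(est.total_le, abs=1e-12)
        assert est2.dfle == pytest.approx(est.dfle, abs=1e-12)


class TestMicrosimulate:
    def test_frozen_cohort_exact_ten_years(self):
        M = constant_mortality_matrices(q=0.0)
        est = microsimulate(M, _nd_baseline(), (80, 89), n=2000, seed=0)
        assert est.total_le == pytest.approx(10.0, abs=1e-12)
        assert est.dfle == pytest.approx(10.0, abs=1e-12)

    def test_constant_mortality_within_monte_carlo_error(self):
        M = constant_mortality_matrices(q=0.1)
        est = microsimulate(M, _nd_baseline(), (80, 89), n=100_000, seed=1,
                            keep_tallies=True)
        total = est.tallies.nd_credit + est.tallies.dis_credit
        se = total.std() / np.sqrt(len(total))
        assert abs(est.total_le - CLOSED_FORM_Q01) < 3 * se

    def test_accounting_identity_every_run(self):
        rng = np.random.default_rng(9)
        for s in range(5):
            M = random_matrix_set(rng)
            est = microsimulate(M, _uniform_baseline(), (80, 89), n=5000, seed=s)
            assert est.total_le == est.dfle + est.disabled_le
            assert 0 <= est.dfle and 0 <= est.disabled_le
            assert est.total_le <= 10.0 + 1e-9

    def test_dead_is_absorbing_in_simulation(self):
        """With certain death in year one, occupancy stops at the death
        credit: no one returns from the dead."""
        M = constant_mortality_matrices(q=1.0)
        est = microsimulate(M, _nd_baseline(), (80, 89), n=500, seed=2)
        assert est.total_le == pytest.approx(0.5, abs=1e-12)

    def test_seed_reproducibility_and_allocation_modes(self):
        M = constant_mortality_matrices(q=0.2)
        b = _uniform_baseline()
        a1 = microsimulate(M, b, (80, 89), n=10_000, seed=5)
        a2 = microsimulate(M, b, (80, 89), n=10_000, seed=5)
        assert a1.total_le == a2.total_le
        prop = microsimulate(M, b, (80, 89), n=10_000, seed=5,
                             allocation="proportional")
        assert prop.total_le == pytest.approx(a1.total_le, abs=0.05)

    def test_convergence_rate_consistent_with_sqrt_n(self):
        """Monte-Carlo error vs the oracle stays within 3 SE at every n in
        {1e3, 1e4, 1e5}, with SE shrinking as 1/sqrt(n)."""
        rng = np.random.default_rng(11)
        M = random_matrix_set(rng)
        b = _uniform_baseline()
        exact = occupancy_oracle(M, b, (80, 89))
        for n in (1000, 10_000, 100_000):
            est = microsimulate(M, b, (80, 89), n=n, seed=n, keep_tallies=True)
            total = est.tallies.nd_credit + est.tallies.dis_credit
            se = total.std() / np.sqrt(n)
            assert abs(est.total_le - exact.total_le) < 3 * se

    def test_window_not_covered_raises(self):
        M = constant_mortality_matrices(q=0.1, ages=(80, 89))
        with pytest.raises(KeyError):
            microsimulate(M, _nd_baseline(), (80, 95), n=100, seed=0)
        with pytest.raises(ValueError):
            microsimulate(M, _nd_baseline(), (80, 89), n=0, seed=0)


class TestBaselineDistribution:
    def test_from_panel_uses_sampling_weights(self, small_octo_panel):
        b = BaselineDistribution.from_panel(small_octo_panel)
        assert b.weights.sum() == pytest.approx(1.0)
        disabled_share = b.weights[:, 1].sum()
        emp = (small_octo_panel.baseline_state == 1).mean()
        assert disabled_share == pytest.approx(emp, abs=0.05)

    def test_rejects_invalid_mass(self):
        with pytest.raises(ValueError):
            BaselineDistribution(weights=np.zeros((8, 2)))
        with pytest.raises(ValueError):
            BaselineDistribution(weights=-np.ones((8, 2)))


class TestEndOfLifeAdjustment:
    def test_no_deaths_leaves_estimate_unchanged(self):
        M = constant_mortality_matrices(q=0.0)
        est = microsimulate(M, _nd_baseline(), (80, 89), n=1000, seed=0,
                            keep_tallies=True)
        res = end_of_life_adjustment(est, seed=1)
        assert res.adjusted.dfle == res.unadjusted.dfle
        assert res.adjusted.disabled_le == res.unadjusted.disabled_le

    def test_reallocation_conserves_total_exactly(self):
        M = constant_mortality_matrices(q=0.15)
        est = microsimulate(M, _uniform_baseline(), (80, 89), n=20_000, seed=3,
                            keep_tallies=True)
        res = end_of_life_adjustment(est, seed=4)
        assert res.adjusted.total_le == res.unadjusted.total_le
        assert res.adjusted.dfle <= res.unadjusted.dfle
        moved = res.unadjusted.dfle - res.adjusted.dfle
        assert res.adjusted.disabled_le - res.unadjusted.disabled_le \
            == pytest.approx(moved, abs=1e-12)

    def test_expected_shift_matches_hand_computation(self):
        """Three fixed paths, two deaths from the nondisabled state: each
        such death carries a 0.5-year final credit, and the expected
        reallocated fraction is E(u) x 0.5 = 0.25 per death, i.e.
        2 x 0.25 / 3 years of DFLE on average."""
        from cohortmslt.mslt import SimulationTallies
        tallies = SimulationTallies(
            nd_credit=np.array([2.5, 4.5, 10.0]),
            dis_credit=np.array([1.0, 0.0, 0.0]),
            died_from_nd=np.array([True, True, False]),
            death_credit=0.5)
        base = LifeTableEstimate(window=(80, 89), total_le=6.0,
                                 dfle=17.0 / 3, disabled_le=1.0 / 3,
                                 n_simulated=3, tallies=tallies)
        shifts = []
        for s in range(4000):
            res = end_of_life_adjustment(base, seed=s)
            shifts.append(res.unadjusted.dfle - res.adjusted.dfle)
            assert 0 <= shifts[-1] <= 2 * 0.5 / 3
        expected = 2 * 0.25 / 3
        assert np.mean(shifts) == pytest.approx(expected, abs=3 * np.std(shifts)
                                                / np.sqrt(len(shifts)))

    def test_requires_retained_tallies(self):
        est = LifeTableEstimate(window=(80, 89), total_le=5.0, dfle=4.0,
                                disabled_le=1.0)
        with pytest.raises(ValueError, match="keep_tallies"):
            end_of_life_adjustment(est, seed=0)


class TestLifeTableEstimateInvariants:
    def test_identity_violation_rejected(self):
        with pytest.raises(ValueError):
            LifeTableEstimate(window=(80, 89), total_le=5.0, dfle=4.0,
                              disabled_le=0.5)

    def test_window_length_bound_enforced(self):
        with pytest.raises(ValueError):
            LifeTableEstimate(window=(80, 89), total_le=11.0, dfle=11.0,
                              disabled_le=0.0)
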