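"""LD coefficients, neighbor maps, correlation attack, and SPG-LD."""

import numpy as np
import pytest

import beaconshield as bs


def _block_panel(n=40, blocks=3, block_len=5, seed=0):
    """Perfectly correlated blocks whose carrier frequency is 0.5."""
    p_block = 1.0 - np.sqrt(0.5)  # Hardy-Weinberg carrier frequency = 0.5
    cfg = bs.SimulationConfig(
        n=n, n_ref=n, m=blocks * block_len, block_len=block_len, rho=1.0,
        block_p=p_block, seed=seed,
    )
    return bs.simulate_panel(cfg)


class TestLdCoefficient:
    def test_identical_columns_at_half_frequency(self):
        col = np.array([1, 0] * 20)
        assert bs.ld_coefficient(col, col) == pytest.approx(0.25)

    def test_complementary_columns_at_half_frequency(self):
        col = np.array([1, 0] * 20)
        assert bs.ld_coefficient(col, 1 - col) == pytest.approx(-0.25)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(0)
        a = (rng.random(20_000) < 0.4).astype(int)
        b = (rng.random(20_000) < 0.4).astype(int)
        assert abs(bs.ld_coefficient(a, b)) < 0.02

    def test_bounded_by_quarter(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = (rng.random(30) < rng.random()).astype(int)
            b = (rng.random(30) < rng.random()).astype(int)
            assert -0.25 <= bs.ld_coefficient(a, b) <= 0.25

    def test_analytic_maximum_is_quarter(self):
        assert bs.max_ld_coefficient() == pytest.approx(0.25, abs=1e-6)


class TestBuildLdMap:
    def test_independent_snvs_have_no_neighbors(self):
        cfg = bs.SimulationConfig(n=200, n_ref=200, m=10, seed=3)
        panel = bs.simulate_panel(cfg)
        ld = bs.build_ld_map(panel, window=1, t_ld=0.2)
        assert ld.neighbors == {}

    def test_identical_block_fully_connected(self):
        panel = _block_panel(blocks=1, block_len=5)
        ld = bs.build_ld_map(panel, window=4, t_ld=0.2, source="ref")
        for j in range(5):
            assert sorted(ld.neighbors[j]) == [k for k in range(5) if k != j]

    def test_restrict_to_limits_targets(self):
        panel = _block_panel(blocks=1, block_len=5)
        ld = bs.build_ld_map(panel, window=4, t_ld=0.2, restrict_to=[2])
        assert set(ld.neighbors) == {2}

    def test_coefficients_within_bounds(self):
        panel = _block_panel(blocks=2, block_len=4, seed=5)
        ld = bs.build_ld_map(panel, window=8, t_ld=0.0)
        for c in ld.coefficients.values():
            assert -0.25 <= c <= 0.25


class TestCorrelationAttack:
    def _setup(self):
        panel = _block_panel(n=60, blocks=2, block_len=4, seed=11)
        const = bs.compute_constants(panel)
        release = bs.make_release(panel)
        spec = bs.AttackSpec(model="fixed", theta=-5.0)
        return panel, const, release, spec

    def test_no_edits_means_no_change(self):
        panel, const, release, spec = self._setup()
        ld = bs.build_ld_map(panel, window=4)
        plan = bs.DefensePlan.empty(panel.m, bs.BEACON)
        attacked = bs.correlation_attack(release, plan, ld, panel, spec, const)
        plain = bs.evaluate_attack(panel, release, plan, spec, const)
        np.testing.assert_allclose(attacked.scores, plain.scores)
        assert attacked.n_protected == plain.n_protected

    def test_flipped_snv_with_unanimous_yes_neighbors_is_reverted(self):
        panel, const, release, spec = self._setup()
        assert (release.x[:4] == 1).all()
        ld = bs.build_ld_map(panel, window=4)
        delta = np.zeros(panel.m)
        delta[0] = -1.0
        plan = bs.DefensePlan(m=panel.m, mode=bs.BEACON, delta=delta)
        inferred = bs.infer_edited_responses(release, plan, ld)
        assert list(inferred) == [0]
        attacked = bs.correlation_attack(release, plan, ld, panel, spec, const)
        undefended = bs.evaluate_attack(panel, release, None, spec, const)
        # the edit is undone: scores revert to the undefended ones
        np.testing.assert_allclose(attacked.scores, undefended.scores, atol=1e-12)

    def test_below_vote_threshold_not_inferred(self):
        panel, const, release, spec = self._setup()
        ld = bs.build_ld_map(panel, window=4)
        # flip SNV 0 and 2 of its 3 voting neighbors -> 1/3 yes < 75%
        delta = np.zeros(panel.m)
        delta[[0, 1, 2]] = -1.0
        plan = bs.DefensePlan(m=panel.m, mode=bs.BEACON, delta=delta)
        assert 0 not in bs.infer_edited_responses(release, plan, ld)

    def test_masked_neighbors_do_not_vote(self):
        panel, const, release, spec = self._setup()
        ld = bs.build_ld_map(panel, window=4)
        delta = np.zeros(panel.m)
        delta[0] = -1.0
        masked = np.zeros(panel.m, bool)
        masked[[1, 2, 3]] = True  # all of SNV 0's neighbors masked
        plan = bs.DefensePlan(m=panel.m, mode=bs.BEACON, delta=delta, masked=masked)
        inferred = bs.infer_edited_responses(release, plan, ld)
        assert 0 not in inferred

    def test_untouched_noncarriers_unaffected(self):
        panel, const, release, spec = self._setup()
        ld = bs.build_ld_map(panel, window=4)
        delta = np.zeros(panel.m)
        delta[0] = -1.0
        plan = bs.DefensePlan(m=panel.m, mode=bs.BEACON, delta=delta)
        attacked = bs.correlation_attack(release, plan, ld, panel, spec, const)
        defended = bs.evaluate_attack(panel, release, plan, spec, const)
        avoids = panel.d[:, 0] == 0
        np.testing.assert_allclose(
            attacked.scores[avoids], defended.scores[avoids], atol=1e-12
        )


class TestSpgLd:
    def test_empty_map_reduces_to_spg_b(self, sim_beacon_panel):
        panel, const, release = sim_beacon_panel
        eta = bs.beacon_scores(const, release, None, panel.d)
        spec = bs.AttackSpec(model="fixed", theta=float(np.median(eta)))
        empty = bs.LDMap(neighbors={}, window=4, t_ld=0.2)
        plan_ld, pt_ld = bs.spg_ld(panel, const, release, spec, 1.0, 0.5, empty)
        plan_b, pt_b = bs.spg_b(panel, const, release, spec, 1.0, 0.5)
        np.testing.assert_array_equal(plan_ld.masked, plan_b.masked)
        np.testing.assert_array_equal(plan_ld.delta, plan_b.delta)
        assert pt_ld.objective == pt_b.objective

    def test_group_size_divides_marginal_scores(self):
        from beaconshield.spg_beacon import MarginalTable, average_marginals

        table = MarginalTable(
            delta_F=np.array([4.0]), delta_M=np.array([2.0]), in_Q1=np.array([True])
        )
        base_f, base_m = average_marginals(table, np.array([2.0]), 4, 0.5)
        grp_f, grp_m = average_marginals(
            table, np.array([2.0]), 4, 0.5, group_size=np.array([4.0])
        )
        assert grp_f[0] == pytest.approx(base_f[0] / 4)
        assert grp_m[0] == pytest.approx(base_m[0] / 4)

    def test_selected_snv_drags_whole_group(self):
        panel = _block_panel(n=60, blocks=1, block_len=5, seed=13)
        const = bs.compute_constants(panel)
        release = bs.make_release(panel)
        eta = bs.beacon_scores(const, release, None, panel.d)
        spec = bs.AttackSpec(model="fixed", theta=float(eta.max()) + 1.0)
        ld = bs.build_ld_map(panel, window=4, source="members")
        plan, _ = bs.spg_ld(panel, const, release, spec, w=1e6, alpha=0.5, ld=ld)
        edited = set(plan.masked_indices) | set(plan.flipped_indices)
        # any edit inside the block implies the whole block was edited
        if edited:
            assert edited == set(range(5))

    def test_group_editing_defeats_correlation_attack(self):
        panel = _block_panel(n=60, blocks=3, block_len=5, seed=17)
        const = bs.compute_constants(panel)
        release = bs.make_release(panel)
        eta = bs.beacon_scores(const, release, None, panel.d)
        spec = bs.AttackSpec(model="fixed", theta=float(np.median(eta)) + 0.5)
        ld = bs.build_ld_map(panel, window=4, source="members")
        plan, _ = bs.spg_ld(panel, const, release, spec, w=100.0, alpha=0.5, ld=ld)
        attacker_ld = bs.build_ld_map(panel, window=4, source="ref")
        assert len(bs.infer_edited_responses(release, plan, attacker_ld)) == 0
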