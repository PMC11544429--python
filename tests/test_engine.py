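"""Update rules: hand-checked algebra, identities, fixed points, run loop."""

import numpy as np
import pytest

import cryphase as cp
from cryphase.engine import algorithm_step
from cryphase.projections import FourierConstraint
from cryphase.reciprocal import DensityMap

from conftest import SMALL_CELL


def toy_projections():
    """Two affine projections in R^2 (onto lines) with a unique intersection.

    P_A projects onto the x-axis, P_B onto the line y = x. Intersection: the
    origin. Convexity makes every algorithm's behavior analytically known.
    """

    def PA(v):
        return np.array([v[0], 0.0])

    def PB(v):
        s = (v[0] + v[1]) / 2.0
        return np.array([s, s])

    return PA, PB


class TestUpdateAlgebra:
    """Hand-evaluated one-step results on the R^2 toy."""

    x0 = np.array([2.0, 4.0])

    def test_er_hand_value(self):
        PA, PB = toy_projections()
        x1, eA, eB = cp.er_update(self.x0, PA, PB)
        # PB x = (3,3); PA PB x = (3,0)
        assert np.allclose(eB, [3.0, 3.0])
        assert np.allclose(x1, [3.0, 0.0])

    def test_rrr_hand_value(self):
        PA, PB = toy_projections()
        beta = 0.5
        x1, eA, eB = cp.rrr_update(self.x0, PA, PB, beta)
        # PB x = (3,3); 2 PB x - x = (4,2); PA(...) = (4,0)
        assert np.allclose(eB, [3.0, 3.0])
        assert np.allclose(eA, [4.0, 0.0])
        assert np.allclose(x1, self.x0 + beta * (np.array([4.0, 0.0]) - np.array([3.0, 3.0])))

    def test_revrrr_hand_value(self):
        PA, PB = toy_projections()
        beta = 0.5
        x1, eA, eB = cp.revrrr_update(self.x0, PA, PB, beta)
        # PA x = (2,0); 2 PA x - x = (2,-4); PB(...) = (-1,-1)
        assert np.allclose(eA, [2.0, 0.0])
        assert np.allclose(eB, [-1.0, -1.0])
        assert np.allclose(x1, self.x0 + beta * (np.array([-1.0, -1.0]) - np.array([2.0, 0.0])))

    def test_dm_hand_value(self):
        PA, PB = toy_projections()
        beta = 0.5
        g = 1.0 / beta
        x1, eA, eB = cp.dm_update(self.x0, PA, PB, beta)
        fB = (1 + g) * np.array([3.0, 3.0]) - g * self.x0  # (5,1)
        fA = (1 - g) * np.array([2.0, 0.0]) + g * self.x0  # (2,8)
        assert np.allclose(eA, PA(fB))
        assert np.allclose(eB, PB(fA))
        assert np.allclose(x1, self.x0 + beta * (PA(fB) - PB(fA)))

    def test_raar_hand_value(self):
        PA, PB = toy_projections()
        beta = 0.7
        x1, eA, eB = cp.raar_update(self.x0, PA, PB, beta)
        # PA x = (2,0); 2 PA x - x = (2,-4); PB(...) = (-1,-1)
        expect = beta * (self.x0 + np.array([-1.0, -1.0])) + (1 - 2 * beta) * np.array([2.0, 0.0])
        assert np.allclose(x1, expect)

    def test_dm_update_identity_links_estimates(self):
        # x' - x = beta (est_A - est_B), so stationarity forces coincidence
        PA, PB = toy_projections()
        for beta in (-0.7, 0.3, 0.9):
            x1, eA, eB = cp.dm_update(self.x0, PA, PB, beta)
            assert np.allclose(x1 - self.x0, beta * (eA - eB), atol=1e-12)


class TestIdentities:
    def test_raar_beta1_equals_revrrr_beta1(self):
        PA, PB = toy_projections()
        rng = np.random.default_rng(0)
        x_r = x_v = rng.normal(size=2)
        for _ in range(20):
            x_r, _, _ = cp.raar_update(x_r, PA, PB, 1.0)
            x_v, _, _ = cp.revrrr_update(x_v, PA, PB, 1.0)
            assert np.allclose(x_r, x_v, atol=1e-10)

    def test_raar_beta1_equals_revrrr_on_crystal(self, small_crystal, small_refl):
        truth, env, prior = small_crystal
        PB = FourierConstraint(small_refl)

        def PA(v):
            return cp.project_real(DensityMap(v, truth.cell), env, prior).values

        rng = np.random.default_rng(1)
        x_r = x_v = rng.normal(size=truth.cell.shape)
        for _ in range(3):
            x_r, _, _ = cp.raar_update(x_r, PA, PB, 1.0)
            x_v, _, _ = cp.revrrr_update(x_v, PA, PB, 1.0)
            assert np.allclose(x_r, x_v, atol=1e-10)

    def test_rrr_beta1_is_douglas_rachford(self):
        PA, PB = toy_projections()
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.normal(size=2)
            x_rrr, _, _ = cp.rrr_update(x, PA, PB, 1.0)
            RB = 2.0 * PB(x) - x
            x_dr = 0.5 * (x + (2.0 * PA(RB) - RB))
            assert np.allclose(x_rrr, x_dr, atol=1e-12)

    def test_dm_sign_flip_swaps_constraint_roles(self):
        PA, PB = toy_projections()
        rng = np.random.default_rng(3)
        x = rng.normal(size=2)
        x1, eA, eB = cp.dm_update(x, PA, PB, 0.6)
        x2, eB2, eA2 = cp.dm_update(x, PB, PA, -0.6)
        # swapping the projections and negating beta gives the same iterate
        # with the two estimates' roles exchanged
        assert np.allclose(x1, x2, atol=1e-12)
        assert np.allclose(eA, eA2, atol=1e-12)
        assert np.allclose(eB, eB2, atol=1e-12)


class TestFixedPoints:
    def test_all_algorithms_nearly_preserve_the_truth(self, small_crystal, small_refl):
        """The truth satisfies both constraints up to band-limiting.

        A sharp-solvent map cannot be exactly band-limited (an analytic
        band-limited function vanishing on the solvent region would vanish
        everywhere), so the constraint sets intersect only approximately;
        each rule must hold the truth fixed to that truncation residual.
        Exact fixed-point preservation is checked on the convex R^2 toy.
        """
        truth, env, prior = small_crystal
        PB = FourierConstraint(small_refl)

        def PA(v):
            return cp.project_real(DensityMap(v, truth.cell), env, prior).values

        nrm = np.linalg.norm(truth.values)
        for name, beta in [("ER", None), ("DM", 0.7), ("RRR", 0.8), ("revRRR", 0.8), ("RAAR", 0.9)]:
            x1, eA, eB = algorithm_step(name, truth.values, PA, PB, beta)
            assert np.linalg.norm(x1 - truth.values) / nrm < 0.03, name
            assert np.linalg.norm(eA - eB) / nrm < 0.03, name

    def test_exact_fixed_point_on_convex_toy(self):
        """A point in the intersection is held exactly fixed by every rule."""
        PA, PB = toy_projections()
        x = np.zeros(2)  # the intersection of the two lines
        for name, beta in [("ER", None), ("DM", 0.7), ("RRR", 0.8), ("revRRR", 0.8), ("RAAR", 0.9)]:
            x1, eA, eB = algorithm_step(name, x, PA, PB, beta)
            assert np.allclose(x1, x, atol=1e-14), name
            assert np.allclose(eA, eB, atol=1e-14), name

    def test_convex_toy_converges_to_intersection(self):
        PA, PB = toy_projections()
        for name, beta in [("ER", None), ("DM", 0.7), ("RRR", 0.8), ("revRRR", 0.8), ("RAAR", 0.6)]:
            x = np.array([5.0, -3.0])
            for _ in range(300):
                x, eA, eB = algorithm_step(name, x, PA, PB, beta)
            assert np.linalg.norm(eA) < 1e-6, name
            assert np.linalg.norm(eB) < 1e-6, name


class TestProjectionCounts:
    def test_per_iteration_projection_cost(self):
        counts = {"A": 0, "B": 0}
        PA0, PB0 = toy_projections()

        def PA(v):
            counts["A"] += 1
            return PA0(v)

        def PB(v):
            counts["B"] += 1
            return PB0(v)

        x = np.array([1.0, 2.0])
        for name, beta, total in [("ER", None, 2), ("DM", 0.5, 4), ("RRR", 0.8, 2),
                                  ("revRRR", 0.8, 2), ("RAAR", 0.9, 2)]:
            counts["A"] = counts["B"] = 0
            algorithm_step(name, x, PA, PB, beta)
            assert counts["A"] + counts["B"] == total, name


class TestConfigValidation:
    def test_beta_ranges(self):
        with pytest.raises(ValueError, match="beta = 0"):
            cp.AlgorithmConfig(name="DM", beta=0.0)
        with pytest.raises(ValueError):
            cp.AlgorithmConfig(name="DM", beta=1.0)
        cp.AlgorithmConfig(name="DM", beta=-0.5)  # negative beta is legal for DM
        with pytest.raises(ValueError):
            cp.AlgorithmConfig(name="RRR", beta=2.0)
        with pytest.raises(ValueError):
            cp.AlgorithmConfig(name="RAAR", beta=1.2)
        with pytest.raises(ValueError):
            cp.AlgorithmConfig(name="RRR", beta=None)
        with pytest.raises(ValueError):
            cp.AlgorithmConfig(name="XYZ", beta=0.5)

    def test_monitored_estimate_validated(self):
        with pytest.raises(ValueError):
            cp.AlgorithmConfig(name="RRR", beta=0.8, monitored_estimate="C")


class TestRunLoop:
    def test_run_records_fixed_length_and_is_deterministic(self, small_crystal, small_refl):
        truth, env, prior = small_crystal
        corrupted = cp.corrupt_phases(small_refl, cp.ErrorSpec(0.4, seed=9))
        start = small_refl.amplitudes * np.exp(1j * corrupted.phases)
        cfg = cp.AlgorithmConfig(name="RRR", beta=0.8, n_iterations=12, trailing_window=6,
                                 solvent_fraction=0.74, window_radius=2.5)
        rec1 = cp.run(start, small_refl, cfg, prior, envelope=env)
        rec2 = cp.run(start, small_refl, cfg, prior, envelope=env)
        assert rec1.n_iterations == 12
        assert rec1.coeffs.shape == (6, len(small_refl))
        assert np.array_equal(rec1.coeffs, rec2.coeffs)
        assert rec1.metrics["correlation"].notna().all()

    def test_er_from_truth_stays_at_solution(self, small_crystal, small_refl):
        truth, env, prior = small_crystal
        cfg = cp.AlgorithmConfig(name="ER", beta=None, n_iterations=5, trailing_window=5,
                                 solvent_fraction=0.74, window_radius=2.5)
        rec = cp.run(truth, small_refl, cfg, prior, envelope=env)
        assert rec.final_correlation > 0.98

    def test_monitored_estimate_b_satisfies_amplitudes(self, small_crystal, small_refl):
        truth, env, prior = small_crystal
        cfg = cp.AlgorithmConfig(name="RRR", beta=0.8, n_iterations=4, trailing_window=4,
                                 solvent_fraction=0.74, window_radius=2.5,
                                 monitored_estimate="B")
        rec = cp.run(truth, small_refl, cfg, prior, envelope=env)
        assert np.allclose(np.abs(rec.coeffs[-1]), small_refl.amplitudes, atol=1e-8)

    def test_thinned_record(self, small_crystal, small_refl):
        truth, env, prior = small_crystal
        cfg = cp.AlgorithmConfig(name="ER", beta=None, n_iterations=9, trailing_window=3,
                                 thin=3, solvent_fraction=0.74, window_radius=2.5)
        rec = cp.run(truth, small_refl, cfg, prior, envelope=env)
        assert list(rec.thinned_iterations) == [3, 6, 9]
        assert rec.thinned.shape == (3, len(small_refl))

    def test_needs_envelope_or_fraction(self, small_crystal, small_refl):
        truth, _, prior = small_crystal
        cfg = cp.AlgorithmConfig(name="ER", beta=None, n_iterations=1, solvent_fraction=None)
        with pytest.raises(ValueError, match="solvent fraction"):
            cp.run(truth, small_refl, cfg, prior)

    def test_rejects_mismatched_start(self, small_crystal, small_refl):
        truth, env, prior = small_crystal
        cfg = cp.AlgorithmConfig(name="ER", beta=None, n_iterations=1, solvent_fraction=0.74)
        with pytest.raises(ValueError, match="complex"):
            cp.run(np.zeros(5), small_refl, cfg, prior, envelope=env)
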