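"""Constraint projections: idempotence, distance minimization, envelope recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cryphase as cp
from cryphase.projections import FourierConstraint, register_envelope, wilson_shell_means
from cryphase.reciprocal import DensityMap

from conftest import SMALL_CELL, TINY_CELL


class TestEnvelope:
    def test_mask_recovery_from_truth(self, small_crystal):
        truth, env_true, _ = small_crystal
        est = cp.estimate_envelope(truth, env_true.solvent_fraction_target, window_radius=2.5)
        agreement = np.mean(est.mask == env_true.mask)
        assert agreement >= 0.95

    def test_solvent_voxel_count_exact(self, small_crystal):
        truth, _, _ = small_crystal
        frac = 0.74
        est = cp.estimate_envelope(truth, frac, window_radius=2.5)
        n_solvent = int(np.ceil(frac * truth.values.size))
        assert int((~est.mask).sum()) == n_solvent

    def test_featureless_map_raises(self):
        flat = DensityMap(np.ones(TINY_CELL.shape), TINY_CELL)
        with pytest.raises(ValueError, match="featureless"):
            cp.estimate_envelope(flat, 0.5, window_radius=4.0)

    def test_deterministic_under_ties(self):
        rng = np.random.default_rng(0)
        vals = np.round(rng.random(TINY_CELL.shape), 1)  # heavy ties
        dmap = DensityMap(vals, TINY_CELL)
        a = cp.estimate_envelope(dmap, 0.5, window_radius=4.0)
        b = cp.estimate_envelope(dmap, 0.5, window_radius=4.0)
        assert np.array_equal(a.mask, b.mask)

    def test_invalid_fraction(self, small_crystal):
        truth, _, _ = small_crystal
        with pytest.raises(ValueError):
            cp.estimate_envelope(truth, 1.0)


class TestRegisterEnvelope:
    def test_recovers_known_shift(self, small_crystal):
        _, env_true, _ = small_crystal
        shifted = cp.Envelope(np.roll(env_true.mask, (3, -2, 5), axis=(0, 1, 2)),
                              env_true.solvent_fraction_target)
        back, shift = register_envelope(shifted, env_true)
        assert np.array_equal(back.mask, env_true.mask)

    def test_identity_when_aligned(self, small_crystal):
        _, env_true, _ = small_crystal
        back, shift = register_envelope(env_true, env_true)
        assert shift == (0, 0, 0)
        assert back is env_true


class TestProjectReal:
    def test_idempotent(self, small_crystal, rng):
        truth, env, prior = small_crystal
        noisy = DensityMap(truth.values + 0.3 * rng.normal(size=truth.values.shape), truth.cell)
        once = cp.project_real(noisy, env, prior)
        twice = cp.project_real(once, env, prior)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    def test_fixed_point_on_truth(self, small_crystal):
        truth, env, prior = small_crystal
        out = cp.project_real(truth, env, prior)
        assert np.allclose(out.values, truth.values, atol=1e-9)

    def test_solvent_flattened_to_mean(self, small_crystal, rng):
        truth, env, prior = small_crystal
        noisy = DensityMap(rng.normal(size=truth.values.shape), truth.cell)
        out = cp.project_real(noisy, env, prior)
        solvent = ~env.mask
        assert np.allclose(out.values[solvent], noisy.values[solvent].mean())

    def test_rank_transport_preserves_order(self, small_crystal, rng):
        truth, env, prior = small_crystal
        noisy = DensityMap(rng.normal(size=truth.values.shape), truth.cell)
        out = cp.project_real(noisy, env, prior)
        v_in = noisy.values[env.mask]
        v_out = out.values[env.mask]
        order = np.argsort(v_in, kind="stable")
        assert np.all(np.diff(v_out[order]) >= -1e-12)

    def test_protein_histogram_matches_reference(self, small_crystal, rng):
        truth, env, prior = small_crystal
        noisy = DensityMap(rng.normal(size=truth.values.shape), truth.cell)
        out = cp.project_real(noisy, env, prior)
        got = np.sort(out.values[env.mask])
        # same number of protein voxels as reference values here, so the
        # transported sample reproduces the reference order statistics
        assert np.allclose(got, prior.reference_values, atol=1e-12)

    def test_distance_minimizing_among_candidates(self, small_crystal, rng):
        # among maps satisfying the constraint (reference values permuted onto
        # the protein region + constant solvent), the projection is closest
        truth, env, prior = small_crystal
        noisy = DensityMap(rng.normal(size=truth.values.shape), truth.cell)
        proj = cp.project_real(noisy, env, prior)
        best = np.sum((proj.values - noisy.values) ** 2)
        for _ in range(5):
            cand = noisy.values.copy()
            cand[~env.mask] = noisy.values[~env.mask].mean()
            cand[env.mask] = rng.permutation(np.sort(proj.values[env.mask]))
            assert np.sum((cand - noisy.values) ** 2) >= best - 1e-9


class TestDensityPrior:
    def test_quantile_endpoints_and_monotonicity(self):
        prior = cp.DensityPrior(np.array([0.0, 1.0, 4.0, 9.0]))
        u = np.linspace(0, 1, 33)
        q = prior.quantile(u)
        assert q[0] == 0.0 and q[-1] == 9.0
        assert np.all(np.diff(q) >= 0)

    def test_rejects_tiny_or_nonfinite(self):
        with pytest.raises(ValueError):
            cp.DensityPrior(np.array([1.0]))
        with pytest.raises(ValueError):
            cp.DensityPrior(np.array([1.0, np.nan]))


class TestProjectFourier:
    def test_measured_amplitudes_replaced_phases_kept(self, small_crystal, small_refl, rng):
        truth, _, _ = small_crystal
        noisy = DensityMap(truth.values + 0.5 * rng.normal(size=truth.values.shape), truth.cell)
        out = cp.project_fourier(noisy, small_refl)
        coeffs_in = cp.density_to_structure_factors(noisy, small_refl)
        coeffs_out = cp.density_to_structure_factors(out, small_refl)
        assert np.allclose(np.abs(coeffs_out), small_refl.amplitudes, atol=1e-9)
        # phases preserved
        assert np.allclose(np.angle(coeffs_out * np.conj(coeffs_in)), 0.0, atol=1e-9)

    def test_idempotent(self, small_crystal, small_refl, rng):
        truth, _, _ = small_crystal
        noisy = DensityMap(rng.normal(size=truth.values.shape), truth.cell)
        once = cp.project_fourier(noisy, small_refl)
        twice = cp.project_fourier(once, small_refl)
        assert np.allclose(once.values, twice.values, atol=1e-10)

    def test_band_limiting_and_f000(self, small_crystal, small_refl, rng):
        truth, _, _ = small_crystal
        noisy = DensityMap(rng.normal(size=truth.values.shape), truth.cell)
        out = cp.project_fourier(noisy, small_refl)
        fgrid = np.fft.ifftn(out.values) * out.values.size
        assert fgrid[0, 0, 0].real == pytest.approx(small_refl.f000, rel=1e-9)
        # out-of-set coefficients are zeroed
        keep = np.zeros(truth.cell.shape, dtype=bool)
        i, j, k = small_refl.grid_indices()
        keep[i, j, k] = True
        hkl = small_refl.hkl
        n1, n2, n3 = truth.cell.shape
        keep[(-hkl[:, 0]) % n1, (-hkl[:, 1]) % n2, (-hkl[:, 2]) % n3] = True
        keep[0, 0, 0] = True
        assert np.max(np.abs(fgrid[~keep])) < 1e-9

    def test_zero_amplitude_coefficient_gets_phase_zero(self, small_refl):
        fc = FourierConstraint(small_refl)
        coeffs = np.zeros(len(small_refl), dtype=complex)
        out = fc.project_coefficients(coeffs)
        assert np.allclose(out.imag, 0.0)
        assert np.allclose(out.real, fc.F_measured)

    def test_wilson_cap_on_unmeasured(self, small_crystal):
        truth, _, _ = small_crystal
        refl = cp.simulate_data(truth, completeness=0.8, seed=5)
        fc = FourierConstraint(refl, wilson_cap=2.0)
        rng = np.random.default_rng(2)
        # large random coefficients: unmeasured terms must come back capped
        coeffs = 1e6 * (rng.normal(size=len(refl)) + 1j * rng.normal(size=len(refl)))
        out = fc.project_coefficients(coeffs)
        unmeasured = ~fc.measured
        assert unmeasured.any()
        expect = 2.0 * wilson_shell_means(refl)
        assert np.all(np.abs(out[unmeasured]) <= expect[unmeasured] + 1e-6)
        # measured terms still replaced exactly
        assert np.allclose(np.abs(out[fc.measured]), fc.F_measured[fc.measured])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_projections_idempotent_property(seed):
    cell = TINY_CELL
    spec = cp.ToyCrystalSpec(cell=cell, seed=3, n_blobs=6, blob_width=1.6, solvent_fraction=0.6)
    truth, env, prior = cp.make_toy_crystal(spec)
    refl = cp.simulate_data(truth, seed=3)
    rng = np.random.default_rng(seed)
    dmap = DensityMap(rng.normal(size=cell.shape), cell)
    pa = cp.project_real(dmap, env, prior)
    assert np.allclose(cp.project_real(pa, env, prior).values, pa.values, atol=1e-10)
    pb = cp.project_fourier(dmap, refl)
    assert np.allclose(cp.project_fourier(pb, refl).values, pb.values, atol=1e-9)
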