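"""Constraint projections for density modification.

Two constraint sets are used throughout:

* **A — real space.** Solvent flatness plus histogram equivalence: the
  density in the solvent region is set to its mean value, and the density
  values in the protein region are remapped by an order-preserving
  (quantile-transport) transformation onto a reference histogram. The
  protein/solvent envelope is determined by thresholding the local variance
  of the current density estimate.

* **B — Fourier space.** The Fourier amplitudes of measured reflections are
  replaced by their measured values while phases are retained; unmeasured
  terms are restrained via Wilson statistics (a per-shell amplitude cap);
  terms beyond the resolution limit are zeroed and F(000) is held fixed.

Both operations are projections in the least-squares sense: they satisfy
their constraint exactly while minimizing the squared change to the input,
and they are idempotent for a fixed envelope and prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reciprocal import DensityMap, ReflectionSet, UnitCellGrid, resolution_shells

__all__ = [
    "Envelope",
    "DensityPrior",
    "estimate_envelope",
    "register_envelope",
    "project_real",
    "project_fourier",
    "FourierConstraint",
    "wilson_shell_means",
]


@dataclass
class Envelope:
    """Binary protein/solvent mask on the grid (True = protein)."""

    mask: np.ndarray
    solvent_fraction_target: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (0.0 < self.solvent_fraction_target < 1.0):
            raise ValueError("solvent fraction must lie in (0, 1)")

    @property
    def solvent_fraction(self) -> float:
        return 1.0 - self.mask.mean()


@dataclass
class DensityPrior:
    """Reference density distribution for the protein region plus solvent level.

    ``reference_values`` is a sample of protein-region density values; its
    empirical quantile function (linear interpolation between order
    statistics) defines the target histogram for quantile transport.
    """

    reference_values: np.ndarray
    solvent_level: float = 0.0

    def __post_init__(self):
        ref = np.sort(np.asarray(self.reference_values, dtype=float).ravel())
        if ref.size < 2:
            raise ValueError("reference histogram needs at least two values")
        if not np.all(np.isfinite(ref)):
            raise ValueError("non-finite reference histogram values")
        self.reference_values = ref

    def quantile(self, u: np.ndarray) -> np.ndarray:
        """Non-decreasing quantile function on [0, 1]."""
        u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
        n = self.reference_values.size
        return np.interp(u * (n - 1), np.arange(n), self.reference_values)

    @property
    def protein_mean(self) -> float:
        return float(self.reference_values.mean())


def _spherical_kernel(cell: UnitCellGrid, radius: float) -> np.ndarray:
    """Periodic spherical window (radius in Angstrom) centred on voxel (0,0,0)."""
    n1, n2, n3 = cell.shape
    off = [np.where(np.arange(n) > n // 2, np.arange(n) - n, np.arange(n)) for n in (n1, n2, n3)]
    I, J, K = np.meshgrid(*off, indexing="ij")
    frac = np.stack([I / n1, J / n2, K / n3], axis=-1)
    orth = cell.orthogonalization_matrix
    cart = frac @ orth.T
    dist = np.linalg.norm(cart, axis=-1)
    kernel = (dist <= radius).astype(float)
    return kernel


def estimate_envelope(dmap: DensityMap, solvent_fraction: float, window_radius: float = 4.0) -> Envelope:
    """Estimate the molecular envelope by thresholding the local density variance.

    The local variance within a spherical window (periodic boundaries) is
    computed as mean-of-squares minus square-of-mean of the smoothed map;
    the threshold is chosen so that exactly ``ceil(solvent_fraction * N)``
    of the lowest-variance voxels are classed as solvent. Ties in local
    variance are broken by voxel lexicographic index so the solvent count
    is deterministic.
    """
    if not (0.0 < solvent_fraction < 1.0):
        raise ValueError("solvent fraction must lie in (0, 1)")
    values = dmap.values
    if np.ptp(values) == 0.0:
        raise ValueError("featureless map: cannot estimate an envelope from zero global variance")
    cell = dmap.cell
    kernel = _spherical_kernel(cell, window_radius)
    if kernel.sum() < 3**3:
        raise ValueError("local-variance window covers fewer than 3 voxels per axis")
    fk = np.fft.rfftn(kernel) / kernel.sum()
    local_mean = np.fft.irfftn(np.fft.rfftn(values) * fk, s=values.shape, axes=(0, 1, 2))
    local_meansq = np.fft.irfftn(np.fft.rfftn(values**2) * fk, s=values.shape, axes=(0, 1, 2))
    local_var = local_meansq - local_mean**2
    order = np.argsort(local_var.ravel(), kind="stable")
    n_solvent = int(np.ceil(solvent_fraction * values.size))
    mask = np.ones(values.size, dtype=bool)
    mask[order[:n_solvent]] = False
    return Envelope(mask.reshape(values.shape), solvent_fraction)


def register_envelope(env: Envelope, reference: Envelope) -> tuple[Envelope, tuple[int, int, int]]:
    """Translate an envelope onto a reference by the best integer-voxel shift.

    In P1 both constraint sets are invariant under lattice translations, so
    the origin of a reconstruction is a free gauge and can drift when the
    envelope is re-estimated from the evolving solution estimate. Registering
    each new envelope against an anchor (the run's initial envelope) pins the
    origin without otherwise altering the projections. The shift maximizing
    the periodic overlap of the two protein masks is found by FFT
    cross-correlation; the translated envelope and the applied shift (in
    voxels) are returned.
    """
    if env.mask.shape != reference.mask.shape:
        raise ValueError("envelopes are on different grids")
    a = reference.mask.astype(float)
    b = env.mask.astype(float)
    cc = np.fft.irfftn(np.conj(np.fft.rfftn(a)) * np.fft.rfftn(b), s=a.shape, axes=(0, 1, 2))
    peak = np.unravel_index(int(np.argmax(cc)), cc.shape)
    shift = tuple(int(p - n) if p > n // 2 else int(p) for p, n in zip(peak, a.shape))
    if shift == (0, 0, 0):
        return env, shift
    moved = np.roll(env.mask, tuple(-s for s in shift), axis=(0, 1, 2))
    return Envelope(moved, env.solvent_fraction_target), shift


def project_real(dmap: DensityMap, env: Envelope, prior: DensityPrior) -> DensityMap:
    """Project onto the solvent-flatness + histogram-equivalence constraint.

    Solvent voxels are set to the mean of the input solvent-region values;
    protein voxels are replaced by the reference quantile at their input
    rank, preserving order. Idempotent for a fixed envelope and prior.
    """
    if env.mask.shape != dmap.values.shape:
        raise ValueError("envelope and map are on different grids")
    out = dmap.values.copy()
    solvent = ~env.mask
    if solvent.any():
        out[solvent] = dmap.values[solvent].mean()
    protein_vals = dmap.values[env.mask]
    n = protein_vals.size
    if n > 0:
        order = np.argsort(protein_vals, kind="stable")
        ranks = np.empty(n, dtype=float)
        ranks[order] = np.arange(n)
        u = ranks / (n - 1) if n > 1 else np.full(n, 0.5)
        out[env.mask] = prior.quantile(u)
    return DensityMap(out, dmap.cell)


def wilson_shell_means(refl: ReflectionSet, n_shells: int = 10) -> np.ndarray:
    """Per-reflection expected amplitude <|F|> from measured terms in the same shell.

    The expectation is the shell mean of the measured amplitudes, used as the
    scale of the Wilson restraint on unmeasured reflections.
    """
    n_shells = min(n_shells, max(1, len(refl) // 20))
    shell, _ = resolution_shells(refl, n_shells)
    F = refl.amplitudes
    measured = refl.is_measured & np.isfinite(F)
    expect = np.zeros(len(refl))
    overall = F[measured].mean() if measured.any() else 1.0
    for j in range(n_shells):
        sel_m = (shell == j) & measured
        expect[shell == j] = F[sel_m].mean() if sel_m.any() else overall
    return expect


class FourierConstraint:
    """Precomputed Fourier-amplitude projection P_B for a reflection set.

    Parameters
    ----------
    refl : ReflectionSet
        Measured amplitudes, measured/unmeasured flags and geometry.
    f000 : float, optional
        Fixed zero-order term; defaults to the set's recorded F(000).
    wilson_cap : float
        Unmeasured amplitudes are capped at ``wilson_cap`` times the shell
        mean of the measured amplitudes (Wilson restraint).
    """

    def __init__(self, refl: ReflectionSet, f000: float | None = None, wilson_cap: float = 2.0):
        self.refl = refl
        self.cell = refl.cell
        self.f000 = refl.f000 if f000 is None else float(f000)
        self.wilson_cap = float(wilson_cap)
        F = refl.amplitudes
        self.measured = refl.is_measured & np.isfinite(F)
        if np.any(F[self.measured] < 0):
            raise ValueError("negative measured amplitude")
        self.F_measured = np.where(self.measured, F, 0.0)
        if np.all(self.measured):
            self.unmeasured_cap = None
        else:
            self.unmeasured_cap = self.wilson_cap * wilson_shell_means(refl)
        n1, n2, n3 = self.cell.shape
        hkl = refl.hkl
        self._pos = (hkl[:, 0] % n1, hkl[:, 1] % n2, hkl[:, 2] % n3)
        self._neg = ((-hkl[:, 0]) % n1, (-hkl[:, 1]) % n2, (-hkl[:, 2]) % n3)

    def project_coefficients(self, coeffs: np.ndarray) -> np.ndarray:
        """Amplitude replacement on an aligned complex coefficient array."""
        amp = np.abs(coeffs)
        # a zero-amplitude coefficient carries phase 0 by convention
        phase_factor = np.where(amp > 0, coeffs / np.where(amp > 0, amp, 1.0), 1.0)
        new_amp = np.where(self.measured, self.F_measured, amp)
        if self.unmeasured_cap is not None:
            new_amp = np.where(self.measured, new_amp, np.minimum(new_amp, self.unmeasured_cap))
        return new_amp * phase_factor

    def __call__(self, values: np.ndarray) -> np.ndarray:
        """Apply P_B to a raw density array (same grid), returning a new array."""
        n = values.size
        fgrid = np.fft.ifftn(values) * n
        coeffs = fgrid[self._pos]
        new = self.project_coefficients(coeffs)
        out = np.zeros_like(fgrid)
        out[self._pos] = new
        out[self._neg] = np.conj(new)
        out[0, 0, 0] = self.f000
        return (np.fft.fftn(out) / n).real.copy()

    def project(self, dmap: DensityMap) -> DensityMap:
        if dmap.cell != self.cell:
            raise ValueError("map and constraint are on different cells")
        return DensityMap(self(dmap.values), self.cell)


def project_fourier(
    dmap: DensityMap,
    refl: ReflectionSet,
    f000: float | None = None,
    wilson_cap: float = 2.0,
) -> DensityMap:
    """Project a map onto the measured-amplitude (Fourier-space) constraint."""
    return FourierConstraint(refl, f000=f000, wilson_cap=wilson_cap).project(dmap)
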