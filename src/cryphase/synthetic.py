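"""Synthetic toy crystals and geometry-free statistical reflection sets.

Emulates the high-solvent-content regime in which solvent flatness is a
strong constraint: a periodic unit cell holding a contiguous protein region
(a cluster of positive Gaussian blobs confined to a sub-volume) embedded in
flat solvent, with a controlled solvent fraction. Diffraction data are the
exact Fourier amplitudes of the truth, optionally perturbed by fractional
Gaussian amplitude noise and thinned to a target completeness; reference
phases are stored for scoring. A geometry-free generator draws Wilson
(Rayleigh) amplitudes with uniform phases for error-model and metric
calibration experiments that need no grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .projections import DensityPrior, Envelope
from .reciprocal import (
    REFLECTION_COLUMNS,
    DensityMap,
    ReflectionSet,
    UnitCellGrid,
    full_transform,
    hemisphere_hkl,
)

__all__ = ["ToyCrystalSpec", "make_toy_crystal", "simulate_data", "make_phase_experiment_set"]

DEFAULT_CELL = UnitCellGrid(
    cell_lengths=(40.0, 40.0, 40.0),
    cell_angles=(90.0, 90.0, 90.0),
    shape=(48, 48, 48),
    d_min=2.5,
)


@dataclass
class ToyCrystalSpec:
    """Parameters of a synthetic crystal.

    Blob centres are drawn inside a central sub-box occupying the protein
    volume fraction, so the protein region stays (approximately) connected.
    """

    cell: UnitCellGrid = field(default_factory=lambda: DEFAULT_CELL)
    solvent_fraction: float = 0.74
    n_blobs: int = 60
    blob_width: float = 2.0
    amplitude_noise: float = 0.0
    seed: int = 0
    centric_fraction: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.solvent_fraction < 1.0):
            raise ValueError("solvent fraction must lie in (0, 1)")
        if self.n_blobs < 1:
            raise ValueError("need at least one blob")
        if self.blob_width <= 0:
            raise ValueError("blob width must be positive")
        if not (0.0 <= self.centric_fraction < 1.0):
            raise ValueError("centric fraction must lie in [0, 1)")
        min_len = min(self.cell.cell_lengths)
        if self.blob_width > min_len / 4:
            raise ValueError("blobs do not fit in the cell at the requested size")


def make_toy_crystal(spec: ToyCrystalSpec) -> tuple[DensityMap, Envelope, DensityPrior]:
    """Build the ground-truth density, envelope and protein-density prior.

    The density is a sum of positive Gaussian blobs placed in a central
    sub-box, thresholded by rank so that the protein region holds exactly
    the non-solvent voxel count; the solvent level is zero. The prior's
    reference histogram is the truth's protein-region value distribution.
    """
    cell = spec.cell
    rng = np.random.default_rng(spec.seed)
    n1, n2, n3 = cell.shape
    protein_fraction = 1.0 - spec.solvent_fraction
    # central sub-box with the protein volume fraction (per-axis cube root)
    half = 0.5 * protein_fraction ** (1.0 / 3.0)
    centers = rng.uniform(0.5 - half, 0.5 + half, size=(spec.n_blobs, 3))

    axes = [np.arange(n) / n for n in (n1, n2, n3)]
    orth = cell.orthogonalization_matrix
    g = np.zeros(cell.shape)
    two_w2 = 2.0 * spec.blob_width**2
    for c in centers:
        d2 = np.zeros(cell.shape)
        # periodic minimum-image separation, axis by axis in Cartesian terms
        frac_d = [
            (ax - cc + 0.5) % 1.0 - 0.5 for ax, cc in zip(axes, c)
        ]
        D = np.stack(np.meshgrid(*frac_d, indexing="ij"), axis=-1)
        cart = D @ orth.T
        d2 = np.sum(cart**2, axis=-1)
        g += np.exp(-d2 / two_w2)

    n_solvent = int(round(spec.solvent_fraction * g.size))
    order = np.argsort(g.ravel(), kind="stable")
    mask = np.ones(g.size, dtype=bool)
    mask[order[:n_solvent]] = False
    mask = mask.reshape(g.shape)
    threshold = g.ravel()[order[n_solvent - 1]] if n_solvent else 0.0
    density = np.where(mask, g - threshold, 0.0)

    envelope = Envelope(mask, spec.solvent_fraction)
    prior = DensityPrior(density[mask], solvent_level=0.0)
    return DensityMap(density, cell), envelope, prior


def simulate_data(
    truth: DensityMap,
    amplitude_noise: float = 0.0,
    completeness: float = 1.0,
    seed: int = 0,
    d_min: float | None = None,
) -> ReflectionSet:
    """Exact diffraction data of a truth map, with optional noise and gaps.

    Amplitudes are |F_true| (1 + noise * N(0,1)) clipped at zero; reference
    phases are stored for scoring; a random (1 - completeness) subset is
    flagged unmeasured with the amplitude withheld. F(000) is recorded on
    the returned set. All reflections are acentric (P1, general positions).
    """
    if not (0.0 < completeness <= 1.0):
        raise ValueError("completeness must lie in (0, 1]")
    cell = truth.cell
    if d_min is not None and d_min < cell.d_min:
        raise ValueError("requested d_min is below the grid's resolution support")
    rng = np.random.default_rng(seed)
    hkl = hemisphere_hkl(cell, d_min)
    fgrid = full_transform(truth.values)
    coeffs = fgrid[hkl[:, 0] % cell.shape[0], hkl[:, 1] % cell.shape[1], hkl[:, 2] % cell.shape[2]]
    F = np.abs(coeffs)
    if amplitude_noise > 0:
        F = np.clip(F * (1.0 + amplitude_noise * rng.standard_normal(F.size)), 0.0, None)
    measured = rng.random(F.size) < completeness
    table = pd.DataFrame(
        {
            "h": hkl[:, 0],
            "k": hkl[:, 1],
            "l": hkl[:, 2],
            "F": np.where(measured, F, np.nan),
            "phi": np.angle(coeffs),
            "centric": False,
            "epsilon": 1,
            "d": cell.d_spacing(hkl),
            "is_measured": measured,
        }
    )
    return ReflectionSet(table[REFLECTION_COLUMNS], cell, f000=float(truth.values.sum()))


def _synthetic_hkl(n: int) -> np.ndarray:
    """The n smallest unique Friedel-hemisphere index triples by radius."""
    r = 1
    while True:
        rng_ax = np.arange(-r, r + 1)
        H, K, L = np.meshgrid(rng_ax, rng_ax, rng_ax, indexing="ij")
        hkl = np.stack([H.ravel(), K.ravel(), L.ravel()], axis=1)
        pos = (hkl[:, 0] > 0) | ((hkl[:, 0] == 0) & (hkl[:, 1] > 0)) | (
            (hkl[:, 0] == 0) & (hkl[:, 1] == 0) & (hkl[:, 2] > 0)
        )
        hkl = hkl[pos]
        if len(hkl) >= n:
            norm = np.linalg.norm(hkl, axis=1)
            order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0], norm))
            return hkl[order][:n]
        r += 1


def make_phase_experiment_set(
    n_reflections: int, centric_fraction: float = 0.0, seed: int = 0
) -> ReflectionSet:
    """Geometry-free reflection set for statistical calibration experiments.

    Amplitudes follow the acentric Wilson (Rayleigh) law normalized to
    <F^2> = 1; phases are uniform on (-pi, pi]; a ``centric_fraction``
    subset is flagged centric with two-point phases in {0, pi}. Used where
    no density grid is needed (error-model and metric calibration).
    """
    if n_reflections < 1:
        raise ValueError("need at least one reflection")
    if not (0.0 <= centric_fraction < 1.0):
        raise ValueError("centric fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    hkl = _synthetic_hkl(n_reflections)
    # Rayleigh with scale 1/sqrt(2) gives <F^2> = 1
    F = rng.rayleigh(scale=1.0 / np.sqrt(2.0), size=n_reflections)
    phi = rng.uniform(-np.pi, np.pi, size=n_reflections)
    centric = np.zeros(n_reflections, dtype=bool)
    n_centric = int(round(centric_fraction * n_reflections))
    if n_centric:
        centric[rng.choice(n_reflections, size=n_centric, replace=False)] = True
        phi[centric] = rng.choice([0.0, np.pi], size=n_centric)
    radius = np.linalg.norm(hkl, axis=1)
    d = 100.0 / radius  # nominal geometry: d in Angstrom for a 100 A pseudo-cell
    d_min = float(d.min()) * 0.99
    # Shannon-adequate grid: spacing 100/nmax must not exceed d_min/2
    nmax = 2 * (int(np.ceil(100.0 / d_min)) + 1)
    cell = UnitCellGrid((100.0, 100.0, 100.0), (90.0, 90.0, 90.0), (nmax, nmax, nmax), d_min=d_min)
    table = pd.DataFrame(
        {
            "h": hkl[:, 0],
            "k": hkl[:, 1],
            "l": hkl[:, 2],
            "F": F,
            "phi": phi,
            "centric": centric,
            "epsilon": 1,
            "d": d,
            "is_measured": True,
        }
    )
    return ReflectionSet(table[REFLECTION_COLUMNS], cell)
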