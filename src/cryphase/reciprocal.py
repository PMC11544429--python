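"""Real-space grid, reflection list, and their mutual Fourier mapping.

The electron density lives on a discrete 3D grid sampling the unit cell;
structure factors live on the reciprocal lattice. This module defines both
containers and the discrete Fourier transform between them, together with
the statistical degeneracy factors (epsilon) and resolution-shell binning
used by the agreement statistics.

Conventions
-----------
* Space group P1 with Friedel symmetry only; exactly one member of each
  Friedel pair {h, -h} is stored (the lexicographically positive one) and
  (0,0,0) is excluded, its value being carried separately as F(000).
* Forward transform: F(h) = sum_x rho(x) exp(+2*pi*i h.x) with x the
  fractional coordinate of each voxel; phases reported in (-pi, pi].
* Grids have even dimensions; voxel (0,0,0) sits at the cell origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "UnitCellGrid",
    "ReflectionSet",
    "DensityMap",
    "hemisphere_hkl",
    "density_to_structure_factors",
    "structure_factors_to_density",
    "assign_epsilon",
    "resolution_shells",
]

REFLECTION_COLUMNS = ["h", "k", "l", "F", "phi", "centric", "epsilon", "d", "is_measured"]


@dataclass(frozen=True)
class UnitCellGrid:
    """Unit cell together with the real-space grid that samples it.

    Parameters
    ----------
    cell_lengths : tuple of float
        a, b, c in Angstrom.
    cell_angles : tuple of float
        alpha, beta, gamma in degrees.
    shape : tuple of int
        Number of grid divisions along each cell axis (even, >= 2).
    d_min : float
        Resolution limit in Angstrom. The grid must sample at or better
        than d_min/2 along every axis (Shannon-adequate).
    """

    cell_lengths: tuple[float, float, float]
    cell_angles: tuple[float, float, float] = (90.0, 90.0, 90.0)
    shape: tuple[int, int, int] = (32, 32, 32)
    d_min: float = 2.0

    def __post_init__(self):
        if len(self.cell_lengths) != 3 or len(self.cell_angles) != 3 or len(self.shape) != 3:
            raise ValueError("cell_lengths, cell_angles and shape must be triples")
        object.__setattr__(self, "cell_lengths", tuple(float(x) for x in self.cell_lengths))
        object.__setattr__(self, "cell_angles", tuple(float(x) for x in self.cell_angles))
        object.__setattr__(self, "shape", tuple(int(x) for x in self.shape))
        if any(a <= 0 for a in self.cell_lengths):
            raise ValueError("cell lengths must be positive")
        if any(not (0.0 < ang < 180.0) for ang in self.cell_angles):
            raise ValueError("cell angles must lie in (0, 180) degrees")
        if any(n < 2 for n in self.shape):
            raise ValueError("grid shape entries must be >= 2")
        if any(n % 2 for n in self.shape):
            raise ValueError("grid dimensions must be even")
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")
        for length, n in zip(self.cell_lengths, self.shape):
            if length / n > self.d_min / 2.0 + 1e-9:
                raise ValueError(
                    f"grid spacing {length / n:.3f} A exceeds d_min/2 = "
                    f"{self.d_min / 2.0:.3f} A; grid is not Shannon-adequate"
                )

    @property
    def gemmi_cell(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(*self.cell_lengths, *self.cell_angles)

    @property
    def volume(self) -> float:
        """Cell volume in cubic Angstrom."""
        return self.gemmi_cell.volume

    @property
    def n_grid(self) -> int:
        return int(np.prod(self.shape))

    @property
    def orthogonalization_matrix(self) -> np.ndarray:
        """3x3 matrix taking fractional to Cartesian (Angstrom) coordinates."""
        m = self.gemmi_cell.orth.mat
        return np.array(m.tolist(), dtype=float)

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d(h) in Angstrom for an (n, 3) array of Miller indices."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        # reciprocal-lattice vector s = (O^-1)^T h, d = 1/|s|
        frac = np.array(self.gemmi_cell.frac.mat.tolist(), dtype=float)
        s = hkl @ frac  # row h times O^-1 equals (O^-1)^T h as a row
        inv_d = np.linalg.norm(s, axis=1)
        with np.errstate(divide="ignore"):
            return np.where(inv_d > 0, 1.0 / inv_d, np.inf)


def _validate_reflection_table(df: pd.DataFrame, cell: UnitCellGrid) -> pd.DataFrame:
    df = df.copy()
    hkl = df[["h", "k", "l"]].to_numpy(dtype=int)
    if len(df) == 0:
        raise ValueError("empty reflection set")
    if np.any(np.all(hkl == 0, axis=1)):
        raise ValueError("(0,0,0) must not appear in the reflection list; F(000) is carried separately")
    keys = [tuple(row) for row in hkl]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate hkl in reflection set")
    neg = {tuple(-row) for row in hkl}
    both = neg.intersection(keys)
    if both:
        raise ValueError(f"both Friedel mates stored for {sorted(both)[0]}")
    if np.any(df["epsilon"].to_numpy() < 1):
        raise ValueError("epsilon factors must be >= 1")
    finite_F = df["F"].to_numpy(dtype=float)
    if np.any(finite_F[np.isfinite(finite_F)] < 0):
        raise ValueError("measured amplitudes must be non-negative")
    if np.any(df["d"].to_numpy() < cell.d_min - 1e-9):
        raise ValueError("reflection beyond the d_min resolution limit")
    # stable lexicographic order so replicate runs align term-by-term
    df = df.sort_values(["h", "k", "l"], kind="stable").reset_index(drop=True)
    return df


@dataclass
class ReflectionSet:
    """Ordered, validated collection of reflections on a common cell.

    The table is held as a pandas DataFrame with columns
    ``h k l F phi centric epsilon d is_measured``, sorted lexicographically
    by (h, k, l). ``phi`` is the reference phase in radians (NaN when
    absent) used only for scoring and corruption experiments.
    """

    table: pd.DataFrame
    cell: UnitCellGrid
    f000: float = 0.0

    def __post_init__(self):
        missing = [c for c in REFLECTION_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"reflection table missing columns {missing}")
        self.table = _validate_reflection_table(self.table[REFLECTION_COLUMNS], self.cell)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def hkl(self) -> np.ndarray:
        return self.table[["h", "k", "l"]].to_numpy(dtype=int)

    @property
    def amplitudes(self) -> np.ndarray:
        return self.table["F"].to_numpy(dtype=float)

    @property
    def phases(self) -> np.ndarray:
        return self.table["phi"].to_numpy(dtype=float)

    @property
    def centric(self) -> np.ndarray:
        return self.table["centric"].to_numpy(dtype=bool)

    @property
    def epsilon(self) -> np.ndarray:
        return self.table["epsilon"].to_numpy(dtype=float)

    @property
    def d(self) -> np.ndarray:
        return self.table["d"].to_numpy(dtype=float)

    @property
    def is_measured(self) -> np.ndarray:
        return self.table["is_measured"].to_numpy(dtype=bool)

    def with_columns(self, **cols) -> "ReflectionSet":
        """Return a copy with the given columns replaced."""
        table = self.table.copy()
        for name, values in cols.items():
            table[name] = values
        return ReflectionSet(table, self.cell, self.f000)

    def grid_indices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """FFT-grid indices of each stored reflection (h mod n along each axis)."""
        n1, n2, n3 = self.cell.shape
        hkl = self.hkl
        return hkl[:, 0] % n1, hkl[:, 1] % n2, hkl[:, 2] % n3


@dataclass
class DensityMap:
    """Real scalar density (or iterate surrogate) on the cell grid."""

    values: np.ndarray
    cell: UnitCellGrid

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.cell.shape):
            raise ValueError(f"map shape {self.values.shape} does not match grid {self.cell.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite map values")

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def hemisphere_hkl(cell: UnitCellGrid, d_min: float | None = None) -> np.ndarray:
    """Enumerate the unique Friedel hemisphere of grid frequencies with d >= d_min.

    One index of each Friedel pair is kept: (h,k,l) with h > 0, or h == 0 and
    k > 0, or h == k == 0 and l > 0. Nyquist frequencies (|h| = n/2), which are
    their own Friedel mates on the grid, are excluded.
    """
    if d_min is None:
        d_min = cell.d_min
    n1, n2, n3 = cell.shape
    h = np.arange(-(n1 // 2) + 1, n1 // 2)
    k = np.arange(-(n2 // 2) + 1, n2 // 2)
    l = np.arange(-(n3 // 2) + 1, n3 // 2)
    H, K, L = np.meshgrid(h, k, l, indexing="ij")
    hkl = np.stack([H.ravel(), K.ravel(), L.ravel()], axis=1)
    pos = (hkl[:, 0] > 0) | ((hkl[:, 0] == 0) & (hkl[:, 1] > 0)) | (
        (hkl[:, 0] == 0) & (hkl[:, 1] == 0) & (hkl[:, 2] > 0)
    )
    hkl = hkl[pos]
    d = cell.d_spacing(hkl)
    keep = d >= d_min - 1e-9
    order = np.lexsort((hkl[keep, 2], hkl[keep, 1], hkl[keep, 0]))
    return hkl[keep][order]


def full_transform(values: np.ndarray) -> np.ndarray:
    """Full-grid forward DFT, F(h) = sum_x rho(x) exp(+2 pi i h.x)."""
    return np.fft.ifftn(values) * values.size


def density_to_structure_factors(dmap: DensityMap, refl: ReflectionSet) -> np.ndarray:
    """Structure factors F(h) of a map at the stored reflections.

    Returns a complex array aligned with the reflection order. Friedel mates
    are implied by the real-valued input and are not returned explicitly.
    """
    if dmap.cell != refl.cell:
        raise ValueError("map and reflection set are on different cells")
    fgrid = full_transform(dmap.values)
    i, j, k = refl.grid_indices()
    return fgrid[i, j, k]


def structure_factors_to_density(
    coeffs: np.ndarray,
    refl: ReflectionSet,
    cell: UnitCellGrid | None = None,
    f000: float | None = None,
) -> DensityMap:
    """Fourier synthesis of a real map from one Friedel hemisphere of coefficients.

    Coefficients must be supplied for every stored reflection (zero-filled
    explicitly if unknown); the Friedel mate of each term is completed
    internally so the synthesized map is real.
    """
    if cell is None:
        cell = refl.cell
    coeffs = np.asarray(coeffs, dtype=complex)
    if coeffs.shape != (len(refl),):
        raise ValueError(
            f"need one coefficient per stored reflection ({len(refl)}), got shape {coeffs.shape}"
        )
    if not np.all(np.isfinite(coeffs)):
        raise ValueError("non-finite coefficients")
    if f000 is None:
        f000 = refl.f000
    n1, n2, n3 = cell.shape
    fgrid = np.zeros(cell.shape, dtype=complex)
    hkl = refl.hkl
    i, j, k = hkl[:, 0] % n1, hkl[:, 1] % n2, hkl[:, 2] % n3
    fgrid[i, j, k] = coeffs
    im, jm, km = (-hkl[:, 0]) % n1, (-hkl[:, 1]) % n2, (-hkl[:, 2]) % n3
    fgrid[im, jm, km] = np.conj(coeffs)
    fgrid[0, 0, 0] = f000
    values = np.fft.fftn(fgrid) / fgrid.size
    return DensityMap(values.real.copy(), cell)


def assign_epsilon(refl: ReflectionSet, epsilon: np.ndarray | None = None) -> ReflectionSet:
    """Attach statistical degeneracy factors epsilon(h).

    In P1 with Friedel symmetry there is no point-group degeneracy, so
    epsilon = 1 everywhere. For data imported from a higher-symmetry space
    group a precomputed epsilon column may be passed through unchanged.
    """
    if epsilon is None:
        eps = np.ones(len(refl), dtype=int)
    else:
        eps = np.asarray(epsilon)
        if eps.shape != (len(refl),):
            raise ValueError("epsilon column length does not match reflection set")
        if np.any(eps <= 0):
            raise ValueError("imported epsilon factors must be positive")
    return refl.with_columns(epsilon=eps)


def resolution_shells(refl: ReflectionSet, n_shells: int) -> tuple[np.ndarray, pd.DataFrame]:
    """Bin reflections into shells of (approximately) equal count in 1/d^3.

    Returns the shell index of every reflection (0 = lowest resolution) and
    a table of shell boundaries in Angstrom. A reflection falling exactly on
    a boundary is assigned to the lower-resolution (smaller 1/d) shell.
    """
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    n = len(refl)
    if n < n_shells:
        raise ValueError(f"cannot form {n_shells} shells from {n} reflections")
    s3 = 1.0 / refl.d**3
    order = np.sort(s3)
    # inner edges: the largest 1/d^3 belonging to each shell but the last
    cuts = [int(np.ceil(n * (j + 1) / n_shells)) - 1 for j in range(n_shells - 1)]
    edges = order[cuts]
    shell = np.searchsorted(edges, s3, side="left")
    rows = []
    for j in range(n_shells):
        sel = shell == j
        dsel = refl.d[sel]
        rows.append(
            {
                "shell": j,
                "d_max": float(dsel.max()) if sel.any() else np.nan,
                "d_min": float(dsel.min()) if sel.any() else np.nan,
                "count": int(sel.sum()),
            }
        )
    return shell, pd.DataFrame(rows)
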