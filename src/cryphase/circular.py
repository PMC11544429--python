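"""Circular agreement statistics and parametric summaries of phase samples.

Phases are angles on the circle; all differences are computed on the circle
(via trigonometric construction), never as raw subtraction. Summations over
an asymmetric unit accept statistical degeneracy weights epsilon(h); in P1
these are identically 1 and the weighted forms reduce to the plain ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

__all__ = [
    "CircularSummary",
    "AmplitudeSummary",
    "wrapped_difference",
    "mean_abs_phase_diff",
    "map_correlation",
    "fisher_lee_correlation",
    "circular_moments",
    "fit_von_mises_kappa",
    "bessel_ratio",
    "von_mises_pdf",
    "fit_joint_sf_pdf",
    "JointSFDensity",
]

KAPPA_MAX = 1.0e4


@dataclass
class CircularSummary:
    """First trigonometric moment of a circular sample, in polar form.

    ``mean_direction`` is undefined when the mean length is (numerically)
    zero; the condition is flagged rather than silently zeroed so that
    downstream Fourier synthesis can drop the term.
    """

    mean_direction: float
    mean_length: float
    n: int
    kappa: float | None = None
    direction_defined: bool = True


@dataclass
class AmplitudeSummary:
    """Gaussian summary (sample mean and SD) of an amplitude trajectory."""

    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def wrap_angle(phi: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    phi = np.asarray(phi, dtype=float)
    out = np.mod(-phi + np.pi, 2.0 * np.pi)
    return np.pi - out


def wrapped_difference(phi1: np.ndarray, phi2: np.ndarray) -> np.ndarray:
    """Signed circular difference phi1 - phi2 in (-pi, pi]."""
    phi1 = np.asarray(phi1, dtype=float)
    phi2 = np.asarray(phi2, dtype=float)
    return np.arctan2(np.sin(phi1 - phi2), np.cos(phi1 - phi2))


def mean_abs_phase_diff(
    phases1: np.ndarray, phases2: np.ndarray, epsilon_weights: np.ndarray | None = None
) -> float:
    """Mean absolute (unsigned) phase difference in degrees.

    Each difference is placed in [0, pi] via the four-quadrant construction
    before averaging; with weights the epsilon-weighted mean is returned.
    """
    phases1 = np.asarray(phases1, dtype=float)
    phases2 = np.asarray(phases2, dtype=float)
    if phases1.size == 0 or phases1.shape != phases2.shape:
        raise ValueError("phase sets must be non-empty and aligned")
    d = np.abs(wrapped_difference(phases1, phases2))
    if epsilon_weights is None:
        m = d.mean()
    else:
        w = np.asarray(epsilon_weights, dtype=float)
        m = np.sum(w * d) / np.sum(w)
    return float(np.degrees(m))


def map_correlation(
    F1: np.ndarray,
    F2: np.ndarray,
    dphi: np.ndarray,
    epsilon_weights: np.ndarray | None = None,
) -> float:
    """Real-space Pearson correlation of two maps from Fourier data.

    Computed in the amplitude/phase-difference form
    sum eps * F1 * F2 * cos(dphi) / sqrt(sum eps F1^2 * sum eps F2^2),
    with the F(000) term excluded; equal to the voxel-space Pearson
    correlation of the two synthesized maps.
    """
    F1 = np.asarray(F1, dtype=float)
    F2 = np.asarray(F2, dtype=float)
    dphi = np.asarray(dphi, dtype=float)
    w = np.ones_like(F1) if epsilon_weights is None else np.asarray(epsilon_weights, dtype=float)
    v1 = np.sum(w * F1**2)
    v2 = np.sum(w * F2**2)
    if v1 <= 0 or v2 <= 0:
        raise ValueError("zero-variance map in correlation")
    return float(np.sum(w * F1 * F2 * np.cos(dphi)) / np.sqrt(v1 * v2))


def fisher_lee_correlation(
    phases1: np.ndarray, phases2: np.ndarray, epsilon_weights: np.ndarray | None = None
) -> float:
    """Fisher-Lee circular correlation coefficient between two phase sets.

    Uses the O(n) expansion of the pairwise estimator through the auxiliary
    trigonometric sums; +1 indicates positive association, 0 independence.
    The statistic is invariant to independent constant rotation of either
    phase set. Undefined (raises) when either sample has no angular spread.
    """
    p1 = np.asarray(phases1, dtype=float)
    p2 = np.asarray(phases2, dtype=float)
    if p1.size < 3 or p1.shape != p2.shape:
        raise ValueError("need at least 3 aligned phase pairs")
    w = np.ones_like(p1) if epsilon_weights is None else np.asarray(epsilon_weights, dtype=float)
    n = np.sum(w)
    A = np.sum(w * np.cos(p1) * np.cos(p2))
    B = np.sum(w * np.sin(p1) * np.sin(p2))
    C = np.sum(w * np.cos(p1) * np.sin(p2))
    D = np.sum(w * np.sin(p1) * np.cos(p2))
    E = np.sum(w * np.cos(2.0 * p1))
    Fs = np.sum(w * np.sin(2.0 * p1))
    G = np.sum(w * np.cos(2.0 * p2))
    H = np.sum(w * np.sin(2.0 * p2))
    denom_sq = (n**2 - E**2 - Fs**2) * (n**2 - G**2 - H**2)
    if denom_sq <= 1e-12 * n**4:
        raise ValueError("degenerate phase set: circular correlation undefined")
    return float(4.0 * (A * B - C * D) / np.sqrt(denom_sq))


def circular_moments(phases: np.ndarray, epsilon_weights: np.ndarray | None = None) -> CircularSummary:
    """Sample mean length and mean direction of a circular sample.

    The mean direction is obtained with the four-quadrant inverse tangent of
    the component sums. When the mean length vanishes the direction is
    undefined and the summary is flagged accordingly.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size < 1:
        raise ValueError("empty phase sample")
    w = np.ones_like(phases) if epsilon_weights is None else np.asarray(epsilon_weights, dtype=float)
    W = np.sum(w)
    C = np.sum(w * np.cos(phases)) / W
    S = np.sum(w * np.sin(phases)) / W
    R = float(np.hypot(C, S))
    if R < 1e-12:
        return CircularSummary(np.nan, R, int(phases.size), direction_defined=False)
    return CircularSummary(float(np.arctan2(S, C)), R, int(phases.size))


def bessel_ratio(kappa: np.ndarray) -> np.ndarray:
    """A(kappa) = I1(kappa)/I0(kappa), the von Mises mean resultant length."""
    kappa = np.asarray(kappa, dtype=float)
    return i1e(kappa) / i0e(kappa)


def fit_von_mises_kappa(r_bar: float, n: int | None = None) -> float:
    """Maximum-likelihood von Mises concentration: solve A(kappa) = R-bar.

    Monotone in R-bar; returns 0 at R-bar = 0 and is capped at 1e4 as
    R-bar approaches 1 (where the MLE diverges).
    """
    if not (0.0 <= r_bar):
        raise ValueError("mean resultant length must be non-negative")
    if r_bar >= 1.0:
        import warnings

        warnings.warn("mean resultant length >= 1; concentration capped", stacklevel=2)
        return KAPPA_MAX
    if r_bar == 0.0:
        return 0.0
    if bessel_ratio(KAPPA_MAX) <= r_bar:
        return KAPPA_MAX
    return float(brentq(lambda k: bessel_ratio(k) - r_bar, 0.0, KAPPA_MAX, xtol=1e-10, rtol=1e-12))


def von_mises_pdf(phi: np.ndarray, mu: float, kappa: float) -> np.ndarray:
    """von Mises density on (-pi, pi] (exponentially-scaled Bessel for stability)."""
    phi = np.asarray(phi, dtype=float)
    return np.exp(kappa * (np.cos(phi - mu) - 1.0)) / (2.0 * np.pi * i0e(kappa))


@dataclass
class JointSFDensity:
    """Independent Gaussian-amplitude x von Mises-phase joint density.

    Models the stationary fluctuation of one structure factor: amplitude
    F ~ N(mu, sigma^2), phase phi ~ von Mises(mu_vm, kappa), independent.
    Degenerate when sigma = 0 (flagged; the density is then singular in F).
    """

    amplitude: AmplitudeSummary
    phase: CircularSummary

    @property
    def degenerate(self) -> bool:
        return self.amplitude.sigma == 0.0

    def pdf(self, F: np.ndarray, phi: np.ndarray) -> np.ndarray:
        if self.degenerate:
            raise ValueError("degenerate joint density: zero amplitude variance")
        F = np.asarray(F, dtype=float)
        g = np.exp(-0.5 * ((F - self.amplitude.mu) / self.amplitude.sigma) ** 2) / (
            self.amplitude.sigma * np.sqrt(2.0 * np.pi)
        )
        mu_vm = self.phase.mean_direction if self.phase.direction_defined else 0.0
        return g * von_mises_pdf(phi, mu_vm, self.phase.kappa)


def fit_joint_sf_pdf(amplitudes: np.ndarray, phases: np.ndarray) -> JointSFDensity:
    """Fit the joint structure-factor density over one trajectory window.

    Gaussian parameters are the sample mean/SD of the amplitudes; von Mises
    parameters are the sample mean direction and the maximum-likelihood
    concentration from the sample mean length.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    phases = np.asarray(phases, dtype=float)
    if amplitudes.size < 3 or amplitudes.shape != phases.shape:
        raise ValueError("need an aligned window of at least 3 points")
    amp = AmplitudeSummary(float(amplitudes.mean()), float(amplitudes.std(ddof=1)))
    summ = circular_moments(phases)
    kappa = fit_von_mises_kappa(min(summ.mean_length, 1.0 - 1e-12), summ.n)
    summ.kappa = kappa
    return JointSFDensity(amp, summ)
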