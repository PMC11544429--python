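"""Iterative projection algorithms (IPAs) and the fixed-length run loop.

Five update rules are provided, each acting on the iterate x_n through the
two constraint projections P_A (real space) and P_B (Fourier space):

* **ER** (error reduction / Gerchberg-Saxton): x' = P_A P_B x — classical
  density modification. Converges only locally.
* **DM** (difference map, one-parameter form with the estimate maps tied to
  1/beta): x' = x + beta * [P_A f_B(x) - P_B f_A(x)] with
  f_A(x) = (1 - 1/beta) P_A x + (1/beta) x and
  f_B(x) = (1 + 1/beta) P_B x - (1/beta) x. Changing the sign of beta swaps
  the roles of the two constraints. Not defined at beta = 0.
* **RRR** (relaxed-reflect-reflect): x' = x + beta * [P_A(2 P_B x - x) - P_B x].
  At beta = 1 this is the Douglas-Rachford iteration. Half the per-iteration
  cost of DM (two projection applications instead of four).
* **revRRR**: the RRR rule with the two projections interchanged,
  x' = x + beta * [P_B(2 P_A x - x) - P_A x].
* **RAAR** (relaxed averaged alternating reflections):
  x' = beta * [x + P_B(2 P_A x - x)] + (1 - 2 beta) * P_A x, which at
  beta = 1 coincides with revRRR at beta = 1.

For DM, RRR, revRRR and RAAR the iterate is a surrogate that is not itself a
density estimate; each update yields two solution estimates, one satisfying
the real-space constraints exactly (estimate A) and one satisfying the
Fourier-space constraints exactly (estimate B). At a fixed point the two
estimates coincide and represent a solution. For RAAR with beta != 1 the
estimate is computed with the revRRR estimate formula P_B(2 P_A x - x) as a
pragmatic choice.

Runs are fixed-length (no early stopping); the molecular envelope used by
P_A is re-estimated once per iteration from the monitored solution estimate.
In P1 the constraints are invariant under lattice translations, so the
re-estimated envelope is registered against the run's initial envelope
(``anchor_origin``) to pin the otherwise-free origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .circular import map_correlation, wrapped_difference
from .projections import (
    DensityPrior,
    Envelope,
    FourierConstraint,
    estimate_envelope,
    project_real,
    register_envelope,
)
from .reciprocal import DensityMap, ReflectionSet, structure_factors_to_density

logger = logging.getLogger(__name__)

__all__ = [
    "AlgorithmConfig",
    "IterateState",
    "TrajectoryRecord",
    "er_update",
    "dm_update",
    "dm_estimates",
    "rrr_update",
    "revrrr_update",
    "raar_update",
    "algorithm_step",
    "run",
    "ALGORITHMS",
]

Projection = Callable[[np.ndarray], np.ndarray]

ALGORITHMS = ("ER", "DM", "RRR", "revRRR", "RAAR")


def _validate_beta(name: str, beta: float | None) -> None:
    if name == "ER":
        return
    if beta is None:
        raise ValueError(f"{name} requires an adjustable parameter beta")
    if name == "DM":
        if beta == 0.0:
            raise ValueError("the DM algorithm is not defined when beta = 0")
        if not (-1.0 < beta < 1.0):
            raise ValueError("DM requires beta in (-1, 1)")
    elif name in ("RRR", "revRRR"):
        if not (0.0 < beta < 2.0):
            raise ValueError(f"{name} requires beta in (0, 2)")
    elif name == "RAAR":
        if not (0.0 < beta <= 1.0):
            raise ValueError("RAAR requires beta in (0, 1]")
    else:
        raise ValueError(f"unknown algorithm {name!r}")


@dataclass
class AlgorithmConfig:
    """Configuration of a phase-retrieval run.

    ``monitored_estimate`` selects which per-iteration solution estimate is
    recorded and scored: "A" (satisfies the real-space constraints exactly)
    or "B" (satisfies the Fourier amplitude constraints exactly).
    """

    name: str = "RRR"
    beta: float | None = 0.8
    n_iterations: int = 150
    envelope_update: bool = True
    anchor_origin: bool = True
    monitored_estimate: str = "B"
    seed: int = 0
    trailing_window: int = 30
    thin: int = 0  # keep every thin-th iteration of the full run (0 = none)
    solvent_fraction: float | None = None  # None: taken from the supplied envelope
    window_radius: float = 4.0
    wilson_cap: float = 2.0

    def __post_init__(self):
        if self.name not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.name!r}; choose from {ALGORITHMS}")
        _validate_beta(self.name, self.beta)
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.monitored_estimate not in ("A", "B"):
            raise ValueError("monitored_estimate must be 'A' or 'B'")


@dataclass
class IterateState:
    """The surrogate iterate and the two constraint-satisfying estimates."""

    x: np.ndarray
    iteration: int
    envelope: Envelope
    estimate_A: np.ndarray
    estimate_B: np.ndarray


def er_update(x: np.ndarray, PA: Projection, PB: Projection):
    """One ER iteration: sequential composition of the two projections."""
    est_B = PB(x)
    est_A = PA(est_B)
    return est_A, est_A, est_B


def dm_update(x: np.ndarray, PA: Projection, PB: Projection, beta: float):
    """One DM iteration; returns (x', estimate_A, estimate_B)."""
    est_A, est_B = dm_estimates(x, PA, PB, beta)
    return x + beta * (est_A - est_B), est_A, est_B


def dm_estimates(x: np.ndarray, PA: Projection, PB: Projection, beta: float):
    """The two DM solution estimates (constraint-A- and constraint-B-satisfying)."""
    _validate_beta("DM", beta)
    g = 1.0 / beta
    fB = (1.0 + g) * PB(x) - g * x
    fA = (1.0 - g) * PA(x) + g * x
    return PA(fB), PB(fA)


def rrr_update(x: np.ndarray, PA: Projection, PB: Projection, beta: float):
    """One RRR iteration; returns (x', estimate_A, estimate_B)."""
    _validate_beta("RRR", beta)
    est_B = PB(x)
    est_A = PA(2.0 * est_B - x)
    return x + beta * (est_A - est_B), est_A, est_B


def revrrr_update(x: np.ndarray, PA: Projection, PB: Projection, beta: float):
    """One reversed-RRR iteration (projection roles interchanged)."""
    _validate_beta("revRRR", beta)
    est_A = PA(x)
    est_B = PB(2.0 * est_A - x)
    return x + beta * (est_B - est_A), est_A, est_B


def raar_update(x: np.ndarray, PA: Projection, PB: Projection, beta: float):
    """One RAAR iteration; at beta = 1 identical to revRRR with beta = 1.

    The solution estimate uses the revRRR estimate formula P_B(2 P_A x - x)
    for every beta, since for beta != 1 the iterate admits no exact estimate.
    """
    _validate_beta("RAAR", beta)
    est_A = PA(x)
    est_B = PB(2.0 * est_A - x)
    return beta * (x + est_B) + (1.0 - 2.0 * beta) * est_A, est_A, est_B


def algorithm_step(name: str, x: np.ndarray, PA: Projection, PB: Projection, beta: float | None):
    """Dispatch one iteration of the named algorithm."""
    if name == "ER":
        return er_update(x, PA, PB)
    if name == "DM":
        return dm_update(x, PA, PB, beta)
    if name == "RRR":
        return rrr_update(x, PA, PB, beta)
    if name == "revRRR":
        return revrrr_update(x, PA, PB, beta)
    if name == "RAAR":
        return raar_update(x, PA, PB, beta)
    raise ValueError(f"unknown algorithm {name!r}")


@dataclass
class TrajectoryRecord:
    """Per-iteration structure factors of the monitored estimate plus metrics.

    ``coeffs`` holds the complex structure factors of the monitored solution
    estimate over the trailing window (rows = iterations, oldest first),
    aligned with the reflection-set ordering. ``metrics`` has one row per
    iteration with the real-space correlation against the reference (when
    reference phases are available). ``thinned`` optionally keeps a
    decimated full-run record for plotting.
    """

    refl: ReflectionSet
    config: AlgorithmConfig
    coeffs: np.ndarray
    coeff_iterations: np.ndarray
    metrics: pd.DataFrame
    final_estimate_A: DensityMap
    final_estimate_B: DensityMap
    final_envelope: Envelope
    thinned: np.ndarray | None = None
    thinned_iterations: np.ndarray | None = None

    @property
    def n_iterations(self) -> int:
        return len(self.metrics)

    @property
    def final_correlation(self) -> float:
        return float(self.metrics["correlation"].iloc[-1])


def _reference_correlation(coeffs: np.ndarray, refl: ReflectionSet, eps: np.ndarray) -> float:
    """Real-space correlation (amplitude/phase-difference form) vs the reference."""
    ref_phi = refl.phases
    if np.any(~np.isfinite(ref_phi)):
        return np.nan
    F_ref = refl.amplitudes
    ok = np.isfinite(F_ref)
    dphi = wrapped_difference(np.angle(coeffs[ok]), ref_phi[ok])
    return map_correlation(np.abs(coeffs[ok]), F_ref[ok], dphi, eps[ok])


def run(
    start: DensityMap | np.ndarray,
    refl: ReflectionSet,
    config: AlgorithmConfig,
    prior: DensityPrior,
    envelope: Envelope | None = None,
    solvent_fraction: float | None = None,
) -> TrajectoryRecord:
    """Execute a fixed number of IPA iterations and record the trajectory.

    Parameters
    ----------
    start : DensityMap or complex array
        Starting iterate. A complex array of length ``len(refl)`` is taken
        as starting structure factors (e.g. measured amplitudes with
        corrupted phases) and synthesized into a map.
    refl : ReflectionSet
        Measured amplitudes, reference phases (optional, for scoring) and
        geometry. F(000) is taken from ``refl.f000``.
    config : AlgorithmConfig
    prior : DensityPrior
        Protein-region reference histogram and solvent level for P_A.
    envelope : Envelope, optional
        Envelope used at iteration 0. When absent it is estimated from the
        starting map. Re-estimated each iteration from the monitored
        estimate when ``config.envelope_update`` is set.
    solvent_fraction : float, optional
        Target solvent fraction for envelope re-estimation; defaults to the
        supplied envelope's target.
    """
    cell = refl.cell
    if isinstance(start, DensityMap):
        if start.cell != cell:
            raise ValueError("starting map and reflections are on different cells")
        x = start.values.copy()
    else:
        start = np.asarray(start)
        if np.iscomplexobj(start) and start.shape == (len(refl),):
            x = structure_factors_to_density(start, refl).values
        else:
            raise ValueError("start must be a DensityMap or per-reflection complex coefficients")

    frac = solvent_fraction if solvent_fraction is not None else config.solvent_fraction
    if envelope is None:
        if frac is None:
            raise ValueError("need either an envelope or a solvent fraction")
        envelope = estimate_envelope(DensityMap(x, cell), frac, config.window_radius)
    if frac is None:
        frac = envelope.solvent_fraction_target
    anchor = envelope

    PB = FourierConstraint(refl, wilson_cap=config.wilson_cap)
    eps = refl.epsilon
    window = min(config.trailing_window, config.n_iterations)
    n_refl = len(refl)
    coeff_buffer: list[np.ndarray] = []
    coeff_iters: list[int] = []
    thinned: list[np.ndarray] = []
    thinned_iters: list[int] = []
    rows = []

    est_A = est_B = x
    for it in range(1, config.n_iterations + 1):
        env_mask = envelope  # envelope fixed during the iteration

        def PA(v: np.ndarray) -> np.ndarray:
            return project_real(DensityMap(v, cell), env_mask, prior).values

        x, est_A, est_B = algorithm_step(config.name, x, PA, PB, config.beta)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(
                f"{config.name} iterate diverged (non-finite values) at iteration {it}"
            )
        monitored = est_A if config.monitored_estimate == "A" else est_B
        mon_coeffs = (np.fft.ifftn(monitored) * monitored.size)[PB._pos]
        corr = _reference_correlation(mon_coeffs, refl, eps)
        rows.append({"iteration": it, "correlation": corr})
        logger.info("%s iter %d correlation %.4f", config.name, it, corr)

        coeff_buffer.append(mon_coeffs)
        coeff_iters.append(it)
        if len(coeff_buffer) > window:
            coeff_buffer.pop(0)
            coeff_iters.pop(0)
        if config.thin and it % config.thin == 0:
            thinned.append(mon_coeffs)
            thinned_iters.append(it)

        if config.envelope_update:
            envelope = estimate_envelope(DensityMap(monitored, cell), frac, config.window_radius)
            if config.anchor_origin:
                # pin the P1 translational gauge to the run's initial envelope
                envelope, _ = register_envelope(envelope, anchor)

    return TrajectoryRecord(
        refl=refl,
        config=config,
        coeffs=np.array(coeff_buffer),
        coeff_iterations=np.array(coeff_iters),
        metrics=pd.DataFrame(rows),
        final_estimate_A=DensityMap(est_A, cell),
        final_estimate_B=DensityMap(est_B, cell),
        final_envelope=envelope,
        thinned=np.array(thinned) if thinned else None,
        thinned_iterations=np.array(thinned_iters) if thinned_iters else None,
    )
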