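"""Post-convergence exploitation of the algorithm trajectory.

Once an IPA has converged, the iterate keeps fluctuating about a stationary
mean because the constraints cannot all be satisfied simultaneously and
exactly. The structure-factor trajectory over a trailing window then holds
usable information: per-reflection circular averaging of the phases yields
a better Fourier synthesis than the single final iterate, and the
phase-retrieval transfer function (PRTF) summarizes phase reliability as a
function of resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import circular_moments, wrapped_difference
from .engine import AlgorithmConfig, TrajectoryRecord, run
from .projections import DensityPrior, Envelope
from .reciprocal import DensityMap, ReflectionSet, resolution_shells, structure_factors_to_density

__all__ = [
    "trajectory_summaries",
    "synthesize_averaged_map",
    "er_polish",
    "prtf",
    "stationarity_report",
    "StationarityReport",
]


def trajectory_summaries(record: TrajectoryRecord, window: int | None = None) -> pd.DataFrame:
    """Nonparametric per-reflection summaries over the trailing window.

    For each reflection the sample mean direction and mean length of the
    phase trajectory and the mean/SD of the amplitude trajectory are
    computed over the last ``window`` recorded iterations. Valid for
    centric and acentric terms alike.

    Returns a DataFrame aligned with the reflection order, with columns
    ``h k l mean_direction mean_length amp_mean amp_sd n direction_defined``.
    """
    stored = record.coeffs.shape[0]
    if window is None:
        window = stored
    if window < 2:
        raise ValueError("summary window must span at least 2 iterations")
    if window > stored:
        raise ValueError(f"window {window} exceeds stored trailing window {stored}")
    coeffs = record.coeffs[-window:]
    amps = np.abs(coeffs)
    C = np.cos(np.angle(coeffs)).mean(axis=0)
    S = np.sin(np.angle(coeffs)).mean(axis=0)
    R = np.hypot(C, S)
    defined = R >= 1e-12
    direction = np.where(defined, np.arctan2(S, C), np.nan)
    hkl = record.refl.hkl
    return pd.DataFrame(
        {
            "h": hkl[:, 0],
            "k": hkl[:, 1],
            "l": hkl[:, 2],
            "mean_direction": direction,
            "mean_length": R,
            "amp_mean": amps.mean(axis=0),
            "amp_sd": amps.std(axis=0, ddof=1),
            "n": window,
            "direction_defined": defined,
        }
    )


def synthesize_averaged_map(
    summaries: pd.DataFrame,
    refl: ReflectionSet,
    mode: str = "unweighted",
) -> DensityMap:
    """Fourier synthesis using trajectory mean directions as phases.

    mode "unweighted": amplitude = measured amplitude; mode "weighted":
    amplitude = mean length x measured amplitude. Reflections whose mean
    direction is undefined (or amplitude unmeasured) enter with weight 0.
    """
    if mode not in ("unweighted", "weighted"):
        raise ValueError("mode must be 'unweighted' or 'weighted'")
    if len(summaries) != len(refl):
        raise ValueError("summaries are not aligned with the reflection set")
    F = np.where(refl.is_measured & np.isfinite(refl.amplitudes), refl.amplitudes, 0.0)
    phase = summaries["mean_direction"].to_numpy(dtype=float)
    R = summaries["mean_length"].to_numpy(dtype=float)
    defined = summaries["direction_defined"].to_numpy(dtype=bool)
    amp = F * (R if mode == "weighted" else 1.0)
    coeffs = np.where(defined, amp * np.exp(1j * np.where(defined, phase, 0.0)), 0.0)
    return structure_factors_to_density(coeffs, refl)


def er_polish(
    final_estimate: DensityMap,
    refl: ReflectionSet,
    prior: DensityPrior,
    envelope: Envelope | None = None,
    n_iter: int = 30,
    solvent_fraction: float | None = None,
    monitored_estimate: str = "A",
) -> DensityMap:
    """Damp post-convergence fluctuations with a short ER run.

    Deterministic given its input; serves as the comparison baseline for
    trajectory averaging. Returns the monitored solution estimate after
    ``n_iter`` ER iterations.
    """
    config = AlgorithmConfig(
        name="ER",
        beta=None,
        n_iterations=n_iter,
        envelope_update=True,
        monitored_estimate=monitored_estimate,
        trailing_window=1,
    )
    rec = run(final_estimate, refl, config, prior, envelope=envelope, solvent_fraction=solvent_fraction)
    return rec.final_estimate_A if monitored_estimate == "A" else rec.final_estimate_B


def prtf(
    record: TrajectoryRecord,
    window: int | None = None,
    n_shells: int = 8,
) -> tuple[pd.Series, pd.DataFrame]:
    """Phase-retrieval transfer function per reflection and per resolution shell.

    Per reflection: |mean over the window of the reconstructed complex
    coefficients| / measured amplitude. Shell means are epsilon-weighted.
    Values may slightly exceed 1 when reconstructed amplitudes exceed the
    measured ones; they are reported unclipped. Reflections with zero or
    unmeasured amplitude are excluded from the shell means and counted.
    """
    stored = record.coeffs.shape[0]
    if window is None:
        window = stored
    if not (1 <= window <= stored):
        raise ValueError(f"window must lie in [1, {stored}]")
    refl = record.refl
    mean_coeff = record.coeffs[-window:].mean(axis=0)
    F = refl.amplitudes
    usable = refl.is_measured & np.isfinite(F) & (F > 0)
    per_reflection = pd.Series(
        np.where(usable, np.abs(mean_coeff) / np.where(usable, F, 1.0), np.nan), name="prtf"
    )
    shell, bounds = resolution_shells(refl, n_shells)
    eps = refl.epsilon
    rows = []
    for j in range(n_shells):
        sel = (shell == j) & usable
        excluded = int(((shell == j) & ~usable).sum())
        if sel.any():
            val = float(np.sum(eps[sel] * per_reflection[sel]) / np.sum(eps[sel]))
        else:
            val = np.nan
        rows.append(
            {
                "shell": j,
                "d_max": bounds.loc[j, "d_max"],
                "d_min": bounds.loc[j, "d_min"],
                "prtf": val,
                "count": int(sel.sum()),
                "excluded": excluded,
            }
        )
    return per_reflection, pd.DataFrame(rows)


@dataclass
class StationarityReport:
    """Half-window drift diagnostics for one run."""

    stationary: bool
    mean_direction_drift: float  # radians, mean over reflections
    metric_drift: float  # change in mean global correlation between half-windows
    per_reflection_drift: pd.Series


def stationarity_report(record: TrajectoryRecord, drift_threshold: float = 0.1) -> StationarityReport:
    """Flag whether the recorded trailing window is stationary.

    The window is split in half; for each reflection the circular distance
    between the half-window mean directions is computed. The summary drift
    is the amplitude- and reliability-weighted mean of these distances
    (weights: measured amplitude times the smaller half-window mean length),
    which is what the Fourier synthesis is sensitive to — an unweighted mean
    would be dominated by weak terms whose phases fluctuate freely even at
    stationarity. The run is flagged stationary when the weighted drift is
    below the threshold (default 0.1 rad); per-reflection (unweighted)
    drifts and the global-metric drift between half-windows are reported
    alongside. Purely diagnostic — runs are always fixed-length.
    """
    stored = record.coeffs.shape[0]
    if stored < 4:
        raise ValueError("need a trailing window of at least 4 iterations (two half-windows)")
    half = stored // 2
    first, second = record.coeffs[:half], record.coeffs[half : 2 * half]

    def moments(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        C = np.cos(np.angle(block)).mean(axis=0)
        S = np.sin(np.angle(block)).mean(axis=0)
        return np.arctan2(S, C), np.hypot(C, S)

    d1, r1 = moments(first)
    d2, r2 = moments(second)
    drift = np.abs(wrapped_difference(d1, d2))
    refl = record.refl
    F = np.where(refl.is_measured & np.isfinite(refl.amplitudes), refl.amplitudes, 0.0)
    w = F * np.minimum(r1, r2)
    mean_drift = float(np.sum(w * drift) / np.sum(w)) if np.sum(w) > 0 else float(drift.mean())
    corr = record.metrics["correlation"].to_numpy()
    tail = corr[-2 * half :]
    metric_drift = float(np.nanmean(tail[half:]) - np.nanmean(tail[:half]))
    return StationarityReport(
        stationary=mean_drift < drift_threshold,
        mean_direction_drift=mean_drift,
        metric_drift=metric_drift,
        per_reflection_drift=pd.Series(drift, name="direction_drift"),
    )
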