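"""Controlled corruption of reference phases with circular error distributions.

Acentric phases (unrestricted) are replaced by von Mises random variates
centred on the reference phase; centric phases (restricted to a two-point
set) are flipped by pi with a Bernoulli probability. Both distributions are
parameterized by a single circular variance V in [0, 1]:

* von Mises: V = 1 - I1(kappa)/I0(kappa), solved for the concentration
  kappa by bracketed root finding.
* wrapped Bernoulli on {phi_m, phi_m + pi} with probabilities (p, 1-p):
  the mean resultant length is |2p - 1|, so V = 1 - |2p - 1| and p = 1 - V/2
  (taking p >= 1/2). p = 1 introduces no error; p = 0.5 fully randomizes.

The same error distribution is applied to every reflection regardless of
amplitude or resolution. Randomness is drawn from per-reflection substreams
keyed by (seed, h, k, l), so corruption commutes with reflection reordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circular import bessel_ratio, wrap_angle
from .reciprocal import ReflectionSet

__all__ = [
    "ErrorSpec",
    "kappa_from_variance",
    "p_from_variance",
    "sample_von_mises",
    "corrupt_phases",
]


def kappa_from_variance(V: float) -> float:
    """von Mises concentration with circular variance V, 0 < V <= 1.

    Solves 1 - I1(kappa)/I0(kappa) = V. V = 1 gives kappa = 0 (uniform
    limit); V <= 0 would require infinite concentration and is rejected —
    callers must special-case exact phases.
    """
    if not (0.0 < V <= 1.0):
        raise ValueError("circular variance must lie in (0, 1]; V <= 0 implies infinite kappa")
    if V == 1.0:
        return 0.0
    if V < 1e-3:
        # asymptotic branch: A(kappa) ~ 1 - 1/(2 kappa) for large kappa
        return 1.0 / (2.0 * V)
    from scipy.optimize import brentq

    return float(brentq(lambda k: (1.0 - bessel_ratio(k)) - V, 1e-8, 1e4, xtol=1e-12, rtol=1e-12))


def p_from_variance(V: float) -> float:
    """Bernoulli probability p >= 1/2 whose wrapped two-point distribution has circular variance V."""
    if not (0.0 <= V <= 1.0):
        raise ValueError("circular variance must lie in [0, 1]")
    return 1.0 - V / 2.0


@dataclass
class ErrorSpec:
    """Phase-error specification at a single circular variance.

    kappa (acentric von Mises concentration) and p (centric flip-retention
    probability) are derived from V on construction.
    """

    circular_variance: float
    seed: int = 0
    kappa: float = field(init=False)
    p_centric: float = field(init=False)

    def __post_init__(self):
        V = self.circular_variance
        if not (0.0 <= V <= 1.0):
            raise ValueError("circular variance must lie in [0, 1]")
        self.kappa = np.inf if V == 0.0 else kappa_from_variance(V)
        self.p_centric = p_from_variance(V)


def _best_fisher_block(kappa: float, u: np.ndarray) -> np.ndarray:
    """Vectorized Best-Fisher rejection sampling of von Mises(0, kappa).

    ``u`` has shape (n, 3*m): m candidate uniform triples per row. Returns
    the first accepted variate per row (NaN if none accepted — vanishingly
    unlikely for sensible m).
    """
    n, cols = u.shape
    m = cols // 3
    u1 = u[:, 0:m]
    u2 = u[:, m : 2 * m]
    u3 = u[:, 2 * m : 3 * m]
    tau = 1.0 + np.sqrt(1.0 + 4.0 * kappa**2)
    rho = (tau - np.sqrt(2.0 * tau)) / (2.0 * kappa)
    r = (1.0 + rho**2) / (2.0 * rho)
    z = np.cos(np.pi * u1)
    f = (1.0 + r * z) / (r + z)
    c = kappa * (r - f)
    with np.errstate(divide="ignore", invalid="ignore"):
        accept = (c * (2.0 - c) - u2 > 0.0) | (np.log(c / u2) + 1.0 - c >= 0.0)
    first = np.argmax(accept, axis=1)
    ok = accept[np.arange(n), first]
    fsel = f[np.arange(n), first]
    theta = np.sign(u3[np.arange(n), first] - 0.5) * np.arccos(np.clip(fsel, -1.0, 1.0))
    return np.where(ok, theta, np.nan)


def sample_von_mises(mu: float | np.ndarray, kappa: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. von Mises(mu, kappa) variates via the Best-Fisher procedure.

    kappa = 0 falls back to the uniform distribution on (-pi, pi].
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa < 1e-12:
        return wrap_angle(rng.uniform(-np.pi, np.pi, size=n) + np.asarray(mu))
    m = 32
    out = np.full(n, np.nan)
    todo = np.arange(n)
    while todo.size:
        u = rng.random((todo.size, 3 * m))
        theta = _best_fisher_block(kappa, u)
        done = ~np.isnan(theta)
        out[todo[done]] = theta[done]
        todo = todo[~done]
    return wrap_angle(out + np.asarray(mu))


def _substream_uniforms(seed: int, hkl: np.ndarray, n_cols: int) -> np.ndarray:
    """One row of uniforms per reflection from a stream keyed by (seed, h, k, l)."""
    rows = np.empty((len(hkl), n_cols))
    for i, (h, k, l) in enumerate(hkl):
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence([int(seed), int(h) + 512, int(k) + 512, int(l) + 512]))
        )
        rows[i] = rng.random(n_cols)
    return rows


def corrupt_phases(refl: ReflectionSet, spec: ErrorSpec) -> ReflectionSet:
    """Replace reference phases with random variates at the specified circular variance.

    Acentric phases become von Mises(phi_ref, kappa); centric phases flip to
    phi_ref + pi with probability q = 1 - p. Amplitudes are untouched, and
    the same error distribution is used at every resolution.
    """
    phi = refl.phases
    if np.any(~np.isfinite(phi)):
        raise ValueError("reference phases missing: cannot corrupt")
    V = spec.circular_variance
    if V == 0.0:
        return refl.with_columns(phi=phi.copy())
    centric = refl.centric
    new_phi = phi.copy()
    hkl = refl.hkl

    n_ac = int((~centric).sum())
    if n_ac and spec.kappa < 1e-12:  # uniform limit (V = 1)
        u = _substream_uniforms(spec.seed, hkl[~centric], 1)[:, 0]
        new_phi[~centric] = wrap_angle(phi[~centric] + (2.0 * u - 1.0) * np.pi)
    elif n_ac:
        m = 24
        u = _substream_uniforms(spec.seed, hkl[~centric], 3 * m)
        theta = _best_fisher_block(spec.kappa, u)
        bad = np.isnan(theta)
        if bad.any():  # top up stragglers from their own substreams
            for idx in np.flatnonzero(bad):
                h, k, l = hkl[~centric][idx]
                rng = np.random.Generator(
                    np.random.PCG64(
                        np.random.SeedSequence([int(spec.seed), int(h) + 512, int(k) + 512, int(l) + 512, 1])
                    )
                )
                theta[idx] = sample_von_mises(0.0, spec.kappa, 1, rng)[0]
        new_phi[~centric] = wrap_angle(phi[~centric] + theta)

    n_c = int(centric.sum())
    if n_c:
        u = _substream_uniforms(spec.seed, hkl[centric], 1)[:, 0]
        flip = u > spec.p_centric
        new_phi[centric] = wrap_angle(phi[centric] + np.where(flip, np.pi, 0.0))

    return refl.with_columns(phi=new_phi)
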