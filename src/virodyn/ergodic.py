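"""Ergodic analysis: occupation densities, Lyapunov exponents, k-sweeps.

By the strong law of large numbers for an ergodic invariant measure,
the relative occupation time of one long trajectory approximates the
measure's stationary density — so 2-D occupation histograms of the
``(x, y)`` projection stand in for the densities of the leaf measures
``pi(k)``, and their shape (one-peak vs. crater-like) exhibits the
phenomenological (P-) Hopf bifurcation as the leaf index
``k = z2(0)/z1(0)^rho`` varies.  Component Lyapunov exponents are
estimated by the endpoint quotient ``ln c(t)/t``; their sign changes
along a k-grid exhibit the dynamical (D-) bifurcation.  The
invariant-manifold identity ``z2(t) = k z1(t)^rho exp(tau2 W2 - rho
tau1 W1)`` (valid for symmetric clearance, ``h1 = h2``) is checked
pathwise from the stored Brownian drivers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .classify import (EQ_TOL, bifurcation_roots, stochastic_clearance_rates,
                       InvariantSupport)
from .model import NondimParams, baseline_initial_state
from .simulate import SimulationSettings, Trajectory, simulate, derive_seed

__all__ = [
    "OccupationHistogram", "LyapunovEstimate", "KSweepResult",
    "ManifoldCheck", "DistanceSummary",
    "occupation_histogram", "shape_classification", "lyapunov_estimate",
    "k_sweep", "manifold_check", "distance_to_support",
]

_COMPONENTS = ("x", "y", "z1", "z2")


# ---------------------------------------------------------------------------
# occupation histograms and their shape
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OccupationHistogram:
    """Normalized 2-D relative-occupation-time histogram."""

    projection: tuple
    edges: tuple               # (x_edges, y_edges)
    masses: np.ndarray         # (nx, ny), sums to 1
    burn_in: float
    n_samples: int

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        ex, ey = self.edges
        return 0.5 * (ex[1:] + ex[:-1]), 0.5 * (ey[1:] + ey[:-1])


def occupation_histogram(traj: Trajectory,
                         projection: tuple = ("x", "y"),
                         bins: int = 60,
                         burn_in: float = 0.0) -> OccupationHistogram:
    """Occupation histogram of a coordinate pair after discarding burn-in.

    The default 60x60 binning over the data range of the retained
    samples matches the visual granularity of the stationary-density
    plots this estimator is meant to reproduce.
    """
    if burn_in >= traj.times[-1]:
        raise ValueError("burn_in must be smaller than the trajectory horizon")
    keep = traj.times >= burn_in
    cols = [traj.component(c)[keep] for c in projection]
    counts, ex, ey = np.histogram2d(cols[0], cols[1], bins=bins)
    total = counts.sum()
    if total == 0:
        raise ValueError("no samples retained after burn-in")
    return OccupationHistogram(projection=tuple(projection), edges=(ex, ey),
                               masses=counts / total, burn_in=burn_in,
                               n_samples=int(total))


def shape_classification(h: OccupationHistogram,
                         smooth_sigma: float = 1.5,
                         unimodal_ratio: float = 1.5,
                         crater_ratio: float = 0.67) -> str:
    """Classify a stationary-density estimate as ``unimodal``/``crater``.

    After mild Gaussian smoothing, the density at the occupation
    centroid is compared against the maximum density on the ring of
    radius equal to the RMS distance from the centroid (distances in
    per-axis standardized coordinates, so elongated supports are not
    penalized).  Centroid-to-ring ratios above ``unimodal_ratio`` are
    one-peak, below ``crater_ratio`` crater-like, anything between
    ``indeterminate``.
    """
    masses = h.masses
    if masses.sum() <= 0:
        raise ValueError("empty histogram")
    dens = ndimage.gaussian_filter(masses, sigma=smooth_sigma, mode="nearest")
    cx, cy = h.centers()
    mx = masses.sum(axis=1)
    my = masses.sum(axis=0)
    mean_x = float(np.dot(mx, cx))
    mean_y = float(np.dot(my, cy))
    std_x = math.sqrt(max(float(np.dot(mx, (cx - mean_x) ** 2)), 1e-300))
    std_y = math.sqrt(max(float(np.dot(my, (cy - mean_y) ** 2)), 1e-300))
    X = (cx[:, None] - mean_x) / std_x
    Y = (cy[None, :] - mean_y) / std_y
    dist = np.sqrt(X ** 2 + Y ** 2)          # (nx, ny) standardized distances
    rms = math.sqrt(float(np.sum(masses * dist ** 2)))
    # density at the centroid: maximum over the inner disc of radius rms/4,
    # robust to sub-bin peaks slightly offset from the centroid; inside a
    # crater the whole disc is the low-density hole, so craters still read low
    disc = dist <= 0.25 * rms
    if disc.any():
        center_dens = float(dens[disc].max())
    else:
        i0 = int(np.argmin(np.abs(cx - mean_x)))
        j0 = int(np.argmin(np.abs(cy - mean_y)))
        center_dens = float(dens[i0, j0])
    # ring: bins whose standardized distance is within half a bin diagonal
    bin_diag = math.sqrt((cx[1] - cx[0]) ** 2 / std_x ** 2 +
                         (cy[1] - cy[0]) ** 2 / std_y ** 2) if len(cx) > 1 else rms
    width = max(0.5 * bin_diag, 0.1 * rms)
    ring = np.abs(dist - rms) <= width
    if not ring.any():
        return "indeterminate"
    ring_max = float(dens[ring].max())
    if ring_max <= 0:
        return "unimodal" if center_dens > 0 else "indeterminate"
    ratio = center_dens / ring_max
    if ratio > unimodal_ratio:
        return "unimodal"
    if ratio < crater_ratio:
        return "crater"
    return "indeterminate"


# ---------------------------------------------------------------------------
# Lyapunov exponents
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LyapunovEstimate:
    """Finite-time Lyapunov-exponent estimate for one solution component.

    ``value`` is the endpoint quotient — ``ln c(T)/T`` when
    ``burn_in == 0`` (the estimator of the source method), else the
    difference quotient ``(ln c(T) - ln c(b))/(T - b)`` which removes
    the initial-value and transient contributions.  ``regression_value``
    is the slope of ``ln c(t)`` on the retained window, reported as a
    diagnostic.
    """

    component: str
    value: float
    regression_value: float
    t_final: float
    burn_in: float


def lyapunov_estimate(traj: Trajectory, component: str,
                      burn_in: float = 0.0) -> LyapunovEstimate:
    """Estimate the exponential growth rate of one component."""
    c = traj.component(component)
    t = traj.times
    keep = t >= burn_in
    if not keep.any():
        raise ValueError("burn_in leaves no samples")
    cw = c[keep]
    tw = t[keep]
    bad = np.nonzero(cw <= 0)[0]
    if bad.size:
        raise ValueError(
            f"component {component} non-positive at t={tw[bad[0]]:.6g}")
    logc = np.log(cw)
    if burn_in <= 0:
        value = float(logc[-1] / tw[-1])
    else:
        value = float((logc[-1] - logc[0]) / (tw[-1] - tw[0]))
    if len(tw) > 1:
        slope = float(np.polyfit(tw, logc, 1)[0])
    else:
        slope = value
    return LyapunovEstimate(component=component, value=value,
                            regression_value=slope,
                            t_final=float(tw[-1]), burn_in=burn_in)


# ---------------------------------------------------------------------------
# k-sweep (D-bifurcation)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KSweepResult:
    """Per-leaf Lyapunov-exponent estimates across a k-grid.

    ``estimates`` has shape ``(n_k, n_seeds, 4)`` in component order
    ``(x, y, z1, z2)``; ``inits`` the per-k initial states.
    """

    k_grid: np.ndarray
    seeds: tuple
    estimates: np.ndarray
    inits: np.ndarray
    components: tuple = _COMPONENTS

    def mean(self) -> np.ndarray:
        return self.estimates.mean(axis=1)

    def stderr(self) -> np.ndarray:
        n = self.estimates.shape[1]
        if n < 2:
            return np.zeros_like(self.mean())
        return self.estimates.std(axis=1, ddof=1) / math.sqrt(n)

    def sign_changes(self, component: str = "z1") -> list[float]:
        """k-locations (interval midpoints, log scale) where the
        seed-averaged exponent of ``component`` changes sign."""
        idx = self.components.index(component)
        m = self.mean()[:, idx]
        out = []
        for i in range(len(m) - 1):
            if m[i] == 0.0 or m[i] * m[i + 1] < 0.0:
                out.append(float(math.sqrt(self.k_grid[i] * self.k_grid[i + 1])))
        return out


def k_sweep(p: NondimParams, k_grid: Sequence[float],
            settings: SimulationSettings,
            seeds: Sequence[int] = (0,),
            eq_tol: float = EQ_TOL) -> KSweepResult:
    """Sweep the leaf index k and estimate all four component exponents.

    Requires symmetric clearance (``h1 = h2``) with ``a`` inside the
    Hopf window ``(a1, a2)``; other parameter sets are refused (run
    ``classify_regime`` to see why).  Each (k, seed) pair gets its own
    derived trajectory seed, and each trajectory starts from
    ``(0.5, 0.5, 0.01 k, 0.01)``.
    """
    h1, h2 = stochastic_clearance_rates(p)
    scale = max(abs(h1), abs(h2), 1e-300)
    if abs(h1 - h2) > eq_tol * scale:
        raise ValueError(
            "k_sweep requires h1 == h2 (Case 3); classify_regime explains "
            f"the current regime (|h1-h2| = {abs(h1 - h2):g})")
    roots = bifurcation_roots(p, eq_tol)
    if not roots.exists or not (roots.a1 < p.a < roots.a2):
        raise ValueError(
            "k_sweep requires a inside the Hopf window (a1, a2); "
            "see classify_regime")
    k_grid = np.asarray(k_grid, dtype=float)
    if k_grid.ndim != 1 or np.any(np.diff(k_grid) <= 0):
        raise ValueError("k_grid must be strictly increasing")
    n_k, n_s = len(k_grid), len(seeds)
    estimates = np.empty((n_k, n_s, 4))
    inits = np.empty((n_k, 4))
    for i, k in enumerate(k_grid):
        init = baseline_initial_state(k)
        inits[i] = init
        for j, s in enumerate(seeds):
            st = replace(settings, seed=derive_seed(s, i))
            traj = simulate(p, init, st)
            for ci, comp in enumerate(_COMPONENTS):
                estimates[i, j, ci] = lyapunov_estimate(traj, comp).value
    return KSweepResult(k_grid=k_grid, seeds=tuple(seeds),
                        estimates=estimates, inits=inits)


# ---------------------------------------------------------------------------
# invariant-manifold identity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifoldCheck:
    """Pathwise check of ``z2 = k z1^rho exp(tau2 W2 - rho tau1 W1)``."""

    k_implied: float
    max_rel_dev: float


def manifold_check(traj: Trajectory, p: NondimParams,
                   eq_tol: float = EQ_TOL) -> ManifoldCheck:
    """Verify the invariant-manifold relation along a saved path.

    Valid only for symmetric clearance (``h1 = h2``); the leaf index is
    implied by the initial state, ``k = z2(0)/z1(0)^rho``, and the
    stored Brownian drivers supply the martingale factor.
    """
    h1, h2 = stochastic_clearance_rates(p)
    scale = max(abs(h1), abs(h2), 1e-300)
    if abs(h1 - h2) > eq_tol * scale:
        raise ValueError("manifold_check requires h1 == h2 (Case 3)")
    z1 = traj.component("z1")
    z2 = traj.component("z2")
    if z1[0] <= 0 or z2[0] <= 0:
        raise ValueError("manifold_check needs z1(0), z2(0) > 0")
    rho = p.rho
    k = z2[0] / z1[0] ** rho
    mart = np.exp(p.tau2 * traj.W[:, 1] - rho * p.tau1 * traj.W[:, 0])
    pred = k * z1 ** rho * mart
    rel = np.abs(z2 - pred) / z2
    return ManifoldCheck(k_implied=float(k), max_rel_dev=float(rel.max()))


# ---------------------------------------------------------------------------
# distance to an invariant support
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceSummary:
    """Summary of Euclidean distances from a path to a support."""

    median: float
    q95: float
    n_samples: int


def distance_to_support(traj: Trajectory, supp: InvariantSupport,
                        burn_in: float = 0.0,
                        n_dense: int = 2048) -> DistanceSummary:
    """Distance of retained states to an invariant-measure support.

    Segment supports are minimized over the parameterization by dense
    sampling followed by a local parabolic refinement of the squared
    distance; point supports use the exact distance.
    """
    keep = traj.times >= burn_in
    pts = traj.states[keep]
    if supp.kind == "point":
        d = np.linalg.norm(pts - supp.point, axis=1)
    else:
        samples = supp.sample(n_dense)
        d = np.empty(len(pts))
        chunk = 4096
        for lo in range(0, len(pts), chunk):
            block = pts[lo:lo + chunk]
            dm = cdist(block, samples)
            arg = dm.argmin(axis=1)
            best = dm[np.arange(len(block)), arg]
            # parabolic refinement of squared distance over neighbors
            inner = (arg > 0) & (arg < n_dense - 1)
            if inner.any():
                ii = np.nonzero(inner)[0]
                a = dm[ii, arg[ii] - 1] ** 2
                b = dm[ii, arg[ii]] ** 2
                c = dm[ii, arg[ii] + 1] ** 2
                denom = a - 2 * b + c
                ok = denom > 0
                t = np.zeros(len(ii))
                t[ok] = 0.5 * (a[ok] - c[ok]) / denom[ok]
                t = np.clip(t, -1.0, 1.0)
                refined = b + 0.5 * (c - a) * t + 0.5 * denom * t * t
                best[ii] = np.sqrt(np.maximum(refined, 0.0))
            d[lo:lo + chunk] = best
    return DistanceSummary(median=float(np.median(d)),
                           q95=float(np.quantile(d, 0.95)),
                           n_samples=len(d))
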