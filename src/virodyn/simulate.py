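"""Seeded sample-path generation for the virotherapy SDE.

Two schemes are provided:

* ``euler-maruyama`` — the classical strong-order-1/2 scheme;
* ``srk1`` — a derivative-free strong-order-1 stochastic Runge–Kutta
  scheme for the model's two-driver *diagonal* noise (each Brownian
  driver multiplies exactly one coordinate, and that coordinate's
  diffusion depends only on itself).  The drift part is a two-stage
  (Heun) Runge–Kutta step; the diffusion correction replaces the
  Milstein derivative term ``g_j' g_j I(j,j)`` by the finite stage
  difference ``(g_j(H_j) - g_j(U)) / sqrt(dt) * I(j,j)`` with supporting
  value ``H_j = U + f dt + g_j sqrt(dt)``.  For diagonal noise the
  cross iterated integrals carry zero coefficients, so only the exact
  diagonal integrals ``I(j,j) = ((dW_j)^2 - dt)/2`` enter the update.

Positivity of the immune components (guaranteed almost surely by the
exact flow) is preserved by reject-and-halve: a local step that would
drive ``z1`` or ``z2`` non-positive is split into two conditioned
half-steps (Brownian-bridge midpoint), recursively up to 10 levels,
after which the run aborts.  Tumor fractions are clamped to the domain
``D`` only for overshoots below a per-step tolerance; larger overshoots
abort, since ``D`` is invariant for the exact flow and persistent
violations signal a step-size problem.

The inner loop is compiled with numba; identical ``(seed, settings,
params, init)`` give bit-identical trajectories.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numba import njit

from .model import NondimParams, drift, diffusion, in_domain

logger = logging.getLogger("virodyn")

__all__ = [
    "SimulationSettings", "Trajectory", "SimulationError",
    "simulate", "em_step", "srk1_step", "iterated_integrals", "derive_seed",
]

_MAX_HALVINGS = 10

_STATUS_OK = 0
_STATUS_NAN = 1
_STATUS_POSITIVITY = 2
_STATUS_DOMAIN = 3


class SimulationError(RuntimeError):
    """Raised when a sample path cannot be continued."""

    def __init__(self, message: str, step: Optional[int] = None):
        super().__init__(message)
        self.step = step


@dataclass(frozen=True)
class SimulationSettings:
    """Integration settings.

    ``dt`` is the fine step (guidance: <= 1e-3 for the packaged
    baseline parameters); states and Brownian values are saved every
    ``save_stride`` fine steps.  ``domain_tol`` is the per-step overshoot
    of ``D`` that is silently clamped (and counted); overshoots beyond
    ``hard_cap`` abort.  ``substeps_for_iterated_integrals`` controls the
    sub-step approximation of the cross iterated integrals (which do not
    enter the update for this model's diagonal noise).
    """

    t_end: float
    dt: float = 1e-3
    scheme: str = "srk1"
    seed: int = 0
    save_stride: int = 100
    domain_tol: float = 1e-6
    hard_cap: float = 1e-3
    substeps_for_iterated_integrals: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.t_end < self.dt:
            raise ValueError("t_end must be >= dt")
        if self.save_stride < 1:
            raise ValueError("save_stride must be >= 1")
        if self.scheme not in ("euler-maruyama", "srk1"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.substeps_for_iterated_integrals < 1:
            raise ValueError("substeps_for_iterated_integrals must be >= 1")


@dataclass(frozen=True)
class Trajectory:
    """A saved sample path together with its Brownian drivers.

    ``states`` has shape ``(n_saved, 4)`` with columns ``x, y, z1, z2``;
    ``W`` holds the driver values ``(W1, W2)`` on the same grid (exactly
    the increments consumed by the stepper, partially summed).
    """

    times: np.ndarray
    states: np.ndarray
    W: np.ndarray
    params: NondimParams
    settings: SimulationSettings
    init: np.ndarray
    clamp_count: int = 0
    halving_count: int = 0
    max_overshoot: float = 0.0
    n_steps: int = 0

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def component(self, name: str) -> np.ndarray:
        idx = {"x": 0, "y": 1, "z1": 2, "z2": 3}[name]
        return self.states[:, idx]

    def clamp_fraction(self) -> float:
        return self.clamp_count / max(self.n_steps, 1)


def derive_seed(master: int, index: int) -> int:
    """Stable per-trajectory seed derived from a master seed.

    Uses :class:`numpy.random.SeedSequence` spawning so replicate
    streams are independent and the result stays below 2**31.
    """
    ss = np.random.SeedSequence(entropy=master, spawn_key=(index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# single steps (reference implementations, also the tested API)
# ---------------------------------------------------------------------------

def em_step(state, dt: float, dW, p: NondimParams) -> np.ndarray:
    """One Euler–Maruyama step: ``U + f dt + g dW`` (no positivity handling)."""
    u = np.asarray(state, dtype=float)
    return u + drift(u, p) * dt + diffusion(u, p) @ np.asarray(dW, dtype=float)


def srk1_step(state, dt: float, dW, iterated, p: NondimParams) -> np.ndarray:
    """One derivative-free strong-order-1 SRK step for diagonal noise.

    ``iterated`` is the 2x2 matrix of iterated Itô integrals for the
    step; only the diagonal (``((dW_j)^2 - dt)/2`` when supplied
    exactly) enters the update, the cross entries having zero
    coefficients for this diffusion.  With ``tau1 = tau2 = 0`` the step
    is Heun's two-stage deterministic Runge–Kutta step.
    """
    u = np.asarray(state, dtype=float)
    dW = np.asarray(dW, dtype=float)
    it = np.asarray(iterated, dtype=float)
    sq = math.sqrt(dt)
    f0 = drift(u, p)
    g1 = p.tau1 * u[2]
    g2 = p.tau2 * u[3]
    # supporting values for the stage-difference Milstein correction
    h1 = u[2] + f0[2] * dt + g1 * sq
    h2 = u[3] + f0[3] * dt + g2 * sq
    # Heun predictor (includes the noise increment)
    ut = u + f0 * dt
    ut[2] += g1 * dW[0]
    ut[3] += g2 * dW[1]
    f1 = drift(ut, p)
    out = u + 0.5 * (f0 + f1) * dt
    out[2] += g1 * dW[0] + p.tau1 * (h1 - u[2]) / sq * it[0, 0]
    out[3] += g2 * dW[1] + p.tau2 * (h2 - u[3]) / sq * it[1, 1]
    return out


def iterated_integrals(dW, dt: float, substeps: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Iterated Itô integrals ``I(i,j)`` over one step of size ``dt``.

    Diagonal entries are exact, ``I(j,j) = ((dW_j)^2 - dt)/2``.  For
    ``substeps >= 2`` the cross entries are sub-step Euler sums over a
    Brownian-bridge refinement conditioned on the supplied increments,
    with the discrete quadratic covariation split symmetrically so that
    ``I(1,2) + I(2,1) = dW_1 dW_2`` holds exactly.  ``substeps == 1``
    returns zero cross entries (degenerate single-increment
    approximation).
    """
    dW = np.asarray(dW, dtype=float)
    out = np.zeros((2, 2))
    out[0, 0] = 0.5 * (dW[0] ** 2 - dt)
    out[1, 1] = 0.5 * (dW[1] ** 2 - dt)
    m = substeps
    if m == 1:
        return out
    h = dt / m
    xi = rng.standard_normal((m, 2)) * math.sqrt(h)
    delta = xi - xi.mean(axis=0) + dW / m        # bridge: sums to dW exactly
    cum = np.vstack([np.zeros(2), np.cumsum(delta, axis=0)[:-1]])
    a12 = float(np.sum(cum[:, 0] * delta[:, 1]))
    a21 = float(np.sum(cum[:, 1] * delta[:, 0]))
    q = float(np.sum(delta[:, 0] * delta[:, 1]))
    out[0, 1] = a12 + 0.5 * q
    out[1, 0] = a21 + 0.5 * q
    return out


# ---------------------------------------------------------------------------
# compiled inner loop
# ---------------------------------------------------------------------------

@njit(cache=True)
def _drift_nb(u, r, a, l1, l2, e1, e2, d1, d2, out):
    x, y, z1, z2 = u[0], u[1], u[2], u[3]
    out[0] = r * x * (1.0 - x - y) - a * x * y - l2 * x * z2
    out[1] = a * x * y - l1 * y * z1 - y
    out[2] = e1 * y * z1 - d1 * z1
    out[3] = e2 * y * z2 - d2 * z2


@njit(cache=True)
def _step_nb(u, dt, dw1, dw2, r, a, l1, l2, e1, e2, d1, d2,
             tau1, tau2, srk, f0, ut, f1, out):
    _drift_nb(u, r, a, l1, l2, e1, e2, d1, d2, f0)
    g1 = tau1 * u[2]
    g2 = tau2 * u[3]
    if srk:
        sq = math.sqrt(dt)
        h1 = u[2] + f0[2] * dt + g1 * sq
        h2 = u[3] + f0[3] * dt + g2 * sq
        i11 = 0.5 * (dw1 * dw1 - dt)
        i22 = 0.5 * (dw2 * dw2 - dt)
        for j in range(4):
            ut[j] = u[j] + f0[j] * dt
        ut[2] += g1 * dw1
        ut[3] += g2 * dw2
        _drift_nb(ut, r, a, l1, l2, e1, e2, d1, d2, f1)
        for j in range(4):
            out[j] = u[j] + 0.5 * (f0[j] + f1[j]) * dt
        out[2] += g1 * dw1 + tau1 * (h1 - u[2]) / sq * i11
        out[3] += g2 * dw2 + tau2 * (h2 - u[3]) / sq * i22
    else:
        for j in range(4):
            out[j] = u[j] + f0[j] * dt
        out[2] += g1 * dw1
        out[3] += g2 * dw2


@njit(cache=True)
def _integrate_nb(init, dW, dt, n_steps, stride, r, a, l1, l2, e1, e2,
                  d1, d2, tau1, tau2, srk, domain_tol, hard_cap,
                  bridge_seed, states, Wsav):
    """Full integration loop.  Returns
    (status, fail_step, clamp_count, halving_count, max_overshoot)."""
    np.random.seed(bridge_seed)
    u = init.copy()
    f0 = np.empty(4)
    ut = np.empty(4)
    f1 = np.empty(4)
    unew = np.empty(4)
    # LIFO stack for reject-and-halve segments
    cap = 4 * (_MAX_HALVINGS + 2)
    seg_dt = np.empty(cap)
    seg_w1 = np.empty(cap)
    seg_w2 = np.empty(cap)
    seg_depth = np.empty(cap, dtype=np.int64)
    W1 = 0.0
    W2 = 0.0
    clamp_count = 0
    halving_count = 0
    max_over = 0.0
    states[0, :] = u
    Wsav[0, 0] = 0.0
    Wsav[0, 1] = 0.0
    save_i = 1
    for i in range(n_steps):
        seg_dt[0] = dt
        seg_w1[0] = dW[i, 0]
        seg_w2[0] = dW[i, 1]
        seg_depth[0] = 0
        top = 1
        while top > 0:
            top -= 1
            hdt = seg_dt[top]
            hw1 = seg_w1[top]
            hw2 = seg_w2[top]
            dep = seg_depth[top]
            _step_nb(u, hdt, hw1, hw2, r, a, l1, l2, e1, e2, d1, d2,
                     tau1, tau2, srk, f0, ut, f1, unew)
            bad = False
            for j in range(4):
                if not math.isfinite(unew[j]):
                    return _STATUS_NAN, i, clamp_count, halving_count, max_over
            if (u[2] > 0.0 and unew[2] <= 0.0) or (u[3] > 0.0 and unew[3] <= 0.0):
                bad = True
            if bad:
                if dep >= _MAX_HALVINGS:
                    return (_STATUS_POSITIVITY, i, clamp_count,
                            halving_count, max_over)
                halving_count += 1
                half = 0.5 * hdt
                sig = math.sqrt(0.25 * hdt)
                m1 = 0.5 * hw1 + sig * np.random.normal()
                m2 = 0.5 * hw2 + sig * np.random.normal()
                # push second half then first half (LIFO order)
                seg_dt[top] = half
                seg_w1[top] = hw1 - m1
                seg_w2[top] = hw2 - m2
                seg_depth[top] = dep + 1
                top += 1
                seg_dt[top] = half
                seg_w1[top] = m1
                seg_w2[top] = m2
                seg_depth[top] = dep + 1
                top += 1
                continue
            # domain handling for the tumor fractions
            over = 0.0
            if unew[0] < 0.0:
                over = max(over, -unew[0])
            if unew[1] < 0.0:
                over = max(over, -unew[1])
            s = unew[0] + unew[1]
            if s > 1.0:
                over = max(over, s - 1.0)
            if over > 0.0:
                if over > hard_cap:
                    return (_STATUS_DOMAIN, i, clamp_count,
                            halving_count, max_over)
                clamp_count += 1
                if over > max_over:
                    max_over = over
                if unew[0] < 0.0:
                    unew[0] = 0.0
                if unew[1] < 0.0:
                    unew[1] = 0.0
                s = unew[0] + unew[1]
                if s > 1.0:
                    unew[0] /= s
                    unew[1] /= s
            for j in range(4):
                u[j] = unew[j]
        W1 += dW[i, 0]
        W2 += dW[i, 1]
        if (i + 1) % stride == 0:
            states[save_i, :] = u
            Wsav[save_i, 0] = W1
            Wsav[save_i, 1] = W2
            save_i += 1
    return _STATUS_OK, n_steps, clamp_count, halving_count, max_over


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def simulate(p: NondimParams, init, settings: SimulationSettings) -> Trajectory:
    """Simulate one sample path of the virotherapy SDE.

    ``init`` is the initial state ``(x, y, z1, z2)``; it must lie in the
    invariant domain ``D``.  Brownian increments are generated at the
    fine ``dt`` grid from ``numpy.random.default_rng(settings.seed)``
    and partially summed to give the saved driver values, so the stored
    paths are exactly those consumed by the stepper.
    """
    init = np.asarray(init, dtype=float)
    if init.shape != (4,):
        raise ValueError("initial state must have 4 components")
    if not in_domain(init, tol=settings.domain_tol):
        raise ValueError(f"initial state {init} outside the domain D")

    dt = settings.dt
    n_steps = int(round(settings.t_end / dt))
    if abs(n_steps * dt - settings.t_end) > 1e-9 * max(1.0, settings.t_end):
        logger.warning("t_end %.6g truncated to %d steps of dt=%.3g",
                       settings.t_end, n_steps, dt)
    stride = settings.save_stride
    if n_steps % stride != 0:
        logger.warning("save_stride %d does not divide %d steps; "
                       "saved grid truncated", stride, n_steps)
    n_saved = n_steps // stride + 1

    rng = np.random.default_rng(settings.seed)
    dW = rng.normal(0.0, math.sqrt(dt), size=(n_steps, 2))
    bridge_seed = (settings.seed * 2654435761 + 97531) % (2 ** 31)

    states = np.empty((n_saved, 4))
    Wsav = np.empty((n_saved, 2))
    status, step, clamps, halvings, max_over = _integrate_nb(
        init, dW, dt, n_steps, stride,
        p.r, p.a, p.l1, p.l2, p.e1, p.e2, p.d1, p.d2, p.tau1, p.tau2,
        settings.scheme == "srk1", settings.domain_tol, settings.hard_cap,
        bridge_seed, states, Wsav)

    if status == _STATUS_NAN:
        raise SimulationError(f"non-finite state at step {step}", step=step)
    if status == _STATUS_POSITIVITY:
        raise SimulationError(
            f"positivity halving cap exceeded at step {step} "
            f"(dt too large for the noise level)", step=step)
    if status == _STATUS_DOMAIN:
        raise SimulationError(
            f"domain overshoot beyond hard cap at step {step}", step=step)

    times = np.arange(n_saved) * (dt * stride)
    if clamps:
        logger.info("trajectory: %d/%d steps clamped (max overshoot %.3g)",
                    clamps, n_steps, max_over)
    return Trajectory(times=times, states=states, W=Wsav, params=p,
                      settings=settings, init=init, clamp_count=int(clamps),
                      halving_count=int(halvings),
                      max_overshoot=float(max_over), n_steps=n_steps)
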