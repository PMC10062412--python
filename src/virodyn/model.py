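"""Core model: parameters, state space, and vector fields.

The model describes oncolytic virotherapy with immune responses as a
four-dimensional Itô stochastic differential equation on the state
``U = (x, y, z1, z2)``:

* ``x``  — uninfected tumor cells (fraction of carrying capacity),
* ``y``  — infected tumor cells (fraction of carrying capacity),
* ``z1`` — innate immune cells relative to carrying capacity,
* ``z2`` — adaptive immune cells relative to carrying capacity.

In non-dimensional form::

    dx  = [ r x (1 - x - y) - a x y - l2 x z2 ] dt
    dy  = [ a x y - l1 y z1 - y ] dt
    dz1 = [ e1 y z1 - d1 z1 ] dt + tau1 z1 dW1
    dz2 = [ e2 y z2 - d2 z2 ] dt + tau2 z2 dW2

Tumor growth is logistic with rate ``r``; ``a`` is the (non-dimensional)
viral infectivity; ``l_i`` are immune killing rates, ``e_i`` immune
stimulation rates, ``d_i`` immune clearance rates; ``tau_i`` are the
multiplicative noise intensities on the two immune compartments, driven
by independent Brownian motions ``W1, W2``.  Free virus is modelled
implicitly through the ``a x y`` infection term.

The state space is the almost-surely invariant domain

    D = { x >= 0, y >= 0, z1 >= 0, z2 >= 0, x + y <= 1 }.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

import numpy as np

logger = logging.getLogger("virodyn")

#: default numerical tolerance for membership checks in the domain D
DOMAIN_TOL = 1e-9


class InvalidParameterError(ValueError):
    """Raised when a parameter set violates its invariants."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional model constants (rates per unit physical time).

    ``lambda_growth`` tumor growth rate (1/time), ``C`` carrying capacity
    (cells), ``beta`` infectivity (1/(cells*time)), ``k1, k2`` immune
    killing rates, ``s1, s2`` immune stimulation rates, ``c1, c2`` immune
    clearance rates (1/time), ``delta`` lysis rate of infected cells
    (1/time), ``tau1, tau2`` noise intensities (1/sqrt(time)).
    """

    lambda_growth: float
    C: float
    beta: float
    k1: float
    k2: float
    s1: float
    s2: float
    c1: float
    c2: float
    delta: float
    tau1: float = 0.0
    tau2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lambda_growth", "beta", "k1", "k2", "s1", "s2",
                     "c1", "c2", "tau1", "tau2"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.C <= 0:
            raise InvalidParameterError("carrying capacity C must be > 0")
        if self.delta <= 0:
            raise InvalidParameterError("lysis rate delta must be > 0")


@dataclass(frozen=True)
class NondimParams:
    """Non-dimensional model constants.

    ``rho = e2 / e1`` is derived once at construction and stored so every
    downstream module uses a single consistent value.  ``provenance``
    optionally records the time/size scales ``(delta, C)`` that were
    divided out, so the dimensional system can be recovered.
    """

    r: float
    a: float
    l1: float
    l2: float
    e1: float
    e2: float
    d1: float
    d2: float
    tau1: float = 0.0
    tau2: float = 0.0
    rho: float = field(init=False)
    provenance: Union[tuple, None] = None

    def __post_init__(self) -> None:
        for name in ("r", "a", "l1", "l2", "e1", "e2", "d1", "d2"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.tau1 < 0 or self.tau2 < 0:
            raise InvalidParameterError("noise intensities must be >= 0")
        object.__setattr__(self, "rho", self.e2 / self.e1)

    def swapped(self) -> "NondimParams":
        """Parameters with the innate and adaptive immune roles exchanged."""
        return NondimParams(r=self.r, a=self.a, l1=self.l2, l2=self.l1,
                            e1=self.e2, e2=self.e1, d1=self.d2, d2=self.d1,
                            tau1=self.tau2, tau2=self.tau1)

    def to_dict(self) -> dict:
        return {k: getattr(self, k)
                for k in ("r", "a", "l1", "l2", "e1", "e2",
                          "d1", "d2", "tau1", "tau2")}


#: keys of a flat non-dimensional parameter config
_NONDIM_KEYS = ("r", "a", "l1", "l2", "e1", "e2", "d1", "d2", "tau1", "tau2")


# ---------------------------------------------------------------------------
# non-dimensionalization
# ---------------------------------------------------------------------------

def nondimensionalize(p: DimensionalParams) -> NondimParams:
    """Map dimensional constants to the non-dimensional system.

    Substitutions: ``r = lambda/delta``, ``a = beta C/delta``,
    ``l_i = k_i C/delta``, ``e_i = s_i C/delta``, ``d_i = c_i/delta``;
    time is rescaled as ``T = delta t`` and populations by ``C``.  The
    noise intensities ``tau_i`` scale as ``tau_i/sqrt(delta)`` so that
    the rescaled Brownian motions stay standard.

    The scales ``(delta, C)`` are recorded in ``provenance`` for the
    inverse map.
    """
    d = p.delta
    return NondimParams(
        r=p.lambda_growth / d,
        a=p.beta * p.C / d,
        l1=p.k1 * p.C / d,
        l2=p.k2 * p.C / d,
        e1=p.s1 * p.C / d,
        e2=p.s2 * p.C / d,
        d1=p.c1 / d,
        d2=p.c2 / d,
        tau1=p.tau1 / math.sqrt(d),
        tau2=p.tau2 / math.sqrt(d),
        provenance=(d, p.C),
    )


def redimensionalize(p: NondimParams,
                     delta: float | None = None,
                     C: float | None = None) -> DimensionalParams:
    """Inverse of :func:`nondimensionalize` given the scales ``(delta, C)``.

    If the scales are omitted they are taken from ``p.provenance``.
    """
    if delta is None or C is None:
        if p.provenance is None:
            raise InvalidParameterError(
                "redimensionalize needs (delta, C): not in provenance")
        delta, C = p.provenance
    if delta <= 0 or C <= 0:
        raise InvalidParameterError("delta and C must be > 0")
    return DimensionalParams(
        lambda_growth=p.r * delta,
        C=C,
        beta=p.a * delta / C,
        k1=p.l1 * delta / C,
        k2=p.l2 * delta / C,
        s1=p.e1 * delta / C,
        s2=p.e2 * delta / C,
        c1=p.d1 * delta,
        c2=p.d2 * delta,
        delta=delta,
        tau1=p.tau1 * math.sqrt(delta),
        tau2=p.tau2 * math.sqrt(delta),
    )


# ---------------------------------------------------------------------------
# vector fields
# ---------------------------------------------------------------------------

def drift(s, p: NondimParams) -> np.ndarray:
    """Itô drift ``f(U)`` of the non-dimensional system at state ``s``."""
    x, y, z1, z2 = s
    return np.array([
        p.r * x * (1.0 - x - y) - p.a * x * y - p.l2 * x * z2,
        p.a * x * y - p.l1 * y * z1 - y,
        p.e1 * y * z1 - p.d1 * z1,
        p.e2 * y * z2 - p.d2 * z2,
    ])


def diffusion(s, p: NondimParams) -> np.ndarray:
    """Diffusion matrix ``g(U)`` (4x2): driver ``W_i`` hits only ``z_i``."""
    _, _, z1, z2 = s
    g = np.zeros((4, 2))
    g[2, 0] = p.tau1 * z1
    g[3, 1] = p.tau2 * z2
    return g


def stratonovich_drift(s, p: NondimParams) -> np.ndarray:
    """Drift of the Stratonovich form of the system.

    The Itô-to-Stratonovich correction for this diagonal multiplicative
    noise removes ``tau_i^2 z_i / 2`` from the two immune equations.
    """
    f = drift(s, p)
    f[2] -= 0.5 * p.tau1 ** 2 * s[2]
    f[3] -= 0.5 * p.tau2 ** 2 * s[3]
    return f


def percapita_growth(s, p: NondimParams) -> np.ndarray:
    """Per-capita Itô-logarithmic growth rates of the four components.

    For a component ``c`` with equation ``dc = c G(U) dt (+ tau c dW)``
    this returns ``G`` (minus ``tau^2/2`` for the noisy components),
    i.e. the instantaneous exponent ``d(log c)/dt`` at state ``s``.
    Evaluated at a point carrying a Dirac invariant measure it yields
    that measure's Lyapunov exponent with respect to each component.
    """
    x, y, z1, z2 = s
    return np.array([
        p.r * (1.0 - x - y) - p.a * y - p.l2 * z2,
        p.a * x - p.l1 * z1 - 1.0,
        p.e1 * y - p.d1 - 0.5 * p.tau1 ** 2,
        p.e2 * y - p.d2 - 0.5 * p.tau2 ** 2,
    ])


def in_domain(s, tol: float = DOMAIN_TOL) -> bool:
    """Membership of ``s`` in the invariant domain D up to tolerance ``tol``."""
    x, y, z1, z2 = s
    return bool(x >= -tol and y >= -tol and z1 >= -tol and z2 >= -tol
                and x + y <= 1.0 + tol)


def immune_free_equilibrium(p: NondimParams) -> np.ndarray:
    """The immune-free state ``(x1*, y1*, 0, 0)`` with ``x1* = 1/a`` and
    ``y1* = r(a-1)/(a(a+r))``; an equilibrium of the drift for ``a > 1``."""
    x1 = 1.0 / p.a
    y1 = p.r * (p.a - 1.0) / (p.a * (p.a + p.r))
    return np.array([x1, y1, 0.0, 0.0])


# ---------------------------------------------------------------------------
# parameter config I/O
# ---------------------------------------------------------------------------

def params_from_dict(d: dict) -> NondimParams:
    """Build :class:`NondimParams` from a flat key-value mapping."""
    missing = [k for k in _NONDIM_KEYS if k not in d]
    if missing:
        raise InvalidParameterError(f"missing parameter keys: {missing}")
    return NondimParams(**{k: float(d[k]) for k in _NONDIM_KEYS})


def load_params(source: Union[str, Path]) -> NondimParams:
    """Load a non-dimensional parameter set.

    ``source`` is either the name of a packaged config (``"baseline"``)
    or a path to a flat JSON/TOML file with keys
    ``r a l1 l2 e1 e2 d1 d2 tau1 tau2``.
    """
    path = Path(source)
    if not path.exists():
        candidate = Path(__file__).parent / "configs" / f"{source}.json"
        if candidate.exists():
            path = candidate
        else:
            raise FileNotFoundError(f"no parameter config {source!r}")
    text = path.read_text()
    if path.suffix == ".toml":
        import tomllib
        d = tomllib.loads(text)
    else:
        d = json.loads(text)
    return params_from_dict(d)


def save_params(p: NondimParams, path: Union[str, Path]) -> None:
    """Write a parameter set as a flat JSON config."""
    Path(path).write_text(json.dumps(p.to_dict(), indent=1) + "\n")


def baseline_params() -> NondimParams:
    """The packaged worked parameter set (oncolytic virotherapy study).

    r = 0.36, a = 5, l1 = l2 = 0.48, e1 = e2 = 10, d1 = d2 = 0.4,
    tau1 = tau2 = 0.01 — a symmetric-immune setting inside the Hopf
    window, used by the demo pipeline.
    """
    return load_params("baseline")


#: initial state used by the worked example, as a function of the leaf index k
def baseline_initial_state(k: float) -> np.ndarray:
    """Initial state ``(0.5, 0.5, 0.01 k, 0.01)`` of the worked example."""
    return np.array([0.5, 0.5, 0.01 * k, 0.01])
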