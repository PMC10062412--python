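"""Regime classification from closed-form thresholds.

The long-term behavior of the stochastic virotherapy model is decided by
a handful of closed-form quantities:

* the **infection value** ``theta = r(a-1)/(a(a+r))`` — the infected-cell
  coordinate of the immune-free equilibrium, a universal critical level;
* the **stochastic relative immune clearance rates**
  ``h_i = d_i/e_i + tau_i^2/(2 e_i)`` — the deterministic clearance-to-
  stimulation ratio inflated by half the noise variance per unit
  stimulation;
* the Lyapunov-type exponents ``lambda_i = e_i (theta - h_i)`` and, when
  ``h1 = h2 =: h``, the combined parameter ``lambda = theta - h``.

The ordering of ``h1`` and ``h2`` selects which immune compartment
survives (Case 1: ``h1 < h2`` — innate only; Case 2: ``h1 > h2`` —
adaptive only; Case 3: ``h1 = h2`` — both), and within a case the signs
of ``a - 1`` and the relevant exponent pick the globally attracting
invariant measure: therapy failure at ``(1,0,0,0)``, the immune-free
point ``(x1*, y1*, 0, 0)``, or an ergodic measure supported on an open
line segment (``S1``, ``S2``, or the family ``S(k)``).  In Case 3 with a
positive exponent the system carries a whole collection ``{pi(k)}`` of
invariant measures indexed by the leaf ``k = z2/z1^rho`` — the setting
of the stochastic Hopf bifurcation without parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .model import NondimParams, in_domain, immune_free_equilibrium

__all__ = [
    "infection_value", "stochastic_clearance_rates", "lyapunov_parameters",
    "bifurcation_roots", "classify_regime", "support_segment",
    "boundary_exponents", "RegimeReport", "InvariantSupport",
    "BifurcationRoots", "EQ_TOL",
]

#: default relative tolerance for deciding h1 == h2 and critical values
EQ_TOL = 1e-10


# ---------------------------------------------------------------------------
# closed-form thresholds
# ---------------------------------------------------------------------------

def infection_value(p: NondimParams) -> float:
    """Infection value ``theta = r(a-1)/(a(a+r))``.

    Equals the infected-tumor coordinate ``y1*`` of the immune-free
    equilibrium; always below 1.
    """
    return p.r * (p.a - 1.0) / (p.a * (p.a + p.r))


def stochastic_clearance_rates(p: NondimParams) -> tuple[float, float]:
    """Stochastic relative immune clearance rates ``(h1, h2)``,
    ``h_i = d_i/e_i + tau_i^2/(2 e_i)``."""
    h1 = p.d1 / p.e1 + p.tau1 ** 2 / (2.0 * p.e1)
    h2 = p.d2 / p.e2 + p.tau2 ** 2 / (2.0 * p.e2)
    return h1, h2


def lyapunov_parameters(p: NondimParams,
                        eq_tol: float = EQ_TOL
                        ) -> tuple[float, float, Optional[float]]:
    """Exponents ``lambda_i = e_i(theta - h_i)`` and, when ``h1 = h2``
    within relative tolerance ``eq_tol``, the combined ``lambda = theta - h1``
    (otherwise ``None``)."""
    theta = infection_value(p)
    h1, h2 = stochastic_clearance_rates(p)
    lam1 = p.e1 * (theta - h1)
    lam2 = p.e2 * (theta - h2)
    lam = theta - h1 if _h_equal(h1, h2, eq_tol) else None
    return lam1, lam2, lam


def _h_equal(h1: float, h2: float, eq_tol: float) -> bool:
    scale = max(abs(h1), abs(h2), 1e-300)
    return abs(h1 - h2) <= eq_tol * scale


# ---------------------------------------------------------------------------
# bifurcation roots
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BifurcationRoots:
    """Roots ``a1 < a2`` of ``m(a) = a^2 + r(1 - 1/h) a + r/h``.

    ``lambda(a) > 0`` exactly for ``a`` in ``(a1, a2)``; the window exists
    iff ``h < 1`` and ``r > 4h/(1-h)^2`` (positive discriminant with both
    roots above 1).  ``discriminant_margin`` is ``r - 4h/(1-h)^2``.
    """

    exists: bool
    a1: Optional[float] = None
    a2: Optional[float] = None
    h: Optional[float] = None
    discriminant_margin: Optional[float] = None

    def m(self, a: float) -> float:
        """Evaluate the quadratic ``m(a)``."""
        h = self.h
        return a * a + self._r * (1.0 - 1.0 / h) * a + self._r / h

    # stashed by bifurcation_roots for m() evaluation
    _r: float = float("nan")


def bifurcation_roots(p: NondimParams, eq_tol: float = EQ_TOL) -> BifurcationRoots:
    """Closed-form roots of ``m(a)`` for symmetric clearance (``h1 = h2``).

    Returns ``exists=False`` (no error) when ``h >= 1`` or the
    discriminant condition ``r > 4h/(1-h)^2`` fails.
    """
    h1, h2 = stochastic_clearance_rates(p)
    if not _h_equal(h1, h2, eq_tol):
        raise ValueError(
            f"bifurcation_roots requires h1 == h2; got |h1-h2| = {abs(h1 - h2):g}")
    h = h1
    r = p.r
    if h >= 1.0:
        return BifurcationRoots(exists=False, h=h, _r=r)
    margin = r - 4.0 * h / (1.0 - h) ** 2
    if margin <= 0.0:
        return BifurcationRoots(exists=False, h=h,
                                discriminant_margin=margin, _r=r)
    half_b = 0.5 * r * (1.0 / h - 1.0)
    disc = math.sqrt(r * r * (1.0 / h - 1.0) ** 2 - 4.0 * r / h)
    a1 = half_b - 0.5 * disc
    a2 = half_b + 0.5 * disc
    return BifurcationRoots(exists=True, a1=a1, a2=a2, h=h,
                            discriminant_margin=margin, _r=r)


# ---------------------------------------------------------------------------
# invariant-measure supports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InvariantSupport:
    """Support of a boundary or interior invariant measure.

    Either a single point in 4-space or an open line segment given by a
    parameterizing coordinate (``z1`` or ``z2``), an open interval
    ``(lo, hi)`` and a map from the parameter to the full state.
    """

    kind: str                              # "point" | "segment"
    point: Optional[np.ndarray] = None
    param_name: Optional[str] = None
    lo: Optional[float] = None
    hi: Optional[float] = None
    param_map: Optional[Callable[[float], np.ndarray]] = None
    k: Optional[float] = None              # leaf index for S(k)
    label: str = ""
    hi_domain: Optional[float] = None      # upper end of the D-valid part

    def sample(self, n: int = 512) -> np.ndarray:
        """Sample ``n`` states along the support (interior of the interval
        for segments; the point repeated otherwise).

        Sampling is restricted to the sub-interval whose image lies in
        the closure of the domain D — for the leaf segments S(k) the
        printed parameter interval extends past the point where the
        infected-cell coordinate hits zero once ``k`` is large enough,
        and the invariant measure carries no mass there.
        """
        if self.kind == "point":
            return np.tile(self.point, (n, 1))
        hi = self.hi if self.hi_domain is None else self.hi_domain
        # open interval: keep strictly inside
        ts = self.lo + (hi - self.lo) * (np.arange(n) + 0.5) / n
        return np.array([self.param_map(t) for t in ts])


def support_segment(p: NondimParams, which: str,
                    k: Optional[float] = None,
                    eq_tol: float = EQ_TOL) -> InvariantSupport:
    """Open-line-segment support of an ergodic invariant measure.

    ``which`` is one of ``"S1"`` (innate-only persistence), ``"S2"``
    (adaptive-only persistence) or ``"Sk"`` (the leaf measure ``pi(k)``,
    requiring ``h1 = h2`` and ``k`` in ``(0, inf)``).  All segments need
    ``a > 1``.
    """
    a, r = p.a, p.r
    if a <= 1.0:
        raise ValueError("support segments require a > 1 (no persistence)")
    y1 = infection_value(p)

    if which == "S1":
        l1 = p.l1
        hi = (a - 1.0) / l1

        def m(z1: float, l1=l1, a=a, r=r) -> np.ndarray:
            return np.array([
                (l1 * z1 + 1.0) / a,
                r * (a - 1.0 - l1 * z1) / (a * (a + r)),
                z1,
                0.0,
            ])

        return InvariantSupport(kind="segment", param_name="z1",
                                lo=0.0, hi=hi, param_map=m, label="S1")

    if which == "S2":
        l2 = p.l2
        hi = r * (a - 1.0) / (a * l2)

        def m(z2: float, l2=l2, a=a, r=r, y1=y1) -> np.ndarray:
            return np.array([
                1.0 / a,
                y1 - l2 * z2 / (a + r),
                0.0,
                z2,
            ])

        return InvariantSupport(kind="segment", param_name="z2",
                                lo=0.0, hi=hi, param_map=m, label="S2")

    if which == "Sk":
        if k is None or not (k > 0) or not np.isfinite(k):
            raise ValueError("Sk requires a finite leaf index k > 0")
        h1, h2 = stochastic_clearance_rates(p)
        if not _h_equal(h1, h2, eq_tol):
            raise ValueError("S(k) supports require h1 == h2")
        l1, l2, rho = p.l1, p.l2, p.rho
        hi = (a - 1.0) / l1

        def m(z1: float, l1=l1, l2=l2, a=a, r=r, y1=y1, k=k, rho=rho
              ) -> np.ndarray:
            return np.array([
                (l1 * z1 + 1.0) / a,
                y1 - r * l1 * z1 / (a * (a + r)) - k * l2 * z1 ** rho / (a + r),
                z1,
                k * z1 ** rho,
            ])

        # the y-coordinate is positive only while
        # l1 z1 + k a l2 z1^rho / r < a - 1; past that root the printed
        # segment leaves D and carries no mass
        def excess(z1: float) -> float:
            return l1 * z1 + k * a * l2 * z1 ** rho / r - (a - 1.0)

        hi_dom = hi
        if excess(hi) > 0:
            from scipy.optimize import brentq
            hi_dom = brentq(excess, 0.0, hi, xtol=1e-14)
        return InvariantSupport(kind="segment", param_name="z1",
                                lo=0.0, hi=hi, param_map=m, k=k,
                                label=f"S(k={k:g})", hi_domain=hi_dom)

    raise ValueError(f"unknown support {which!r}")


def boundary_exponents(p: NondimParams) -> dict:
    """Lyapunov exponents of the Dirac boundary measures.

    Computed by evaluating the per-capita growth rates of the model
    fields at the degenerate supports ``(0,0,0,0)``, ``(1,0,0,0)`` and
    ``(x1*, y1*, 0, 0)``.  Keys are the measure labels ``mu0`` (mass at
    the origin), ``mu1`` (tumor-only state) and ``mu2`` (immune-free
    equilibrium); values are 4-vectors of component exponents
    ``(x, y, z1, z2)``.
    """
    from .model import percapita_growth
    origin = np.zeros(4)
    tumor_only = np.array([1.0, 0.0, 0.0, 0.0])
    immune_free = immune_free_equilibrium(p)
    return {
        "mu0": percapita_growth(origin, p),
        "mu1": percapita_growth(tumor_only, p),
        "mu2": percapita_growth(immune_free, p),
    }


# ---------------------------------------------------------------------------
# the regime decision tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegimeReport:
    """Output of :func:`classify_regime`.

    ``case_label`` records the ordering of the clearance rates (Case1:
    ``h1 < h2``, Case2: ``h1 > h2``, Case3: ``h1 = h2``); ``sub_regime``
    the attracting behavior within the case.  ``attractor`` names the
    globally attracting invariant measure in the catalogue
    (``mu1/mu2/mu3-bar/...``); ``support`` is its support (a family
    prototype for the Hopf regime).
    """

    case_label: str
    sub_regime: str
    theta: float
    h1: float
    h2: float
    lambda1: float
    lambda2: float
    lam: Optional[float]
    attractor: str
    support: Optional[InvariantSupport]
    equality_tolerance: float
    h_gap: float

    def to_dict(self) -> dict:
        d = {
            "case": self.case_label,
            "sub_regime": self.sub_regime,
            "theta": self.theta,
            "h1": self.h1,
            "h2": self.h2,
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "lambda": self.lam,
            "attractor": self.attractor,
            "equality_tolerance": self.equality_tolerance,
            "h_gap": self.h_gap,
            "display": {
                "theta": round(self.theta, 4),
                "h1": round(self.h1, 4),
                "h2": round(self.h2, 4),
                "lambda1": round(self.lambda1, 4),
                "lambda2": round(self.lambda2, 4),
                "lambda": None if self.lam is None else round(self.lam, 4),
            },
        }
        return d


def classify_regime(p: NondimParams, eq_tol: float = EQ_TOL,
                    k: Optional[float] = None) -> RegimeReport:
    """Classify the long-term regime of the model at parameters ``p``.

    Decision tree: first compare ``h1`` and ``h2`` (relative tolerance
    ``eq_tol``) to pick the case; then ``a`` against 1 and the relevant
    exponent (``lambda1``/``lambda2``/``lambda``) against 0.  Values at
    the thresholds (``a = 1`` or exponent ``= 0`` within ``eq_tol``) are
    reported as an explicit ``"critical"`` sub-regime rather than being
    silently assigned to a side — the classification theorems do not
    cover them.  ``k``, when given, selects the leaf ``pi(k)`` reported
    for the Hopf regime; the origin measure ``mu0`` is a repeller in
    every regime.
    """
    theta = infection_value(p)
    h1, h2 = stochastic_clearance_rates(p)
    lam1, lam2, lam = lyapunov_parameters(p, eq_tol)
    a = p.a
    gap = abs(h1 - h2)

    if _h_equal(h1, h2, eq_tol):
        case = "Case3"
        exponent = lam
        labels = ("mu1", "mu2", "{pi(k)}")
        persist = "hopf-without-parameters"
    elif h1 < h2:
        case = "Case1"
        exponent = lam1
        labels = ("mu1-bar", "mu2-bar", "mu3-bar")
        persist = "persistent-innate"
    else:
        case = "Case2"
        exponent = lam2
        labels = ("mu1-tilde", "mu2-tilde", "mu4-tilde")
        persist = "persistent-adaptive"

    fail_label, free_label, persist_label = labels

    def report(sub: str, attractor: str, support) -> RegimeReport:
        return RegimeReport(case_label=case, sub_regime=sub, theta=theta,
                            h1=h1, h2=h2, lambda1=lam1, lambda2=lam2,
                            lam=lam, attractor=attractor, support=support,
                            equality_tolerance=eq_tol, h_gap=gap)

    if abs(a - 1.0) <= eq_tol * max(a, 1.0):
        return report("critical", "degenerate/critical — not classified", None)

    if a < 1.0:
        supp = InvariantSupport(kind="point",
                                point=np.array([1.0, 0.0, 0.0, 0.0]),
                                label=fail_label)
        return report("complete-failure", fail_label, supp)

    # a > 1: sign of the case's exponent decides
    if abs(exponent) <= eq_tol:
        return report("critical", "degenerate/critical — not classified", None)

    if exponent < 0.0:
        supp = InvariantSupport(kind="point",
                                point=immune_free_equilibrium(p),
                                label=free_label)
        sub = "immune-free" if case != "Case3" else "extinction-to-immune-free"
        return report(sub, free_label, supp)

    # persistence
    if case == "Case1":
        supp = support_segment(p, "S1")
    elif case == "Case2":
        supp = support_segment(p, "S2")
    else:
        supp = support_segment(p, "Sk", k=k, eq_tol=eq_tol) if k else None
    return report(persist, persist_label, supp)
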