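"""Logarithmic sensitivities, the support bound, and effective Hill coefficients.

The central quantity is d log f / d log x for steady-state responses
f(x) = <A>/<B> or f(x) = pi_X.  Because stationary weights are polynomials
in x with nonnegative coefficients (tree theorem), the sensitivity of a
ratio of observable averages equals the difference of the coefficient-
weighted mean degrees of numerator and denominator, so it is computed as an
exact rational-function derivative, never a finite difference.  Its absolute
value can never exceed m, the size of the perturbation's support, and for a
set probability pi_X the refined form |d log pi_X / d log x| <= m (1 - pi_X)
holds.

Three inequivalent operational definitions of the effective Hill
coefficient are provided: twice the log-slope at the half-maximum point
("midpoint"), log(81) over the log-ratio of inputs giving 90% and 10% of
maximum output ("s90s10"), and the log-slope of the bound/free site odds
("binding").  All of them are bounded by m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .scheme import (
    KineticScheme,
    Observable,
    StatePartition,
    is_detailed_balanced,
    support_size,
)
from .steady_state import (
    SteadyStatePoly,
    arborescence_polynomials,
    steady_state_linear,
)


# ---------------------------------------------------------------------------
# Polynomial machinery
# ---------------------------------------------------------------------------

def observable_poly(polys: SteadyStatePoly, A: Observable) -> np.ndarray:
    """Coefficients of the unnormalized polynomial sum_k A_k pi_k(x)."""
    w = A.array()
    if len(w) != len(polys.coeffs):
        raise ValueError("observable length does not match the scheme")
    out = np.zeros(polys.support_size + 1)
    for k, c in enumerate(polys.coeffs):
        out[: len(c)] += w[k] * c
    return out


def _mean_degree(coeffs: np.ndarray, x: float) -> float:
    """Coefficient-weighted mean degree sum(i c_i x^i)/sum(c_i x^i),
    evaluated stably in the log domain."""
    nz = np.nonzero(coeffs)[0]
    if nz.size == 0:
        raise ArithmeticError("polynomial is identically zero")
    logs = np.log(coeffs[nz]) + nz * math.log(x)
    w = np.exp(logs - logsumexp(logs))
    return float(np.dot(w, nz))


def _poly_log_value(coeffs: np.ndarray, x: float) -> float:
    nz = np.nonzero(coeffs)[0]
    if nz.size == 0:
        raise ArithmeticError("polynomial is identically zero")
    return float(logsumexp(np.log(coeffs[nz]) + nz * math.log(x)))


def _degree_range(coeffs: np.ndarray) -> tuple[int, int]:
    nz = np.nonzero(coeffs)[0]
    return int(nz[0]), int(nz[-1])


# ---------------------------------------------------------------------------
# Sensitivity reports
# ---------------------------------------------------------------------------

@dataclass
class SensitivityReport:
    """An exact logarithmic sensitivity together with its structural bounds.

    ``value`` is d log(<A>/<B>)/d log x (or d log pi_X/d log x when produced
    by :func:`check_support_bound`).  ``degree_interval`` is the interval
    [a_min - b_max, a_max - b_min] from the numerator/denominator degree
    ranges, which always contains the ratio sensitivity.
    """

    value: float
    m: int
    x: float
    degree_interval: tuple[float, float]
    bound_slack: float
    pi_X: float | None = None
    refined_bound: float | None = None
    aux: dict = field(default_factory=dict)


def log_sensitivity(
    scheme: KineticScheme,
    A: Observable,
    B: Observable,
    x: float,
    polys: SteadyStatePoly | None = None,
) -> SensitivityReport:
    """d log(<A>_pi / <B>_pi) / d log x, exact from the tree polynomials."""
    if x <= 0:
        raise ValueError(f"x must be positive, got {x}")
    if polys is None:
        polys = arborescence_polynomials(scheme)
    pa = observable_poly(polys, A)
    pb = observable_poly(polys, B)
    if not pb.any():
        raise ArithmeticError("<B> vanishes identically: invalid observable")
    if not pa.any():
        raise ArithmeticError("<A> vanishes identically: invalid observable")
    value = _mean_degree(pa, x) - _mean_degree(pb, x)
    a_min, a_max = _degree_range(pa)
    b_min, b_max = _degree_range(pb)
    m = polys.support_size
    return SensitivityReport(
        value=value,
        m=m,
        x=x,
        degree_interval=(a_min - b_max, a_max - b_min),
        bound_slack=m - abs(value),
    )


def check_support_bound(
    scheme: KineticScheme,
    X: StatePartition,
    x: float,
    polys: SteadyStatePoly | None = None,
    tol: float = 1e-9,
) -> SensitivityReport:
    """d log pi_X / d log x with the refined bound m (1 - pi_X) asserted."""
    if polys is None:
        polys = arborescence_polynomials(scheme)
    A, B = X.indicator_pair(scheme)
    ratio = log_sensitivity(scheme, A, B, x, polys=polys)
    la = _poly_log_value(observable_poly(polys, A), x)
    lb = _poly_log_value(observable_poly(polys, B), x)
    pi_X = float(np.exp(la - np.logaddexp(la, lb)))
    value = (1.0 - pi_X) * ratio.value
    bound = ratio.m * (1.0 - pi_X)
    if abs(value) > bound + tol:
        raise AssertionError(
            f"support bound violated: |{value:g}| > {ratio.m}*(1-{pi_X:g})"
        )
    return SensitivityReport(
        value=value,
        m=ratio.m,
        x=x,
        degree_interval=ratio.degree_interval,
        bound_slack=bound - abs(value),
        pi_X=pi_X,
        refined_bound=bound,
    )


# ---------------------------------------------------------------------------
# Response curves
# ---------------------------------------------------------------------------

class ResponseCurve:
    """An evaluable map x > 0 -> f(x) with queryable limits f(0+), f(inf).

    Scheme-backed curves carry an exact logarithmic derivative via the tree
    polynomials; closed-form curves may supply one, else a central
    difference in log x (step 1e-6) is used.
    """

    def __init__(self, fn, f0: float, finf: float, log_derivative=None, label: str = ""):
        self._fn = fn
        self.f0 = float(f0)
        self.finf = float(finf)
        self._logderiv = log_derivative
        self.label = label

    def __call__(self, x: float) -> float:
        if x <= 0:
            raise ValueError(f"x must be positive, got {x}")
        return float(self._fn(x))

    def log_derivative(self, x: float, step: float = 1e-6) -> float:
        if self._logderiv is not None:
            return float(self._logderiv(x))
        hi = self(x * math.exp(step))
        lo = self(x * math.exp(-step))
        return (math.log(hi) - math.log(lo)) / (2 * step)

    def is_monotone(self, lo: float = 1e-9, hi: float = 1e9, npoints: int = 64) -> bool:
        xs = np.geomspace(lo, hi, npoints)
        ys = np.array([self(x) for x in xs])
        scale = np.abs(ys).max()
        return bool(np.all(np.diff(ys) >= -1e-12 * max(scale, 1.0)))

    # -- constructors -----------------------------------------------------
    @classmethod
    def hill(cls, H: float, K: float) -> "ResponseCurve":
        """Reference Hill curve x^H/(K^H + x^H); log-slope H (1 - f)."""

        def fn(x: float) -> float:
            z = (x / K) ** H
            return z / (1.0 + z)

        return cls(fn, 0.0, 1.0, log_derivative=lambda x: H * (1.0 - fn(x)),
                   label=f"hill(H={H}, K={K})")

    @classmethod
    def from_scheme_partition(
        cls, scheme: KineticScheme, X: StatePartition,
        polys: SteadyStatePoly | None = None, exact: bool = False,
    ) -> "ResponseCurve":
        """The curve x -> pi_X(x) of a kinetic scheme."""
        if polys is None:
            polys = arborescence_polynomials(scheme, exact=exact)
        A, B = X.indicator_pair(scheme)
        pa = observable_poly(polys, A)
        pb = observable_poly(polys, B)
        a_min, a_max = _degree_range(pa)
        b_min, b_max = _degree_range(pb)

        def fn(x: float) -> float:
            la = _poly_log_value(pa, x)
            lb = _poly_log_value(pb, x)
            return float(np.exp(la - np.logaddexp(la, lb)))

        if a_min < b_min:
            f0 = 1.0
        elif a_min > b_min:
            f0 = 0.0
        else:
            f0 = pa[a_min] / (pa[a_min] + pb[b_min])
        if a_max > b_max:
            finf = 1.0
        elif a_max < b_max:
            finf = 0.0
        else:
            finf = pa[a_max] / (pa[a_max] + pb[b_max])

        def logderiv(x: float) -> float:
            return (1.0 - fn(x)) * (_mean_degree(pa, x) - _mean_degree(pb, x))

        return cls(fn, f0, finf, log_derivative=logderiv, label="pi_X")

    @classmethod
    def from_scheme_observables(
        cls, scheme: KineticScheme, A: Observable, B: Observable,
        polys: SteadyStatePoly | None = None, exact: bool = False,
    ) -> "ResponseCurve":
        """The curve x -> <A>/<B> of a kinetic scheme."""
        if polys is None:
            polys = arborescence_polynomials(scheme, exact=exact)
        pa = observable_poly(polys, A)
        pb = observable_poly(polys, B)
        a_min, a_max = _degree_range(pa)
        b_min, b_max = _degree_range(pb)

        def fn(x: float) -> float:
            return float(np.exp(_poly_log_value(pa, x) - _poly_log_value(pb, x)))

        f0 = pa[a_min] / pb[b_min] if a_min == b_min else (0.0 if a_min > b_min else math.inf)
        finf = pa[a_max] / pb[b_max] if a_max == b_max else (0.0 if a_max < b_max else math.inf)

        def logderiv(x: float) -> float:
            return _mean_degree(pa, x) - _mean_degree(pb, x)

        return cls(fn, f0, finf, log_derivative=logderiv, label="<A>/<B>")


# ---------------------------------------------------------------------------
# Root finding on monotone curves
# ---------------------------------------------------------------------------

_BRACKET_LO = 1e-12
_BRACKET_HI = 1e12


def _solve_level(curve: ResponseCurve, target: float, tol: float = 1e-12) -> float:
    """x with curve(x) = target, by bisection in log x on [1e-12, 1e12]."""
    lo, hi = math.log(_BRACKET_LO), math.log(_BRACKET_HI)
    flo = curve(math.exp(lo)) - target
    fhi = curve(math.exp(hi)) - target
    if flo == 0.0:
        return math.exp(lo)
    if fhi == 0.0:
        return math.exp(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"no bracket for level {target:g} on x in [{_BRACKET_LO:g}, {_BRACKET_HI:g}]"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        fmid = curve(math.exp(mid)) - target
        if fmid == 0.0:
            return math.exp(mid)
        if fmid * flo < 0:
            hi = mid
        else:
            lo, flo = mid, fmid
    return math.exp(0.5 * (lo + hi))


def _require_monotone(curve: ResponseCurve) -> None:
    if not curve.is_monotone():
        raise ValueError(
            f"curve {curve.label or repr(curve)} is not monotone increasing on "
            "the scanned range; Hill estimators are undefined"
        )


# ---------------------------------------------------------------------------
# Effective Hill coefficients
# ---------------------------------------------------------------------------

@dataclass
class HillEstimate:
    """An effective Hill coefficient with its method tag and auxiliary points."""

    method: str  # "midpoint" | "s90s10" | "binding"
    value: float
    aux: dict = field(default_factory=dict)


def hill_midpoint(curve: ResponseCurve) -> HillEstimate:
    """Twice the logarithmic slope at the half-maximum point x*."""
    _require_monotone(curve)
    if not (math.isfinite(curve.f0) and math.isfinite(curve.finf)):
        raise ValueError("curve limits must be finite for the midpoint estimator")
    target = 0.5 * (curve.f0 + curve.finf)
    x_star = _solve_level(curve, target)
    value = 2.0 * curve.log_derivative(x_star)
    return HillEstimate("midpoint", value,
                        aux={"x_star": x_star, "f0": curve.f0, "finf": curve.finf})


def hill_s90s10(curve: ResponseCurve) -> HillEstimate:
    """log(81) / log(S_0.9 / S_0.1) with S_p solving f = p * f(inf)."""
    _require_monotone(curve)
    f_max = curve.finf
    if not math.isfinite(f_max) or f_max <= 0:
        raise ValueError("curve maximum f(inf) must be finite and positive")
    if curve.f0 >= 0.1 * f_max:
        raise ValueError(
            f"f(0+) = {curve.f0:g} >= 10% of f(inf) = {f_max:g}: the 10% point "
            "does not exist on this curve"
        )
    s10 = _solve_level(curve, 0.1 * f_max)
    s90 = _solve_level(curve, 0.9 * f_max)
    value = math.log(81.0) / math.log(s90 / s10)
    return HillEstimate("s90s10", value, aux={"S_0.1": s10, "S_0.9": s90, "f_max": f_max})


def hill_binding(
    scheme: KineticScheme, x: float, polys: SteadyStatePoly | None = None
) -> HillEstimate:
    """Log-slope of the bound/free site odds <n_b>/(n - <n_b>) at x."""
    if scheme.n_bound is None:
        raise ValueError("scheme has no n_bound labels: binding estimator undefined")
    n = max(scheme.n_bound.values())
    if n <= 0:
        raise ValueError("scheme never binds a ligand")
    nb = [float(scheme.n_bound[s]) for s in scheme.states]
    free = [float(n - scheme.n_bound[s]) for s in scheme.states]
    if max(free) <= 0:
        raise ValueError("<n_b> = n identically: the odds ratio diverges")
    A = Observable(tuple(nb))
    B = Observable(tuple(free))
    rep = log_sensitivity(scheme, A, B, x, polys=polys)
    return HillEstimate("binding", rep.value, aux={"x": x, "n": n})


def fold_change_witness(curve: ResponseCurve, x0: float, a: float) -> float:
    """log(f(a x0)/f(x0)) / log(a): a fold-change amplification that, by the
    mean value theorem, is witnessed by the local log-sensitivity somewhere
    in [x0, a x0]."""
    if a <= 1:
        raise ValueError(f"fold factor a must exceed 1, got {a}")
    return math.log(curve(a * x0) / curve(x0)) / math.log(a)


# ---------------------------------------------------------------------------
# Equilibrium sensitivity formula
# ---------------------------------------------------------------------------

def equilibrium_hill(
    scheme: KineticScheme, X: StatePartition, x: float, db_rtol: float = 1e-9
) -> float:
    """Conditional-occupancy difference <n_b>_X - <n_b>_Xbar.

    For a detailed-balanced binding scheme this equals the effective Hill
    coefficient in the identity
    d log pi_X / d log x = (<n_b>_X - <n_b>_Xbar)(1 - pi_X), and it can
    never exceed the number of binding sites.
    """
    if scheme.n_bound is None:
        raise ValueError("scheme has no n_bound labels")
    balanced, worst = is_detailed_balanced(scheme, x, rtol=db_rtol)
    if not balanced:
        raise ValueError(
            f"scheme is not detailed balanced (worst cycle ratio {worst:g}); "
            "the equilibrium formula does not apply"
        )
    pi = steady_state_linear(scheme, x)
    in_X = np.array([s in X.X for s in scheme.states])
    if in_X.all() or not in_X.any():
        raise ValueError("partition set X must be a nonempty proper subset")
    nb = np.array([scheme.n_bound[s] for s in scheme.states], dtype=float)
    p_X = pi[in_X].sum()
    mean_X = float(np.dot(nb[in_X], pi[in_X]) / p_X)
    mean_Xbar = float(np.dot(nb[~in_X], pi[~in_X]) / (1.0 - p_X))
    return mean_X - mean_Xbar
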