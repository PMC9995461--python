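"""Constructors for the scheme families where the support bound is informative.

Families
--------
* equilibrium independent-site binding (hypercube, detailed balanced)
* general unordered binding on the n-dimensional hypercube
* nonequilibrium MWC: two conformational rings (CW/CCW) of n binding sites
  coupled by concerted flips, as in models of the flagellar motor switch
* the 3-state Hopfield kinetic-proofreading cycle and general
  "discriminatory fence" schemes, with the discriminatory index nu
* nonequilibrium receptors for concentration sensing, with the
  support-based lower bound on the sensing error
* nested hysteresis: gated, timescale-separated unordered binding whose
  fully-bound probability approaches a Hill function with H = 2^n - 1

Site convention for hypercube-like schemes: states are bit strings
("010" means only site 2 occupied); character i-1 of the label is site i.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .scheme import (
    Edge,
    KineticScheme,
    Observable,
    StatePartition,
    support,
    support_size,
)
from .sensitivity import log_sensitivity
from .steady_state import SteadyStatePoly, arborescence_polynomials

MAX_HYPERCUBE_SITES = 12


def _bits_label(bits: tuple[int, ...]) -> str:
    return "".join(str(b) for b in bits)


def _hypercube_states(n: int) -> list[tuple[int, ...]]:
    return list(itertools.product((0, 1), repeat=n))


# ---------------------------------------------------------------------------
# Unordered binding on the hypercube
# ---------------------------------------------------------------------------

def make_hypercube(n: int, rate_fn=None) -> KineticScheme:
    """Unordered binding of a ligand to ``n`` distinguishable sites.

    ``rate_fn(src_bits, dst_bits) -> rate`` gives the base rate of each
    single-site flip (default 1.0 everywhere); binding flips (occupancy +1)
    additionally carry one factor of x.  The support is every state except
    the fully bound one: m = 2^n - 1.
    """
    if not 1 <= n <= MAX_HYPERCUBE_SITES:
        raise ValueError(f"n must be in 1..{MAX_HYPERCUBE_SITES}, got {n}")
    if rate_fn is None:
        rate_fn = lambda src, dst: 1.0  # noqa: E731
    states = _hypercube_states(n)
    edges = []
    for bits in states:
        for i in range(n):
            flipped = bits[:i] + (1 - bits[i],) + bits[i + 1:]
            rate = float(rate_fn(bits, flipped))
            if rate <= 0:
                raise ValueError(f"rate_fn must be positive on {bits}->{flipped}")
            binding = flipped[i] == 1
            edges.append(Edge(_bits_label(bits), _bits_label(flipped), rate,
                              x_power=1 if binding else 0))
    labels = [_bits_label(b) for b in states]
    n_bound = {_bits_label(b): sum(b) for b in states}
    named = {"all_bound": ["1" * n], "empty": ["0" * n]}
    return KineticScheme(labels, edges, n_bound=n_bound, named_sets=named)


def make_independent_sites(n: int, dissociation_constants=None) -> KineticScheme:
    """Equilibrium binding to ``n`` independent sites: site i binds at rate
    x / K_i and unbinds at rate 1 regardless of the other sites."""
    if dissociation_constants is None:
        dissociation_constants = [1.0] * n
    Ks = [float(K) for K in dissociation_constants]
    if len(Ks) != n or any(K <= 0 for K in Ks):
        raise ValueError(f"need {n} positive dissociation constants")

    def rate_fn(src, dst):
        i = next(j for j in range(n) if src[j] != dst[j])
        return 1.0 / Ks[i] if dst[i] == 1 else 1.0

    return make_hypercube(n, rate_fn)


# ---------------------------------------------------------------------------
# Nonequilibrium MWC (two rings of n sites with concerted flips)
# ---------------------------------------------------------------------------

def make_mwc_noneq(n: int, rates: dict) -> KineticScheme:
    """Two conformational rings (CW and CCW) of occupancies 0..n.

    ``rates`` must provide:

    * ``rates["bind"][ring][j]``   -- base rate of occupancy j -> j+1
      (carries x), for ring in {"CW", "CCW"} and j = 0..n-1; must be > 0
    * ``rates["unbind"][ring][j]`` -- rate of j+1 -> j; must be > 0
    * ``rates["flip"]["CCW_to_CW"][j]`` and ``rates["flip"]["CW_to_CCW"][j]``
      for j = 0..n; a zero entry means the flip is absent at that occupancy.

    The support is every state with an outgoing binding edge: m = 2n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    try:
        bind = {r: list(rates["bind"][r]) for r in ("CW", "CCW")}
        unbind = {r: list(rates["unbind"][r]) for r in ("CW", "CCW")}
        flip = {d: list(rates["flip"][d]) for d in ("CCW_to_CW", "CW_to_CCW")}
    except KeyError as exc:
        raise ValueError(f"incomplete MWC rate table: missing {exc}") from None
    for r in ("CW", "CCW"):
        if len(bind[r]) != n or len(unbind[r]) != n:
            raise ValueError(f"{r} ring needs {n} bind and {n} unbind rates")
        if any(v <= 0 for v in bind[r] + unbind[r]):
            raise ValueError("bind/unbind rates must be strictly positive")
    for d in flip:
        if len(flip[d]) != n + 1:
            raise ValueError(f"{d} needs {n + 1} flip rates (occupancy 0..n)")

    states = [f"{ring}{j}" for ring in ("CCW", "CW") for j in range(n + 1)]
    edges = []
    for ring in ("CCW", "CW"):
        for j in range(n):
            edges.append(Edge(f"{ring}{j}", f"{ring}{j + 1}", bind[ring][j], x_power=1))
            edges.append(Edge(f"{ring}{j + 1}", f"{ring}{j}", unbind[ring][j]))
    for j in range(n + 1):
        if flip["CCW_to_CW"][j] > 0:
            edges.append(Edge(f"CCW{j}", f"CW{j}", flip["CCW_to_CW"][j]))
        if flip["CW_to_CCW"][j] > 0:
            edges.append(Edge(f"CW{j}", f"CCW{j}", flip["CW_to_CCW"][j]))
    named = {
        "CW": [f"CW{j}" for j in range(n + 1)],
        "CCW": [f"CCW{j}" for j in range(n + 1)],
    }
    n_bound = {f"{ring}{j}": j for ring in ("CW", "CCW") for j in range(n + 1)}
    scheme = KineticScheme(states, edges, n_bound=n_bound, named_sets=named)
    if not scheme.is_strongly_connected():
        raise ValueError("MWC rate table leaves the scheme reducible (no flips?)")
    return scheme


def mwc_equilibrium_rates(n: int, K_cw: float = 0.2, K_ccw: float = 5.0,
                          flip0: float = 0.01) -> dict:
    """A detailed-balanced MWC parameterization: flips scale geometrically so
    every square cycle of the ladder satisfies the Kolmogorov criterion."""
    return {
        "bind": {"CW": [1.0] * n, "CCW": [1.0] * n},
        "unbind": {"CW": [K_cw] * n, "CCW": [K_ccw] * n},
        "flip": {
            "CCW_to_CW": [flip0 * (K_ccw / K_cw) ** j for j in range(n + 1)],
            "CW_to_CCW": [1.0] * (n + 1),
        },
    }


def mwc_saturating_rates(n: int, lam: float) -> dict:
    """A one-parameter driven family approaching the support bound H -> 2n.

    The scheme runs a hysteresis loop: climb the CCW ring by binding, flip
    at full occupancy, descend the CW ring by unbinding, flip back when
    empty.  The loop's extreme states (CCW empty, CW full) are stabilized
    and the bottom flip weakened by eps = 1/lam, so as lam grows the
    clockwise bias pi_CW approaches a Hill function of coefficient 2n.
    """
    if lam <= 1:
        raise ValueError("lam must exceed 1")
    eps = 1.0 / lam
    return {
        "bind": {"CW": [1.0] * n, "CCW": [eps] + [1.0] * (n - 1)},
        "unbind": {"CW": [1.0] * (n - 1) + [eps], "CCW": [1.0] * n},
        "flip": {
            "CCW_to_CW": [0.0] * n + [1.0],
            "CW_to_CCW": [eps] + [0.0] * n,
        },
    }


# ---------------------------------------------------------------------------
# Kinetic proofreading
# ---------------------------------------------------------------------------

HOPFIELD_STATES = ("E", "EW", "EW*")


def make_hopfield_kp(rates) -> KineticScheme:
    """The 3-state Hopfield proofreading cycle E <-> EW <-> EW* <-> E.

    ``rates`` is a 6-tuple of positive base rates
    (E->EW, EW->E, EW->EW*, EW*->EW, EW*->E, E->EW*).  Both dissociation
    edges of the wrong substrate (EW->E and EW*->E) carry x = exp(Delta),
    the Boltzmann factor of the substrate free-energy difference, so the
    support is {EW, EW*} and m = 2.
    """
    vals = [float(r) for r in rates]
    if len(vals) != 6 or any(v <= 0 for v in vals):
        raise ValueError("need 6 strictly positive rates")
    a, b, c, d, e, f = vals
    edges = [
        Edge("E", "EW", a),
        Edge("EW", "E", b, x_power=1),
        Edge("EW", "EW*", c),
        Edge("EW*", "EW", d),
        Edge("EW*", "E", e, x_power=1),
        Edge("E", "EW*", f),
    ]
    named = {"bound": ["EW", "EW*"], "free": ["E"]}
    return KineticScheme(list(HOPFIELD_STATES), edges, named_sets=named)


def hopfield_equilibrium_rates() -> tuple[float, ...]:
    """Rates whose cycle products balance for every x: nu = 1 identically."""
    return (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)


def hopfield_saturating_rates(lam: float) -> tuple[float, ...]:
    """Strongly driven one-parameter family with nu -> 2 as lam -> inf."""
    if lam <= 1:
        raise ValueError("lam must exceed 1")
    return (1.0, lam**2, 1.0, 1.0, lam, lam**3)


def discriminatory_index(
    scheme: KineticScheme,
    bound_state: str = "EW",
    free_state: str = "E",
    delta: float = 0.0,
    polys: SteadyStatePoly | None = None,
) -> float:
    """nu = -d log(pi_bound / pi_free) / d Delta at x = exp(delta).

    Since x multiplies the discard rates, d/dDelta = d/dlog x, and the
    support bound gives nu <= m.
    """
    x = math.exp(delta)
    A = Observable.indicator(scheme, [bound_state])
    B = Observable.indicator(scheme, [free_state])
    return -log_sensitivity(scheme, A, B, x, polys=polys).value


# ---------------------------------------------------------------------------
# Discriminatory fences and sensing receptors
# ---------------------------------------------------------------------------

def make_fence_scheme(nX: int, nY: int, crossings, internal,
                      n_bound: dict | None = None) -> KineticScheme:
    """A scheme split into sides X (states X0..) and Y (states Y0..) where
    every x-dependent edge crosses from Y to X (the "discriminatory fence").

    ``crossings`` and ``internal`` are iterables of
    ``(src, dst, rate, x_power)`` tuples; internal edges must stay within
    one side and be x-independent.  The support is the set of Y-side
    boundary states with x-dependent crossing exits.
    """
    X_states = [f"X{i}" for i in range(nX)]
    Y_states = [f"Y{i}" for i in range(nY)]
    Xset, Yset = set(X_states), set(Y_states)
    edges = []
    for (src, dst, rate, xp) in crossings:
        if xp == 1 and not (src in Yset and dst in Xset):
            raise ValueError(
                f"x-dependent edge {src}->{dst} does not cross from Y to X"
            )
        if (src in Xset) == (dst in Xset):
            raise ValueError(f"crossing {src}->{dst} does not cross the fence")
        edges.append(Edge(src, dst, float(rate), x_power=int(xp)))
    for (src, dst, rate, xp) in internal:
        if xp != 0:
            raise ValueError(f"internal edge {src}->{dst} must be x-independent")
        if (src in Xset) != (dst in Xset):
            raise ValueError(f"internal edge {src}->{dst} crosses the fence")
        edges.append(Edge(src, dst, float(rate)))
    named = {"X": X_states, "Y": Y_states}
    return KineticScheme(X_states + Y_states, edges, n_bound=n_bound, named_sets=named)


@dataclass
class SensingSetup:
    """A receptor scheme sensing a ligand concentration c (the x parameter).

    ``Y`` is the set of signaling (ligand-bound) states; the bound/unbound
    separation plays the role of the fence, so every c-dependent edge must
    cross the X/Y boundary.  ``R_T`` independent receptor copies are read
    out at one instant.
    """

    scheme: KineticScheme
    Y: frozenset
    R_T: int
    c: float

    def __post_init__(self) -> None:
        self.Y = frozenset(self.Y)
        states = set(self.scheme.states)
        if not self.Y or not (self.Y < states):
            raise ValueError("Y must be a nonempty proper subset of the states")
        if self.R_T < 1:
            raise ValueError("R_T must be a positive integer")
        if self.c <= 0:
            raise ValueError("c must be positive")
        for e in self.scheme.edges:
            if e.x_power == 1 and (e.src in self.Y) == (e.dst in self.Y):
                raise ValueError(
                    f"x-dependent edge {e.src}->{e.dst} does not cross the "
                    "X/Y boundary"
                )


def sensing_error(setup: SensingSetup) -> tuple[float, float]:
    """Relative squared error of the concentration estimate from the
    instantaneous count of signaling receptors, and its support bound.

    Returns ``(eps2, bound)`` with
    eps2 = pi_Y (1-pi_Y) / (R_T (c dpi_Y/dc)^2) (binomial readout variance)
    and bound = 1 / (R_T m^2 pi_X (1 - pi_X)) >= 4 / (R_T m^2).
    """
    scheme = setup.scheme
    polys = arborescence_polynomials(scheme)
    A = Observable.indicator(scheme, setup.Y)
    B = Observable.indicator(scheme, set(scheme.states) - setup.Y)
    rep = log_sensitivity(scheme, A, B, setup.c, polys=polys)
    dist = polys.distribution(setup.c)
    pi_Y = float(sum(p for s, p in zip(scheme.states, dist) if s in setup.Y))
    if not 0.0 < pi_Y < 1.0:
        raise ValueError(f"degenerate signaling probability pi_Y = {pi_Y}")
    slope = pi_Y * (1.0 - pi_Y) * rep.value  # = c dpi_Y/dc
    if slope == 0.0:
        raise ArithmeticError("pi_Y does not respond to c: estimator undefined")
    eps2 = pi_Y * (1.0 - pi_Y) / (setup.R_T * slope**2)
    m = rep.m
    pi_X = 1.0 - pi_Y
    bound = 1.0 / (setup.R_T * m**2 * pi_X * (1.0 - pi_X))
    if eps2 < bound * (1.0 - 1e-9):
        raise AssertionError("sensing error fell below its support bound")
    if bound < 4.0 / (setup.R_T * m**2) * (1.0 - 1e-12):
        raise AssertionError("support bound fell below 4/(R_T m^2)")
    return eps2, bound


# ---------------------------------------------------------------------------
# Nested hysteresis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NestedHysteresisSpec:
    """n gated sites, timescale factor s > 1, extreme-state stabilization
    factor q in (0, 1] slowing every exit from the empty and full states."""

    n: int
    s: float
    q: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.s <= 1:
            raise ValueError("s must exceed 1")
        if not 0 < self.q <= 1:
            raise ValueError("q must be in (0, 1]")


def make_nested_hysteresis(spec: NestedHysteresisSpec | None = None, *,
                           n: int | None = None, s: float | None = None,
                           q: float = 1.0) -> KineticScheme:
    """The nested-hysteresis scheme: a gated hypercube subgraph.

    Site i can bind only when all lower-numbered sites are bound and unbind
    only when all lower-numbered sites are unbound; allowed flips at site i
    run a factor s^-(i-1) slower than at site i-1, with binding/unbinding
    rate ratio x at every allowed flip.  All exits from the all-empty and
    all-full states are additionally slowed by q.
    """
    if spec is None:
        if n is None or s is None:
            raise ValueError("provide a NestedHysteresisSpec or n= and s=")
        spec = NestedHysteresisSpec(n, s, q)
    n, s, q = spec.n, spec.s, spec.q
    empty, full = (0,) * n, (1,) * n
    edges = []
    for bits in _hypercube_states(n):
        scale = q if bits in (empty, full) else 1.0
        for i in range(n):
            lower = bits[:i]
            if bits[i] == 0 and all(b == 1 for b in lower):
                dst = bits[:i] + (1,) + bits[i + 1:]
                edges.append(Edge(_bits_label(bits), _bits_label(dst),
                                  scale * s ** (-i), x_power=1))
            elif bits[i] == 1 and all(b == 0 for b in lower):
                dst = bits[:i] + (0,) + bits[i + 1:]
                edges.append(Edge(_bits_label(bits), _bits_label(dst),
                                  scale * s ** (-i)))
    labels = [_bits_label(b) for b in _hypercube_states(n)]
    if n == 1:
        scheme = KineticScheme(labels, edges,
                               n_bound={"0": 0, "1": 1},
                               named_sets={"all_bound": ["1"], "empty": ["0"]})
    else:
        n_bound = {_bits_label(b): sum(b) for b in _hypercube_states(n)}
        named = {"all_bound": [_bits_label(full)], "empty": [_bits_label(empty)]}
        scheme = KineticScheme(labels, edges, n_bound=n_bound, named_sets=named)
    if not scheme.is_strongly_connected():
        raise AssertionError("nested hysteresis scheme must be strongly connected")
    return scheme


def nested_hysteresis_exact(n: int, x: float, q: float = 1.0):
    """Strong-timescale-separation limit of nested hysteresis.

    Returns ``(marginals, pi_all)``: the per-site bound probabilities
    pi(site i bound) = x^(2^(i-1)) / (1 + x^(2^(i-1))) and the fully bound
    probability pi_all = x^(2^n - 1) / (1 + q sum_{j=1}^{2^n-2} x^j +
    x^(2^n - 1)); q = 1 recovers the plain geometric-sum form, and q -> 0
    approaches a Hill function with H = 2^n - 1.
    """
    if x <= 0:
        raise ValueError("x must be positive")
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    marginals = np.array([x ** (2 ** i) / (1.0 + x ** (2 ** i)) for i in range(n)])
    top = 2 ** n - 1
    middle = sum(x ** j for j in range(1, top))
    pi_all = x ** top / (1.0 + q * middle + x ** top)
    return marginals, pi_all


def nested_hysteresis_curve(spec: NestedHysteresisSpec, exact: bool = True):
    """The scheme-backed response curve x -> pi_all for nested hysteresis.

    Rational-arithmetic tree polynomials are used by default: with strong
    timescale separation the polynomial coefficients span many orders of
    magnitude and exact interpolation preserves them all.
    """
    from .sensitivity import ResponseCurve

    scheme = make_nested_hysteresis(spec)
    full = "1" * spec.n
    return ResponseCurve.from_scheme_partition(
        scheme, StatePartition([full]), exact=exact
    )


# ---------------------------------------------------------------------------
# Reference support sizes (structure only, no rates involved)
# ---------------------------------------------------------------------------

def family_support_sizes(n: int) -> dict[str, int]:
    """Support sizes for the three model families with n sites/boundary
    states, alongside their equilibrium Hill-coefficient bounds."""
    return {"kp_ladder": n, "mwc": 2 * n, "unordered": 2 ** n - 1}
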