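"""Steady-state distributions by two independent routes.

1. A direct linear solve at fixed ``x`` using the GTH (Grassmann-Taksar-
   Heyman) elimination, which involves no subtractions and is therefore
   componentwise accurate even when stationary probabilities span many
   orders of magnitude.
2. The Markov chain tree theorem: the unnormalized stationary weight of a
   state k is the sum over spanning in-trees rooted at k of the product of
   edge rates.  Because every x-dependent edge contributes one factor of x
   and an in-tree uses at most one outgoing edge per state, each weight is a
   polynomial in x with nonnegative coefficients and degree at most m, the
   size of the perturbation's support.  These polynomials make logarithmic
   sensitivities exact rational-function derivatives.

Two polynomial backends are provided: explicit in-tree enumeration (small
schemes; also the exact oracle) and interpolation of principal minors of the
negated generator on a geometric grid (all schemes; optionally in exact
rational arithmetic).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.special import logsumexp

from .scheme import KineticScheme, Observable, require_strongly_connected, support_size

DEFAULT_TREE_CAP = 10**6


@dataclass
class SteadyStatePoly:
    """Per-state unnormalized stationary weights as polynomials in x.

    ``coeffs[k][i]`` is the coefficient of x**i in the weight of state k
    (degree-ascending, nonnegative).  ``exact_coeffs`` holds the same data
    as ``Fraction`` lists when computed in rational arithmetic.
    """

    states: list[str]
    coeffs: list[np.ndarray]
    support_size: int
    exact_coeffs: list[list[Fraction]] | None = None

    def degree(self, k: int) -> int:
        nz = np.nonzero(self.coeffs[k])[0]
        return int(nz[-1]) if nz.size else 0

    def min_degree(self, k: int) -> int:
        nz = np.nonzero(self.coeffs[k])[0]
        return int(nz[0]) if nz.size else 0

    def log_evaluate(self, x: float) -> np.ndarray:
        """log of each unnormalized weight, stable for extreme x."""
        if x <= 0:
            raise ValueError(f"x must be positive, got {x}")
        lx = math.log(x)
        out = np.empty(len(self.coeffs))
        for k, c in enumerate(self.coeffs):
            nz = np.nonzero(c)[0]
            if nz.size == 0:
                raise ArithmeticError(f"state {self.states[k]!r} has zero weight")
            out[k] = logsumexp(np.log(c[nz]) + nz * lx)
        return out

    def distribution(self, x: float) -> np.ndarray:
        logs = self.log_evaluate(x)
        return np.exp(logs - logsumexp(logs))


def steady_state_from_polys(polys: SteadyStatePoly, x: float) -> np.ndarray:
    """Evaluate and normalize the tree-theorem polynomials at ``x``."""
    return polys.distribution(x)


def observable_average(dist: np.ndarray, A: Observable) -> float:
    """Steady-state average <A> = sum_i A_i pi_i."""
    return float(np.dot(dist, A.array()))


# ---------------------------------------------------------------------------
# Linear solve (GTH elimination)
# ---------------------------------------------------------------------------

def _gth(rates: np.ndarray) -> np.ndarray:
    """Stationary vector from the matrix of rates[i, j] = rate(i -> j).

    GTH elimination: folds states in from the last, using only additions,
    multiplications and divisions of nonnegative numbers.
    """
    R = rates.astype(float).copy()
    N = R.shape[0]
    np.fill_diagonal(R, 0.0)
    for n in range(N - 1, 0, -1):
        s = R[n, :n].sum()
        if s <= 0:
            raise ValueError("scheme is not strongly connected (GTH pivot vanished)")
        R[:n, n] /= s
        R[:n, :n] += np.outer(R[:n, n], R[n, :n])
        np.fill_diagonal(R[:n, :n], 0.0)
    pi = np.zeros(N)
    pi[0] = 1.0
    for n in range(1, N):
        pi[n] = pi[:n] @ R[:n, n]
    return pi / pi.sum()


def steady_state_linear(scheme: KineticScheme, x: float) -> np.ndarray:
    """Unique stationary distribution of the scheme at parameter value x."""
    require_strongly_connected(scheme)
    if x <= 0:
        raise ValueError(f"x must be positive, got {x}")
    N = scheme.n_states
    idx = {s: i for i, s in enumerate(scheme.states)}
    rates = np.zeros((N, N))
    for e in scheme.edges:
        if e.base_rate <= 0:
            raise ValueError(f"edge {e.src!r}->{e.dst!r} has nonpositive rate")
        rates[idx[e.src], idx[e.dst]] += e.rate_at(x)
    pi = _gth(rates)
    W = scheme.rate_matrix(x)
    resid = np.abs(W @ pi).max()
    if resid >= 1e-10 * rates.max():
        raise ArithmeticError(f"steady-state residual too large: {resid:g}")
    return pi


# ---------------------------------------------------------------------------
# Backend (a): explicit in-tree enumeration
# ---------------------------------------------------------------------------

def count_undirected_spanning_trees(scheme: KineticScheme) -> int:
    """Kirchhoff count of spanning trees of the undirected edge skeleton.

    Upper-bounds the number of rooted in-trees for any root, so it serves as
    the enumeration-cost cap.
    """
    pairs = {frozenset((e.src, e.dst)) for e in scheme.edges}
    N = scheme.n_states
    idx = {s: i for i, s in enumerate(scheme.states)}
    L = np.zeros((N, N))
    for pair in pairs:
        u, v = tuple(pair)
        i, j = idx[u], idx[v]
        L[i, i] += 1
        L[j, j] += 1
        L[i, j] -= 1
        L[j, i] -= 1
    return int(round(np.linalg.det(L[1:, 1:])))


def _undirected_spanning_trees(pairs: list[tuple[str, str]], states: list[str]):
    """Yield spanning trees (as tuples of undirected pairs) by exhaustive
    combination + union-find acyclicity check.  Intended for small schemes."""
    N = len(states)
    idx = {s: i for i, s in enumerate(states)}
    for combo in itertools.combinations(pairs, N - 1):
        parent = list(range(N))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        ok = True
        for (u, v) in combo:
            ru, rv = find(idx[u]), find(idx[v])
            if ru == rv:
                ok = False
                break
            parent[ru] = rv
        if ok:
            yield combo


def _enumerate_polys(scheme: KineticScheme, exact: bool, max_trees: int) -> SteadyStatePoly:
    n_trees = count_undirected_spanning_trees(scheme)
    if n_trees > max_trees:
        raise ValueError(
            f"scheme has ~{n_trees} spanning trees, above the enumeration cap "
            f"{max_trees}; use the interpolation backend"
        )
    m = support_size(scheme)
    edge_map = scheme.edge_rates()
    pairs = sorted({tuple(sorted((e.src, e.dst))) for e in scheme.edges})
    trees = list(_undirected_spanning_trees(pairs, scheme.states))

    zero = Fraction(0) if exact else 0.0
    acc = [[zero] * (m + 1) for _ in scheme.states]
    for tree in trees:
        adj: dict[str, list[str]] = {s: [] for s in scheme.states}
        for (u, v) in tree:
            adj[u].append(v)
            adj[v].append(u)
        for root_i, root in enumerate(scheme.states):
            # orient every tree edge toward the root (child -> parent)
            parent = {root: None}
            stack = [root]
            order = []
            while stack:
                node = stack.pop()
                order.append(node)
                for nb in adj[node]:
                    if nb not in parent:
                        parent[nb] = node
                        stack.append(nb)
            prod = Fraction(1) if exact else 1.0
            xdeg = 0
            valid = True
            for node in order:
                p = parent[node]
                if p is None:
                    continue
                e = edge_map.get((node, p))
                if e is None:
                    valid = False
                    break
                prod *= Fraction(e.base_rate) if exact else e.base_rate
                xdeg += e.x_power
            if valid:
                acc[root_i][xdeg] += prod
    coeffs = [np.array([float(c) for c in row]) for row in acc]
    exact_coeffs = acc if exact else None
    return SteadyStatePoly(list(scheme.states), coeffs, m, exact_coeffs=exact_coeffs)


# ---------------------------------------------------------------------------
# Backend (b): principal-minor interpolation
# ---------------------------------------------------------------------------

def _frac_det(M: list[list[Fraction]]) -> Fraction:
    """Exact determinant by fraction-preserving Gaussian elimination."""
    n = len(M)
    A = [row[:] for row in M]
    det = Fraction(1)
    for col in range(n):
        piv = next((r for r in range(col, n) if A[r][col] != 0), None)
        if piv is None:
            return Fraction(0)
        if piv != col:
            A[col], A[piv] = A[piv], A[col]
            det = -det
        det *= A[col][col]
        inv = Fraction(1) / A[col][col]
        for r in range(col + 1, n):
            factor = A[r][col] * inv
            if factor == 0:
                continue
            for c in range(col, n):
                A[r][c] -= factor * A[col][c]
    return det


def _frac_minor_det(scheme: KineticScheme, x: Fraction, k: int) -> Fraction:
    """Exact det of -W(x) with row and column k deleted; equals the
    unnormalized stationary weight of state k."""
    N = scheme.n_states
    idx = {s: i for i, s in enumerate(scheme.states)}
    A = [[Fraction(0)] * N for _ in range(N)]
    for e in scheme.edges:
        r = Fraction(e.base_rate) * (x if e.x_power else 1)
        A[idx[e.dst]][idx[e.src]] -= r
        A[idx[e.src]][idx[e.src]] += r
    M = [[A[i][j] for j in range(N) if j != k] for i in range(N) if i != k]
    return _frac_det(M)


def _longdouble_minor_dets(scheme: KineticScheme, nodes: np.ndarray, k: int) -> np.ndarray:
    """Extended-precision minors of -W(x) at every node, by partial-pivot
    Gaussian elimination in longdouble (numpy's LAPACK det is double-only)."""
    N = scheme.n_states
    idx = {s: i for i, s in enumerate(scheme.states)}
    out = np.empty(len(nodes), dtype=np.longdouble)
    for jn, xj in enumerate(nodes):
        A = np.zeros((N, N), dtype=np.longdouble)
        for e in scheme.edges:
            r = np.longdouble(e.base_rate) * (xj if e.x_power else np.longdouble(1.0))
            A[idx[e.dst], idx[e.src]] -= r
            A[idx[e.src], idx[e.src]] += r
        M = np.delete(np.delete(A, k, axis=0), k, axis=1)
        n = M.shape[0]
        det = np.longdouble(1.0)
        for c in range(n):
            p = c + int(np.argmax(np.abs(M[c:, c])))
            if M[p, c] == 0:
                det = np.longdouble(0.0)
                break
            if p != c:
                M[[c, p]] = M[[p, c]]
                det = -det
            det *= M[c, c]
            M[c + 1:, c:] -= np.outer(M[c + 1:, c] / M[c, c], M[c, c:])
        out[jn] = det
    return out


def _bjorck_pereyra(nodes: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Solve the Vandermonde system sum_j a_j nodes_i^j = ys_i by the
    Bjorck-Pereyra recurrences (accurate for ordered positive nodes)."""
    a = ys.copy()
    n = len(nodes)
    for k in range(n - 1):
        for i in range(n - 1, k, -1):
            a[i] = (a[i] - a[i - 1]) / (nodes[i] - nodes[i - k - 1])
    for k in range(n - 2, -1, -1):
        for i in range(k, n - 1):
            a[i] -= nodes[k] * a[i + 1]
    return a


# Interpolated coefficients below this fraction of the per-state maximum are
# structural zeros; with extended-precision minors the noise floor sits well
# below this threshold.
CLIP_REL = 1e-12


def _interpolate_polys(scheme: KineticScheme, exact: bool) -> SteadyStatePoly:
    m = support_size(scheme)
    shift = m // 2
    coeffs: list[np.ndarray] = []
    exact_coeffs: list[list[Fraction]] | None = [] if exact else None
    if exact:
        nodes = [Fraction(2) ** (j - shift) for j in range(m + 1)]
        for k in range(scheme.n_states):
            ys = [_frac_minor_det(scheme, xj, k) for xj in nodes]
            c = _lagrange_coeffs(nodes, ys)
            while len(c) < m + 1:
                c.append(Fraction(0))
            if any(ci < 0 for ci in c):
                raise ArithmeticError(
                    f"negative exact tree-polynomial coefficient for state "
                    f"{scheme.states[k]!r}; the scheme is likely invalid"
                )
            exact_coeffs.append(c)
            coeffs.append(np.array([float(ci) for ci in c]))
        return SteadyStatePoly(list(scheme.states), coeffs, m, exact_coeffs=exact_coeffs)

    nodes = np.array([2.0 ** (j - shift) for j in range(m + 1)], dtype=np.longdouble)
    for k in range(scheme.n_states):
        ys = _longdouble_minor_dets(scheme, nodes, k)
        c = _bjorck_pereyra(nodes, ys).astype(float)
        scale = np.abs(c).max()
        if scale > 0:
            if c.min() < -1e-6 * scale:
                raise ArithmeticError(
                    "strongly negative interpolated coefficient "
                    f"({c.min():.3g} vs scale {scale:.3g}) for state "
                    f"{scheme.states[k]!r}; consider exact=True"
                )
            c[np.abs(c) < CLIP_REL * scale] = 0.0  # structural zeros
            c[c < 0] = 0.0
        coeffs.append(c)
    return SteadyStatePoly(list(scheme.states), coeffs, m, exact_coeffs=None)


def _lagrange_coeffs(xs: list[Fraction], ys: list[Fraction]) -> list[Fraction]:
    """Exact interpolating-polynomial coefficients (ascending) via Newton's
    divided differences."""
    n = len(xs)
    dd = list(ys)
    for j in range(1, n):
        for i in range(n - 1, j - 1, -1):
            dd[i] = (dd[i] - dd[i - 1]) / (xs[i] - xs[i - j])
    # expand Newton form: p = dd[0] + dd[1](x-x0) + dd[2](x-x0)(x-x1) + ...
    coeffs = [Fraction(0)] * n
    basis = [Fraction(1)] + [Fraction(0)] * (n - 1)  # running product poly
    for j in range(n):
        for i in range(j + 1):
            coeffs[i] += dd[j] * basis[i]
        if j < n - 1:
            new = [Fraction(0)] * n
            for i in range(j + 1):
                new[i + 1] += basis[i]
                new[i] -= xs[j] * basis[i]
            basis = new
    while len(coeffs) > 1 and coeffs[-1] == 0:
        coeffs.pop()
    return coeffs


# ---------------------------------------------------------------------------
# Public entry point
# ---------------------------------------------------------------------------

def arborescence_polynomials(
    scheme: KineticScheme,
    backend: str = "auto",
    exact: bool = False,
    max_trees: int = DEFAULT_TREE_CAP,
) -> SteadyStatePoly:
    """Tree-theorem stationary weights of every state as polynomials in x.

    ``backend`` is one of ``"auto"`` (interpolation), ``"enumerate"`` (sum
    over explicit rooted in-trees; refuses schemes above ``max_trees``) or
    ``"interpolate"``.  ``exact=True`` runs the chosen backend in rational
    arithmetic (base rates taken as exact binary fractions).
    """
    require_strongly_connected(scheme)
    if backend == "enumerate":
        polys = _enumerate_polys(scheme, exact, max_trees)
    elif backend in ("auto", "interpolate"):
        polys = _interpolate_polys(scheme, exact)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    m = polys.support_size
    for k in range(scheme.n_states):
        if polys.degree(k) > m:
            raise ArithmeticError(
                f"state {scheme.states[k]!r} polynomial degree exceeds the "
                f"support size {m}"
            )
    return polys
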