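"""Seeded generators of random schemes, observables and receptors.

These are the synthetic fixture factory behind the property tests of the
support bound: strong connectivity is guaranteed by construction (a
Hamiltonian directed cycle backbone plus Bernoulli extra edges) rather
than by rejection sampling, so every draw is usable and fully reproducible
from its seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .model_zoo import SensingSetup, _bits_label, _hypercube_states
from .scheme import Edge, KineticScheme, Observable


@dataclass(frozen=True)
class RandomSpec:
    """Parameters of a random-scheme draw.

    ``rate_log10_range`` spans the log-uniform base-rate distribution;
    ``x_edge_prob`` is the chance each edge carries x.
    """

    N: int
    extra_edge_prob: float = 0.3
    rate_log10_range: tuple[float, float] = (-3.0, 3.0)
    x_edge_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not 0 <= self.extra_edge_prob <= 1:
            raise ValueError("extra_edge_prob must be in [0, 1]")
        if not 0 <= self.x_edge_prob <= 1:
            raise ValueError("x_edge_prob must be in [0, 1]")


def random_scheme(spec: RandomSpec) -> KineticScheme:
    """A strongly connected random scheme drawn from ``spec``."""
    rng = np.random.default_rng(spec.seed)
    N = spec.N
    states = [f"s{i}" for i in range(N)]
    order = rng.permutation(N)
    pairs = {(states[order[i]], states[order[(i + 1) % N]]) for i in range(N)}
    for src, dst in itertools.permutations(states, 2):
        if (src, dst) not in pairs and rng.random() < spec.extra_edge_prob:
            pairs.add((src, dst))
    lo, hi = spec.rate_log10_range
    edges = []
    for src, dst in sorted(pairs):
        rate = 10.0 ** rng.uniform(lo, hi)
        xp = 1 if rng.random() < spec.x_edge_prob else 0
        edges.append(Edge(src, dst, rate, x_power=xp))
    return KineticScheme(states, edges)


def random_observables(N: int, seed: int) -> tuple[Observable, Observable]:
    """A random pair of positive observables on N states; one draw in four
    is an indicator pair (X, Xbar) to exercise the partition corollary."""
    if N < 2:
        raise ValueError("N must be >= 2")
    rng = np.random.default_rng(seed)
    if rng.random() < 0.25:
        k = int(rng.integers(1, N))
        members = rng.choice(N, size=k, replace=False)
        a = np.zeros(N)
        a[members] = 1.0
        return Observable(tuple(a)), Observable(tuple(1.0 - a))
    weights = []
    for _ in range(2):
        w = np.exp(rng.normal(0.0, 1.5, size=N))
        w[rng.random(N) < 0.3] = 0.0  # sparse zeros are allowed
        if w.max() <= 0:
            w[int(rng.integers(N))] = 1.0
        weights.append(w)
    return Observable(tuple(weights[0])), Observable(tuple(weights[1]))


def random_db_binding(n: int, seed: int, energy_range: float = 3.0) -> KineticScheme:
    """A detailed-balanced hypercube binding scheme from random state
    energies E_i (uniform on +-energy_range, natural-log units).

    Each binding edge i -> j has rate exp((E_i - E_j)/2) * x and its reverse
    exp((E_j - E_i)/2), so the rate ratio is exp(E_i - E_j) x^(dn) and the
    stationary law is the Boltzmann distribution pi_i ~ exp(-E_i) x^(n_i).
    """
    if not 1 <= n <= 6:
        raise ValueError("n must be in 1..6")
    rng = np.random.default_rng(seed)
    states = _hypercube_states(n)
    E = {b: rng.uniform(-energy_range, energy_range) for b in states}
    edges = []
    for bits in states:
        for i in range(n):
            if bits[i] == 1:
                continue
            dst = bits[:i] + (1,) + bits[i + 1:]
            half = np.exp((E[bits] - E[dst]) / 2.0)
            edges.append(Edge(_bits_label(bits), _bits_label(dst), float(half), x_power=1))
            edges.append(Edge(_bits_label(dst), _bits_label(bits), float(1.0 / half)))
    labels = [_bits_label(b) for b in states]
    n_bound = {_bits_label(b): sum(b) for b in states}
    named = {"all_bound": ["1" * n], "empty": ["0" * n]}
    return KineticScheme(labels, edges, n_bound=n_bound, named_sets=named)


def random_receptor(seed: int, max_side: int = 3,
                    rate_log10_range: tuple[float, float] = (-2.0, 2.0)) -> SensingSetup:
    """A random nonequilibrium receptor in the fence form: nonsignaling
    (unbound) states X, signaling (bound) states Y, with every c-dependent
    binding edge crossing from X to Y and c-independent unbinding edges
    crossing back."""
    rng = np.random.default_rng(seed)
    nX = int(rng.integers(1, max_side + 1))
    nY = int(rng.integers(1, max_side + 1))
    lo, hi = rate_log10_range

    def rate() -> float:
        return float(10.0 ** rng.uniform(lo, hi))

    X_states = [f"X{i}" for i in range(nX)]
    Y_states = [f"Y{i}" for i in range(nY)]
    edges = []
    # backbone rings keep each side internally connected in both directions
    for side in (X_states, Y_states):
        for i in range(len(side)):
            j = (i + 1) % len(side)
            if i != j:
                edges.append(Edge(side[i], side[j], rate()))
                edges.append(Edge(side[j], side[i], rate()))
    binding = [(x, y) for x in X_states for y in Y_states if rng.random() < 0.5]
    if not binding:
        binding = [(X_states[0], Y_states[0])]
    unbinding = [(y, x) for y in Y_states for x in X_states if rng.random() < 0.5]
    if not unbinding:
        unbinding = [(Y_states[0], X_states[0])]
    seen = {(e.src, e.dst) for e in edges}
    for (src, dst) in binding:
        if (src, dst) not in seen:
            edges.append(Edge(src, dst, rate(), x_power=1))
            seen.add((src, dst))
    for (src, dst) in unbinding:
        if (src, dst) not in seen:
            edges.append(Edge(src, dst, rate()))
            seen.add((src, dst))
    scheme = KineticScheme(
        X_states + Y_states, edges,
        named_sets={"X": X_states, "Y": Y_states},
    )
    R_T = int(rng.integers(100, 10001))
    c = float(10.0 ** rng.uniform(-1.0, 1.0))
    return SensingSetup(scheme=scheme, Y=frozenset(Y_states), R_T=R_T, c=c)
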