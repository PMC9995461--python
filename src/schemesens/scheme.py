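"""Kinetic-scheme data model, perturbation support, detailed balance, and JSON I/O.

A kinetic scheme is a finite continuous-time Markov chain: a set of states
connected by directed edges, each carrying a strictly positive transition
rate.  A single scalar control parameter ``x`` (typically a ligand
concentration) multiplicatively scales the rates of a subset of the edges;
the *support* of this perturbation is the set of states with at least one
outgoing x-dependent edge.  The size of the support bounds every logarithmic
steady-state sensitivity of the scheme.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

SCHEME_FORMAT = "schemesens-scheme-v1"


@dataclass(frozen=True)
class Edge:
    """A directed transition with effective rate ``base_rate * x**x_power``.

    ``x_power`` is restricted to {0, 1}: the control parameter only scales
    rates linearly (mass-action binding).  Higher powers are rejected.
    """

    src: str
    dst: str
    base_rate: float
    x_power: int = 0

    def __post_init__(self) -> None:
        if self.src == self.dst:
            raise ValueError(f"self-edge on state {self.src!r} is not allowed")
        if self.x_power not in (0, 1):
            raise ValueError(
                f"x_power must be 0 or 1, got {self.x_power!r}: only linear "
                "multiplicative scaling of rates by x is supported"
            )

    def rate_at(self, x: float) -> float:
        return self.base_rate * (x if self.x_power == 1 else 1.0)


@dataclass
class KineticScheme:
    """A finite kinetic scheme (continuous-time Markov chain).

    Parameters
    ----------
    states
        Ordered unique state labels; the order fixes the index convention
        used by every array-returning operation.
    edges
        Directed transitions.  "No transition" is encoded by edge absence,
        never by a zero rate.
    n_bound
        Optional number of ligands bound in each state.  When present, every
        edge must change it by -1, 0 or +1.
    named_sets
        Optional named state subsets (e.g. ``{"CW": [...], "bound": [...]}``)
        used by partition-based sensitivity queries and the CLI.
    """

    states: list[str]
    edges: list[Edge]
    n_bound: dict[str, int] | None = None
    named_sets: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError("a scheme needs at least two states")
        if len(set(self.states)) != len(self.states):
            raise ValueError("state labels must be unique")
        known = set(self.states)
        for e in self.edges:
            if e.src not in known or e.dst not in known:
                raise ValueError(f"edge {e.src!r}->{e.dst!r} references unknown state")
        if self.n_bound is not None:
            missing = known - set(self.n_bound)
            if missing:
                raise ValueError(f"n_bound missing for states {sorted(missing)}")
        if self.named_sets is not None:
            for name, members in self.named_sets.items():
                bad = set(members) - known
                if bad:
                    raise ValueError(f"named set {name!r} references unknown states {sorted(bad)}")

    # -- indexing helpers -------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, label: str) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise KeyError(f"unknown state {label!r}") from None

    def out_edges(self, label: str) -> list[Edge]:
        return [e for e in self.edges if e.src == label]

    def edge_rates(self) -> dict[tuple[str, str], Edge]:
        return {(e.src, e.dst): e for e in self.edges}

    # -- matrices and graphs ----------------------------------------------
    def rate_matrix(self, x: float) -> np.ndarray:
        """Generator matrix W with ``W[i, j]`` the rate of j -> i and
        columns summing to zero (master equation dp/dt = W p)."""
        if x <= 0:
            raise ValueError(f"x must be positive, got {x}")
        for e in self.edges:
            if e.base_rate <= 0:
                raise ValueError(f"edge {e.src!r}->{e.dst!r} has nonpositive rate")
        N = self.n_states
        idx = {s: i for i, s in enumerate(self.states)}
        W = np.zeros((N, N))
        for e in self.edges:
            W[idx[e.dst], idx[e.src]] += e.rate_at(x)
        W[np.diag_indices(N)] -= W.sum(axis=0)
        return W

    def to_digraph(self) -> nx.DiGraph:
        G = nx.DiGraph()
        G.add_nodes_from(self.states)
        G.add_edges_from((e.src, e.dst, {"edge": e}) for e in self.edges)
        return G

    def is_strongly_connected(self) -> bool:
        return nx.is_strongly_connected(self.to_digraph())

    def set_states(self, name: str) -> list[str]:
        if not self.named_sets or name not in self.named_sets:
            raise KeyError(f"scheme has no named set {name!r}")
        return list(self.named_sets[name])


def require_strongly_connected(scheme: KineticScheme) -> None:
    if not scheme.is_strongly_connected():
        raise ValueError(
            "scheme is not strongly connected: the steady state is not unique"
        )


# ---------------------------------------------------------------------------
# Observables and partitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Observable:
    """Nonnegative per-state weights with at least one strictly positive."""

    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if min(self.weights) < 0:
            raise ValueError("observable weights must be nonnegative")
        if max(self.weights) <= 0:
            raise ValueError("observable needs at least one positive weight")

    @classmethod
    def indicator(cls, scheme: KineticScheme, members) -> "Observable":
        members = set(members)
        return cls(tuple(1.0 if s in members else 0.0 for s in scheme.states))

    @classmethod
    def from_mapping(cls, scheme: KineticScheme, mapping, default: float = 0.0) -> "Observable":
        return cls(tuple(float(mapping.get(s, default)) for s in scheme.states))

    def array(self) -> np.ndarray:
        return np.asarray(self.weights)


@dataclass(frozen=True)
class StatePartition:
    """A nonempty proper subset X of states; its complement is implicit."""

    X: frozenset

    def __init__(self, X) -> None:
        object.__setattr__(self, "X", frozenset(X))
        if not self.X:
            raise ValueError("partition set X must be nonempty")

    def indicator_pair(self, scheme: KineticScheme) -> tuple[Observable, Observable]:
        known = set(scheme.states)
        bad = self.X - known
        if bad:
            raise ValueError(f"partition references unknown states {sorted(bad)}")
        if self.X == known:
            raise ValueError("partition set X must be a proper subset of the states")
        comp = known - self.X
        return Observable.indicator(scheme, self.X), Observable.indicator(scheme, comp)


# ---------------------------------------------------------------------------
# Support of the perturbation
# ---------------------------------------------------------------------------

def support(scheme: KineticScheme) -> list[str]:
    """States with at least one outgoing x-dependent edge, in state order."""
    hot = {e.src for e in scheme.edges if e.x_power == 1}
    return [s for s in scheme.states if s in hot]


def support_size(scheme: KineticScheme) -> int:
    return len(support(scheme))


# ---------------------------------------------------------------------------
# Validation (report-only: callers decide what is fatal)
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    n_states: int
    n_edges: int
    strongly_connected: bool
    duplicate_edges: list = field(default_factory=list)
    nonpositive_rates: list = field(default_factory=list)
    n_bound_errors: list = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return (
            self.strongly_connected
            and not self.duplicate_edges
            and not self.nonpositive_rates
            and not self.n_bound_errors
        )


def validate_scheme(scheme: KineticScheme) -> ValidationReport:
    seen: set[tuple[str, str]] = set()
    dupes, nonpos = [], []
    for e in scheme.edges:
        key = (e.src, e.dst)
        if key in seen:
            dupes.append(key)
        seen.add(key)
        if e.base_rate <= 0:
            nonpos.append(key)
    nb_errors = []
    if scheme.n_bound is not None:
        for e in scheme.edges:
            step = scheme.n_bound[e.dst] - scheme.n_bound[e.src]
            if step not in (-1, 0, 1):
                nb_errors.append((e.src, e.dst, step))
        for s, nb in scheme.n_bound.items():
            if nb < 0:
                nb_errors.append((s, "negative n_bound", nb))
    return ValidationReport(
        n_states=scheme.n_states,
        n_edges=len(scheme.edges),
        strongly_connected=scheme.is_strongly_connected(),
        duplicate_edges=dupes,
        nonpositive_rates=nonpos,
        n_bound_errors=nb_errors,
    )


# ---------------------------------------------------------------------------
# Detailed balance (Kolmogorov cycle criterion)
# ---------------------------------------------------------------------------

def is_detailed_balanced(
    scheme: KineticScheme,
    x: float = 1.0,
    rtol: float = 1e-9,
    strict: bool = False,
) -> tuple[bool, float]:
    """Check the Kolmogorov cycle criterion at parameter value ``x``.

    Every basis cycle of the undirected support graph must have unit
    forward/backward rate-product ratio.  Returns ``(balanced, worst_ratio)``
    where ``worst_ratio`` is the basis-cycle ratio farthest from 1.  A scheme
    with any unpaired edge is not reversible: returns ``(False, inf)``, or
    raises if ``strict``.
    """
    rates = {(e.src, e.dst): e.rate_at(x) for e in scheme.edges}
    for (s, d) in rates:
        if (d, s) not in rates:
            if strict:
                raise ValueError(f"edge {s!r}->{d!r} has no reverse partner")
            return False, math.inf
    G = nx.Graph()
    G.add_nodes_from(scheme.states)
    G.add_edges_from(rates)
    worst = 1.0
    for cycle in nx.cycle_basis(G):
        log_ratio = 0.0
        k = len(cycle)
        for i in range(k):
            u, v = cycle[i], cycle[(i + 1) % k]
            log_ratio += math.log(rates[(u, v)]) - math.log(rates[(v, u)])
        ratio = math.exp(log_ratio)
        if abs(math.log(ratio)) > abs(math.log(worst)):
            worst = ratio
    return abs(worst - 1.0) <= rtol, worst


# ---------------------------------------------------------------------------
# JSON I/O
# ---------------------------------------------------------------------------

def scheme_to_dict(scheme: KineticScheme) -> dict:
    out = {
        "format": SCHEME_FORMAT,
        "states": list(scheme.states),
        "edges": [
            # rates as decimal strings: repr() round-trips doubles exactly
            {"src": e.src, "dst": e.dst, "rate": repr(float(e.base_rate)),
             "x_power": e.x_power}
            for e in scheme.edges
        ],
    }
    if scheme.n_bound is not None:
        out["n_bound"] = dict(scheme.n_bound)
    if scheme.named_sets is not None:
        out["sets"] = {k: list(v) for k, v in scheme.named_sets.items()}
    return out


def scheme_from_dict(data: dict) -> KineticScheme:
    fmt = data.get("format")
    if fmt != SCHEME_FORMAT:
        raise ValueError(f"unknown scheme format {fmt!r}; expected {SCHEME_FORMAT!r}")
    edges = [
        Edge(d["src"], d["dst"], float(d["rate"]), int(d.get("x_power", 0)))
        for d in data["edges"]
    ]
    n_bound = data.get("n_bound")
    if n_bound is not None:
        n_bound = {k: int(v) for k, v in n_bound.items()}
    sets = data.get("sets")
    if sets is not None:
        sets = {k: list(v) for k, v in sets.items()}
    return KineticScheme(list(data["states"]), edges, n_bound=n_bound, named_sets=sets)


def write_scheme(scheme: KineticScheme, path) -> None:
    Path(path).write_text(json.dumps(scheme_to_dict(scheme), indent=1) + "\n")


def read_scheme(path) -> KineticScheme:
    return scheme_from_dict(json.loads(Path(path).read_text()))
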