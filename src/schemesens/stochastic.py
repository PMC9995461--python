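"""Exact stochastic simulation (Gillespie) and master-equation propagation.

Used for trajectory-level illustration (e.g. watching the timescale
hierarchy of nested hysteresis) and as an ergodic cross-check of the exact
steady-state solvers: time-average occupancies of a long trajectory must
match the stationary distribution within Monte-Carlo error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import expm

from .scheme import KineticScheme, require_strongly_connected


@dataclass
class Trajectory:
    """A piecewise-constant jump path: state ``states[i]`` is occupied from
    ``times[i]`` until ``times[i+1]`` (or until ``t_max`` for the last)."""

    times: np.ndarray        # strictly increasing jump times, times[0] == 0
    states: np.ndarray       # visited state indices, len == len(times)
    t_max: float
    seed: int
    state_labels: list[str]

    def to_tsv(self, path) -> None:
        """Write columns time, state_label (+ one 0/1 column per site when
        the state labels are equal-length bit strings)."""
        sites = _site_count(self.state_labels)
        with open(Path(path), "w") as fh:
            cols = ["time", "state"]
            if sites:
                cols += [f"site{i + 1}" for i in range(sites)]
            fh.write("\t".join(cols) + "\n")
            for t, k in zip(self.times, self.states):
                label = self.state_labels[k]
                row = [repr(float(t)), label]
                if sites:
                    row += list(label)
                fh.write("\t".join(row) + "\n")


def _site_count(labels: list[str]) -> int:
    n = len(labels[0])
    if all(len(s) == n and set(s) <= {"0", "1"} for s in labels):
        return n
    return 0


def gillespie(
    scheme: KineticScheme,
    x: float,
    t_max: float,
    seed: int,
    start: str | None = None,
    max_steps: int = 50_000_000,
) -> Trajectory:
    """Statistically exact continuous-time simulation up to ``t_max``.

    One named generator per trajectory (PCG64 seeded with ``seed``);
    exponential waiting times by inverse transform, next state by
    cumulative-rate search, so trajectories are bit-reproducible.
    """
    require_strongly_connected(scheme)
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    N = scheme.n_states
    idx = {s: i for i, s in enumerate(scheme.states)}
    targets: list[np.ndarray] = [np.empty(0, dtype=np.int64) for _ in range(N)]
    cumrates: list[np.ndarray] = [np.empty(0) for _ in range(N)]
    for i, s in enumerate(scheme.states):
        outs = scheme.out_edges(s)
        targets[i] = np.array([idx[e.dst] for e in outs], dtype=np.int64)
        cumrates[i] = np.cumsum([e.rate_at(x) for e in outs])
    rng = np.random.default_rng(seed)
    state = idx[start] if start is not None else 0
    t = 0.0
    times = [0.0]
    visited = [state]
    for _ in range(max_steps):
        total = cumrates[state][-1]
        # inverse-transform exponential waiting time
        t += -math.log(rng.random()) / total
        if t >= t_max:
            break
        nxt = int(targets[state][np.searchsorted(cumrates[state], rng.random() * total)])
        times.append(t)
        visited.append(nxt)
        state = nxt
    else:
        raise RuntimeError(f"gillespie exceeded max_steps={max_steps} before t_max")
    return Trajectory(
        times=np.array(times),
        states=np.array(visited, dtype=np.int64),
        t_max=float(t_max),
        seed=seed,
        state_labels=list(scheme.states),
    )


def occupancy_stats(traj: Trajectory, scheme: KineticScheme) -> dict:
    """Time-weighted occupancy fractions, plus per-site bound fractions when
    the state labels are bit strings."""
    if list(scheme.states) != traj.state_labels:
        raise ValueError("trajectory does not belong to this scheme")
    N = scheme.n_states
    dwell = np.zeros(N)
    bounds = np.append(traj.times, traj.t_max)
    np.add.at(dwell, traj.states, np.diff(bounds))
    fractions = dwell / traj.t_max
    out = {"state_fractions": {s: float(f) for s, f in zip(scheme.states, fractions)}}
    sites = _site_count(traj.state_labels)
    if sites:
        occ = np.array([[int(ch) for ch in s] for s in traj.state_labels], dtype=float)
        out["site_fractions"] = {
            f"site{i + 1}": float(np.dot(fractions, occ[:, i])) for i in range(sites)
        }
    return out


def propagate_master(
    scheme: KineticScheme, p0: np.ndarray, x: float, t: float
) -> np.ndarray:
    """Solve dp/dt = W p from ``p0`` for a time ``t`` via the matrix
    exponential (exact for any stiffness; probability conserved)."""
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (scheme.n_states,):
        raise ValueError("p0 has the wrong length")
    if abs(p0.sum() - 1.0) > 1e-10 or p0.min() < -1e-12:
        raise ValueError("p0 must be a probability distribution")
    if t < 0:
        raise ValueError("t must be nonnegative")
    if t == 0:
        return p0.copy()
    W = scheme.rate_matrix(x)
    # keep the exponent norm moderate and reach large t by repeated squaring
    # of the short-time propagator: accurate for any stiffness
    scale = float(np.abs(W).max()) * t
    doublings = max(0, math.ceil(math.log2(scale / 32.0))) if scale > 32.0 else 0
    P = expm(W * (t / 2**doublings))
    for _ in range(doublings):
        P = P @ P
        P /= P.sum(axis=0)  # re-project onto stochastic matrices
    p = P @ p0
    if abs(p.sum() - 1.0) > 1e-10:
        raise ArithmeticError("probability not conserved by the propagator")
    return p
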