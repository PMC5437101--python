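"""Exact expected SFS for small samples by Markov-chain first principles.

For piecewise-constant timelines and total sample sizes up to six, the
ancestral process is a finite continuous-time Markov chain on *lineage
configurations*: multisets of lineages, each tagged with its deme and
with the number of sampled leaves from each population it subtends.
Expected branch lengths per frequency class are exact time integrals of
state occupancies, computed epoch by epoch with matrix exponentials
(augmented to yield the occupancy integral in the same call) and, for
the infinite ancestral epoch, with the fundamental matrix of the
absorbing chain.  This is deterministic and serves as the independent
oracle for the Monte Carlo engine.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
from scipy.linalg import expm

from .demography import DemographyTimeline
from .sfs import JointSFS

__all__ = ["exact_small_sfs", "exact_branch_lengths"]

_MAX_TOTAL = 6

# A lineage is (deme, i, j); a state is a sorted tuple of lineages.


def _canonical(lineages) -> tuple:
    return tuple(sorted(lineages))


def _transitions(state: tuple, n_demes: int, nus, mig):
    """Yield (rate, new_state) for coalescences and backward migrations."""
    lineages = list(state)
    counts = Counter(lineages)
    distinct = list(counts)
    # coalescence: pairs of lineages in the same deme
    for a in range(len(distinct)):
        for b in range(a, len(distinct)):
            la, lb = distinct[a], distinct[b]
            if la[0] != lb[0]:
                continue
            if a == b:
                npairs = counts[la] * (counts[la] - 1) // 2
            else:
                npairs = counts[la] * counts[lb]
            if npairs == 0:
                continue
            rate = npairs / nus[la[0]]
            merged = (la[0], la[1] + lb[1], la[2] + lb[2])
            new = list(lineages)
            new.remove(la)
            new.remove(lb)
            new.append(merged)
            yield rate, _canonical(new)
    # backward migration: lineage in deme d moves to deme dp at rate M[d][dp]/2
    if n_demes > 1:
        for lin, cnt in counts.items():
            d = lin[0]
            for dp in range(n_demes):
                if dp == d or mig[d][dp] == 0.0:
                    continue
                rate = cnt * mig[d][dp] / 2.0
                new = list(lineages)
                new.remove(lin)
                new.append((dp, lin[1], lin[2]))
                yield rate, _canonical(new)


def _reach(seed_states, n_demes, nus, mig):
    """BFS closure of the state space under one epoch's transitions."""
    states = list(seed_states)
    index = {s: k for k, s in enumerate(states)}
    frontier = list(states)
    while frontier:
        s = frontier.pop()
        for _, t in _transitions(s, n_demes, nus, mig):
            if t not in index:
                index[t] = len(states)
                states.append(t)
                frontier.append(t)
    return states, index


def _rate_matrix(states, index, n_demes, nus, mig):
    Q = np.zeros((len(states), len(states)))
    for k, s in enumerate(states):
        for rate, t in _transitions(s, n_demes, nus, mig):
            Q[k, index[t]] += rate
            Q[k, k] -= rate
    return Q


def _class_counts(states, n1, n2):
    """Matrix C[state, class] = number of lineages of class (i, j) in the state."""
    ncls = (n1 + 1) * (n2 + 1)
    C = np.zeros((len(states), ncls))
    for k, s in enumerate(states):
        for (_, i, j) in s:
            C[k, i * (n2 + 1) + j] += 1.0
    return C


def exact_branch_lengths(timeline: DemographyTimeline, n1: int, n2: int) -> np.ndarray:
    """Exact E[T(i, j)] (scaled units) as an (n1+1, n2+1) array (n2=0 -> 1-D)."""
    if n1 + n2 > _MAX_TOTAL:
        raise ValueError(f"exact oracle limited to n1 + n2 <= {_MAX_TOTAL}")
    for ep in timeline.epochs:
        if any(sf.kind != "constant" for sf in ep.sizes):
            raise ValueError("exact oracle requires piecewise-constant epochs")
    if timeline.n_demes == 1 and n2 != 0:
        raise ValueError("single-deme timeline: pass n2 = 0")
    if timeline.n_demes == 2 and (n1 < 1 or n2 < 1):
        raise ValueError("two-deme timeline needs samples in both demes")

    epochs = list(timeline.epochs)[::-1]  # backward order, present first
    init = [(0, 1, 0)] * n1 + [(1, 0, 1)] * n2
    dist: dict[tuple, float] = {_canonical(init): 1.0}
    ncls = (n1 + 1) * (n2 + 1)
    T = np.zeros(ncls)

    for e, ep in enumerate(epochs):
        n_demes = ep.n_demes
        if n_demes == 1:
            # collapse demes when crossing the split going backwards
            merged: dict[tuple, float] = {}
            for s, p in dist.items():
                s1 = _canonical([(0, i, j) for (_, i, j) in s])
                merged[s1] = merged.get(s1, 0.0) + p
            dist = merged
        nus = [sf.start for sf in ep.sizes]
        mig = ep.migration
        live = [s for s, p in dist.items() if p > 0.0]
        states, index = _reach(live, n_demes, nus, mig)
        p0 = np.zeros(len(states))
        for s, p in dist.items():
            p0[index[s]] = p
        Q = _rate_matrix(states, index, n_demes, nus, mig)
        C = _class_counts(states, n1, n2)
        if math.isinf(ep.duration):
            transient = [k for k, s in enumerate(states) if len(s) > 1]
            if transient:
                Qtt = Q[np.ix_(transient, transient)]
                occ = np.linalg.solve(Qtt.T, -p0[transient])
                T += occ @ C[transient]
            break
        nstat = len(states)
        A = np.zeros((2 * nstat, 2 * nstat))
        A[:nstat, :nstat] = Q
        A[:nstat, nstat:] = np.eye(nstat)
        E = expm(A * ep.duration)
        P = E[:nstat, :nstat]
        I_int = E[:nstat, nstat:]
        occ = p0 @ I_int
        T += occ @ C
        pT = p0 @ P
        dist = {states[k]: pT[k] for k in range(nstat) if pT[k] > 1e-300}

    shape = (n1 + 1, n2 + 1) if n2 > 0 else (n1 + 1,)
    return T.reshape(shape)


def exact_small_sfs(timeline: DemographyTimeline, n1: int, n2: int,
                    theta: float = 1.0) -> JointSFS:
    """Exact expected SFS, E[S(i, j)] = (theta / 2) * E[T(i, j)]."""
    T = exact_branch_lengths(timeline, n1, n2)
    return JointSFS(theta / 2.0 * T)
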