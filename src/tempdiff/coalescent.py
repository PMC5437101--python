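"""Monte Carlo structured-coalescent engine for expected joint SFS.

The expected spectrum under a demographic timeline is obtained from
expected genealogical branch lengths: if ``T(i, j)`` is the total branch
length (in units of ``2*Na`` generations) subtending exactly ``i``
population-1 and ``j`` population-2 sampled leaves, then the expected
number of sites with configuration ``(i, j)`` is
``E[S(i, j)] = (theta / 2) * E[T(i, j)]``.

``E[T]`` is estimated by simulating the ancestral process backwards in
time: within each epoch, pairs of lineages in deme ``k`` coalesce at
rate ``1 / nu_k(t)`` per pair and a lineage in deme ``i`` migrates
(backwards) into deme ``j`` at rate ``M_ij / 2``.  Time-varying deme
sizes (linear or exponential trajectories) are handled by thinning
against a per-epoch rate bound computed from the epoch's extreme sizes,
so no time discretization error is introduced.  Replicates use
independent seeded substreams; with a fixed seed the estimate is a
deterministic, parameter-continuous function, which is what the
optimizer relies on (common random numbers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .demography import DemographyTimeline
from .sfs import JointSFS

__all__ = ["CoalescentConfig", "expected_joint_sfs", "expected_sfs"]

# A large but finite stand-in for the infinite ancestral epoch; with at
# least two lineages the residual coalescence probability beyond this
# horizon is < exp(-1e6).
_T_HUGE = 1e6

_KIND_CODE = {"constant": 0, "linear": 1, "exponential": 2}


@dataclass(frozen=True)
class CoalescentConfig:
    """Monte Carlo settings: replicate count, seed and thinning head-room.

    ``thinning_rate_bound`` multiplies the per-epoch coalescence-rate
    bound derived from the epoch's extreme deme sizes; it exists as a
    guard and the engine raises if an instantaneous rate ever exceeds
    the bound in use.
    """

    replicates: int = 100_000
    seed: int = 0
    thinning_rate_bound: float = 1.0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.thinning_rate_bound < 1.0:
            raise ValueError("thinning_rate_bound must be >= 1")


def _timeline_arrays(timeline: DemographyTimeline):
    """Encode a timeline as flat arrays in backward-time order (present first)."""
    eps = list(timeline.epochs)[::-1]
    ne = len(eps)
    durs = np.empty(ne)
    ndem = np.empty(ne, dtype=np.int64)
    kinds = np.zeros((ne, 2), dtype=np.int64)
    s_old = np.ones((ne, 2))
    s_new = np.ones((ne, 2))
    mig = np.zeros((ne, 2, 2))
    for e, ep in enumerate(eps):
        durs[e] = _T_HUGE if math.isinf(ep.duration) else ep.duration
        ndem[e] = ep.n_demes
        for k, sf in enumerate(ep.sizes):
            kinds[e, k] = _KIND_CODE[sf.kind]
            s_old[e, k] = sf.start
            s_new[e, k] = sf.end
        for a in range(ep.n_demes):
            for b in range(ep.n_demes):
                mig[e, a, b] = ep.migration[a][b]
    return durs, ndem, kinds, s_old, s_new, mig


@njit(cache=True)
def _size_at(kind, s_old, s_new, dur, s):
    # s is backward local time within the epoch: 0 at the recent edge.
    if kind == 0 or dur <= 0.0:
        return s_new
    f = s / dur
    if kind == 1:
        return s_new + (s_old - s_new) * f
    return s_new * (s_old / s_new) ** f


@njit(cache=True)
def _run_replicates(n1, n2, durs, ndem, kinds, s_old, s_new, mig, seeds,
                    bound_factor, t_sum, t_sumsq):
    ne = durs.shape[0]
    nlin0 = n1 + n2
    ncls = (n1 + 1) * (n2 + 1)
    w2 = n2 + 1
    deme = np.empty(nlin0, dtype=np.int64)
    cls = np.empty(nlin0, dtype=np.int64)
    tacc = np.empty(ncls)
    for r in range(seeds.shape[0]):
        np.random.seed(seeds[r])
        for c in range(ncls):
            tacc[c] = 0.0
        for i in range(n1):
            deme[i] = 0
            cls[i] = w2  # one pop-1 leaf: (1, 0)
        for j in range(n2):
            deme[n1 + j] = 1
            cls[n1 + j] = 1  # one pop-2 leaf: (0, 1)
        nact = nlin0
        e = 0
        tloc = 0.0
        while nact > 1:
            nd = ndem[e]
            if nd == 1:
                for x in range(nact):
                    deme[x] = 0
            c0 = 0
            for x in range(nact):
                if deme[x] == 0:
                    c0 += 1
            c1 = nact - c0
            # per-epoch coalescence-rate bound from extreme sizes
            numin0 = min(s_old[e, 0], s_new[e, 0])
            b_coal0 = bound_factor * c0 * (c0 - 1) * 0.5 / numin0
            b_coal1 = 0.0
            rate_m0 = 0.0
            rate_m1 = 0.0
            if nd > 1:
                numin1 = min(s_old[e, 1], s_new[e, 1])
                b_coal1 = bound_factor * c1 * (c1 - 1) * 0.5 / numin1
                rate_m0 = c0 * mig[e, 0, 1] * 0.5
                rate_m1 = c1 * mig[e, 1, 0] * 0.5
            lam = b_coal0 + b_coal1 + rate_m0 + rate_m1
            if lam <= 0.0:
                if e == ne - 1:
                    return -2  # no event possible in the terminal epoch
                # nothing can happen in this epoch; jump to its old edge
                dt = durs[e] - tloc
                for x in range(nact):
                    tacc[cls[x]] += dt
                e += 1
                tloc = 0.0
                continue
            dt = np.random.exponential(1.0 / lam)
            if tloc + dt > durs[e] and e < ne - 1:
                dt = durs[e] - tloc
                for x in range(nact):
                    tacc[cls[x]] += dt
                e += 1
                tloc = 0.0
                continue
            for x in range(nact):
                tacc[cls[x]] += dt
            tloc += dt
            u = np.random.random() * lam
            if u < b_coal0 + b_coal1:
                k = 0 if u < b_coal0 else 1
                rate_true = (1.0 /
                             _size_at(kinds[e, k], s_old[e, k], s_new[e, k],
                                      durs[e], tloc))
                numin = min(s_old[e, k], s_new[e, k])
                if rate_true * numin > bound_factor + 1e-12:
                    # instantaneous rate above the thinning bound
                    return -1
                if np.random.random() < rate_true * numin / bound_factor:
                    # coalesce a uniform pair within deme k
                    ck = c0 if k == 0 else c1
                    a = np.random.randint(ck)
                    b = np.random.randint(ck - 1)
                    if b >= a:
                        b += 1
                    ia = -1
                    ib = -1
                    seen = 0
                    for x in range(nact):
                        if deme[x] == k:
                            if seen == a:
                                ia = x
                            if seen == b:
                                ib = x
                            seen += 1
                    cls[ia] = cls[ia] + cls[ib]
                    deme[nact - 1], deme[ib] = deme[ib], deme[nact - 1]
                    cls[nact - 1], cls[ib] = cls[ib], cls[nact - 1]
                    nact -= 1
            else:
                # migration event (exact rate, never thinned)
                if u < b_coal0 + b_coal1 + rate_m0:
                    src, dst, ck = 0, 1, c0
                else:
                    src, dst, ck = 1, 0, c1
                a = np.random.randint(ck)
                seen = 0
                for x in range(nact):
                    if deme[x] == src:
                        if seen == a:
                            deme[x] = dst
                            break
                        seen += 1
        for c in range(ncls):
            t_sum[c] += tacc[c]
            t_sumsq[c] += tacc[c] * tacc[c]
    return 0


def expected_joint_sfs(timeline: DemographyTimeline, n1: int, n2: int,
                       theta: float, cfg: CoalescentConfig | None = None) -> JointSFS:
    """Monte Carlo expected joint SFS for samples of ``n1`` and ``n2`` haplotypes.

    For a single-deme timeline pass ``n2 = 0`` (or use
    :func:`expected_sfs`).  The returned spectrum carries per-cell
    standard errors in ``.se``.
    """
    cfg = cfg or CoalescentConfig()
    if timeline.n_demes == 2:
        if n1 < 2 or n2 < 2:
            raise ValueError("two-deme timelines need n1 >= 2 and n2 >= 2")
    else:
        if n2 != 0:
            raise ValueError("single-deme timeline: pass n2 = 0")
        if n1 < 2:
            raise ValueError("need at least two sampled haplotypes")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    durs, ndem, kinds, s_old, s_new, mig = _timeline_arrays(timeline)
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(1, 2**31 - 1, size=cfg.replicates).astype(np.int64)
    ncls = (n1 + 1) * (n2 + 1)
    t_sum = np.zeros(ncls)
    t_sumsq = np.zeros(ncls)
    status = _run_replicates(n1, n2, durs, ndem, kinds, s_old, s_new, mig,
                             seeds, cfg.thinning_rate_bound, t_sum, t_sumsq)
    if status == -1:
        raise RuntimeError(
            "instantaneous coalescence rate exceeded the thinning bound; "
            "increase thinning_rate_bound"
        )
    if status == -2:
        raise RuntimeError(
            "terminal epoch admits no events with more than one lineage left "
            "(isolated demes with zero migration?)"
        )
    reps = cfg.replicates
    mean_t = t_sum / reps
    var_t = np.maximum(t_sumsq / reps - mean_t**2, 0.0)
    scale = theta / 2.0
    shape = (n1 + 1, n2 + 1) if n2 > 0 else (n1 + 1,)
    data = (scale * mean_t).reshape(shape)
    se = (scale * np.sqrt(var_t / reps)).reshape(shape)
    out = JointSFS(data)
    out.se = se
    return out


def expected_sfs(timeline: DemographyTimeline, n: int, theta: float,
                 cfg: CoalescentConfig | None = None) -> JointSFS:
    """Single-population convenience wrapper around :func:`expected_joint_sfs`."""
    return expected_joint_sfs(timeline, n, 0, theta, cfg)
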