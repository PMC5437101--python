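"""Poisson composite likelihood, model fitting, model selection, bootstrap.

Treating the cells of a joint SFS as independent Poisson counts gives
the composite log-likelihood ``sum S*ln(M) - M - ln(S!)`` over unmasked
cells, where ``S`` is the observed and ``M`` the expected spectrum.  The
overall mutation supply ``theta`` scales ``M`` linearly and is profiled
out analytically (``theta_hat = sum(S)/sum(M_1)`` against the shape at
``theta = 1``), so the optimizer only searches the demographic
parameters.  Optimization is Nelder-Mead on log-transformed parameters
from multiple starts spaced an order of magnitude apart; nested models
are compared with chi-square likelihood-ratio tests and non-nested ones
with AIC; uncertainty comes from a parametric (Poisson) bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import chi2

from .coalescent import CoalescentConfig, expected_joint_sfs
from .demography import (MODEL_PARAMS, SINGLE_POP_MODELS, ScaledParams,
                         build_timeline)
from .exact_sfs import exact_small_sfs
from .sfs import JointSFS

__all__ = [
    "FitResult",
    "poisson_loglik",
    "optimal_theta",
    "model_spectrum",
    "fit_model",
    "lrt",
    "aic",
    "bootstrap_ci",
    "anscombe_residuals",
]


def _check_compat(model: JointSFS, data: JointSFS) -> None:
    if model.data.shape != data.data.shape:
        raise ValueError("model and data spectra must have identical shapes")
    if not np.array_equal(model.mask, data.mask):
        raise ValueError("model and data spectra must have identical masks")


def poisson_loglik(model: JointSFS, data: JointSFS) -> float:
    """Poisson composite log-likelihood of ``data`` under expectation ``model``.

    Cells where the model expects nothing but data were observed make
    the likelihood -inf, which is the honest verdict rather than an
    exception.
    """
    _check_compat(model, data)
    um = ~data.mask
    M = model.data[um]
    S = data.data[um]
    if np.any(M < 0) or np.any(S < 0):
        raise ValueError("negative entries in spectrum")
    out = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = S * np.log(M) - M - gammaln(S + 1)
    bad = (M == 0) & (S > 0)
    if np.any(bad):
        return -math.inf
    terms = np.where((M == 0) & (S == 0), 0.0, terms)
    out = float(terms.sum())
    return out


def optimal_theta(model_shape: JointSFS, data: JointSFS) -> float:
    """Analytic profile MLE of theta: sum(S) / sum(M) over unmasked cells.

    ``model_shape`` must be computed at theta = 1.
    """
    _check_compat(model_shape, data)
    um = ~data.mask
    denom = float(model_shape.data[um].sum())
    if denom <= 0:
        raise ValueError("model shape has zero unmasked mass")
    return float(data.data[um].sum()) / denom


def model_spectrum(params: ScaledParams, n1: int, n2: int,
                   cfg: CoalescentConfig | None = None,
                   engine: str = "mc", theta: float = 1.0) -> JointSFS:
    """Expected spectrum for a parameter set, by either engine.

    ``engine="mc"`` uses the Monte Carlo structured coalescent;
    ``engine="exact"`` the small-sample Markov-chain solver (piecewise
    constant epochs, n1 + n2 <= 6).  For single-population models pass
    ``n2 = 0``.
    """
    timeline = build_timeline(params)
    if engine == "mc":
        return expected_joint_sfs(timeline, n1, n2, theta, cfg)
    if engine == "exact":
        return exact_small_sfs(timeline, n1, n2, theta)
    raise ValueError(f"unknown engine: {engine!r}")


@dataclass
class FitResult:
    """Outcome of a maximum composite-likelihood fit."""

    model_id: str
    params: ScaledParams          # best parameters, theta set to its profile MLE
    loglik: float
    theta: float
    aic: float
    free_names: tuple[str, ...]
    n_evals: int
    converged: bool
    on_bound: bool
    starts: list[dict] = field(default_factory=list)  # per-start trace
    seed: int | None = None
    engine: str = "mc"
    folded_data: bool = False


def _default_starts(free: tuple[str, ...], init: dict[str, float]) -> list[dict]:
    """Two start vectors one order of magnitude apart around ``init``."""
    lo = {k: init[k] / math.sqrt(10.0) for k in free}
    hi = {k: init[k] * math.sqrt(10.0) for k in free}
    return [lo, hi]


def fit_model(model_id: str, data: JointSFS, *,
              free: tuple[str, ...] | None = None,
              fixed: dict[str, float] | None = None,
              starts: list[dict] | None = None,
              bounds: dict[str, tuple[float, float]] | None = None,
              cfg: CoalescentConfig | None = None,
              engine: str = "mc",
              fatol: float = 1e-8,
              xatol: float = 1e-6,
              maxfev: int = 10_000) -> FitResult:
    """Fit a demographic model to an observed spectrum.

    ``free`` names the parameters to optimize (default: all of the
    model's parameters); the rest must be supplied in ``fixed``.  Each
    start is a dict of initial values for the free parameters; by
    default two starts one order of magnitude apart are used, as in an
    exhaustive-start strategy.  theta is profiled analytically at every
    evaluation.  With a fixed ``cfg.seed`` the Monte Carlo objective is
    deterministic, so refits reproduce bit-identically.
    """
    names = MODEL_PARAMS[model_id]
    fixed = dict(fixed or {})
    if free is None:
        free = tuple(n for n in names if n not in fixed)
    free = tuple(free)
    unknown = (set(free) | set(fixed)) - set(names)
    if unknown:
        raise ValueError(f"unknown parameters for {model_id}: {sorted(unknown)}")
    missing = set(names) - set(free) - set(fixed)
    if missing:
        raise ValueError(f"parameters neither free nor fixed: {sorted(missing)}")
    cfg = cfg or CoalescentConfig()
    n1, *rest = data.sample_sizes
    n2 = rest[0] if rest else 0
    if (model_id in SINGLE_POP_MODELS) != (n2 == 0):
        raise ValueError("model dimensionality does not match the data spectrum")

    bounds = dict(bounds or {})
    def _bounds(name: str) -> tuple[float, float]:
        if name in bounds:
            lo, hi = bounds[name]
        elif name.startswith("nu"):
            lo, hi = 1e-5, 1e3
        elif name.startswith("tau"):
            lo, hi = 1e-8, 10.0
        else:  # migration
            lo, hi = 1e-8, 50.0
        if not (lo > 0 and hi > lo):
            raise ValueError(f"bounds for {name} must be positive and ordered")
        return lo, hi

    def _spectrum(values: dict[str, float]) -> JointSFS:
        params = ScaledParams(model_id, {**fixed, **values})
        return model_spectrum(params, n1, n2, cfg, engine)

    um = ~data.mask

    def _profiled_ll(values: dict[str, float]) -> tuple[float, float]:
        shape = _spectrum(values)
        if data.folded:
            from .sfs import fold_sfs
            shape = fold_sfs(shape)
        th = optimal_theta(shape, data)
        model = JointSFS(shape.data * th, data.mask.copy(), shape.folded)
        return poisson_loglik(model, data), th

    if not free:
        ll, th = _profiled_ll({})
        params = ScaledParams(model_id, dict(fixed), th)
        return FitResult(model_id, params, ll, th, aic(ll, 0), free, 1, True,
                         False, [], cfg.seed, engine, data.folded)

    if starts is None:
        init = {}
        for name in free:
            lo, hi = _bounds(name)
            if name.startswith("nu"):
                init[name] = 1.0
            elif name.startswith("tau"):
                init[name] = 0.1
            else:
                init[name] = 1.0
            init[name] = min(max(init[name], lo * 10), hi / 10)
        starts = _default_starts(free, init)
    if len(starts) < 2:
        raise ValueError("at least two starts are required "
                         "(exhaustive-start strategy)")

    nfev = 0
    trace: list[dict] = []
    best = None
    for start in starts:
        x0 = np.log([start[name] for name in free])
        lo = np.log([_bounds(n)[0] for n in free])
        hi = np.log([_bounds(n)[1] for n in free])

        def objective(x):
            xc = np.clip(x, lo, hi)
            values = {n: float(np.exp(v)) for n, v in zip(free, xc)}
            ll, _ = _profiled_ll(values)
            if not np.isfinite(ll):
                return 1e12  # keep the simplex finite when M=0 meets S>0
            penalty = 1e3 * float(np.sum((x - xc) ** 2))
            return -(ll) + penalty

        res = minimize(objective, x0, method="Nelder-Mead",
                       options=dict(fatol=fatol, xatol=xatol,
                                    maxfev=maxfev, maxiter=maxfev))
        nfev += res.nfev
        xb = np.clip(res.x, lo, hi)
        values = {n: float(np.exp(v)) for n, v in zip(free, xb)}
        ll, th = _profiled_ll(values)
        trace.append(dict(start=dict(start), x=values, loglik=ll,
                          nfev=int(res.nfev), converged=bool(res.success)))
        if best is None or ll > best[0]:
            on_bound = bool(np.any(np.isclose(xb, lo, atol=1e-6))
                            or np.any(np.isclose(xb, hi, atol=1e-6)))
            best = (ll, values, th, bool(res.success), on_bound)

    ll, values, th, converged, on_bound = best
    if not any(t["converged"] for t in trace) and not converged:
        converged = False
    params = ScaledParams(model_id, {**fixed, **values}, th)
    k = len(free)
    return FitResult(model_id, params, ll, th, aic(ll, k), free, nfev,
                     converged, on_bound, trace, cfg.seed, engine, data.folded)


def lrt(ll_null: float, ll_alt: float, df: int,
        tolerance: float = 1e-6) -> float:
    """Likelihood-ratio p-value: upper chi-square tail of 2*(ll_alt - ll_null).

    A slightly negative statistic (within ``tolerance``) is clipped to
    zero, as happens when the alternative's optimizer stops a hair
    short; beyond tolerance it is an error.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (ll_alt - ll_null)
    if stat < -tolerance:
        raise ValueError(
            f"alternative log-likelihood below null by {-stat / 2:.3g}; "
            "nested fits are inconsistent"
        )
    stat = max(stat, 0.0)
    return float(chi2.sf(stat, df))


def aic(ll: float, k: int) -> float:
    """Akaike information criterion 2k - 2*ll."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return 2.0 * k - 2.0 * ll


def bootstrap_ci(model_id: str, fit: FitResult, data: JointSFS, n_boot: int, *,
                 cfg: CoalescentConfig | None = None,
                 seed: int = 0,
                 alpha: float = 0.05,
                 max_failures: float = 0.2,
                 starts: list[dict] | None = None) -> dict[str, tuple[float, float]]:
    """Parametric-bootstrap percentile confidence intervals.

    Each replicate resamples every unmasked cell as Poisson with mean
    equal to the fitted expectation, refits the same free parameters,
    and the per-parameter ``(1 - alpha)`` percentile interval is
    reported (including ``theta``).  Aborts if more than
    ``max_failures`` of the refits fail to converge.
    """
    if n_boot == 0:
        return {}
    cfg = cfg or CoalescentConfig(seed=fit.seed or 0)
    n1, *rest = data.sample_sizes
    n2 = rest[0] if rest else 0
    shape = model_spectrum(fit.params, n1, n2, cfg, fit.engine)
    if data.folded:
        from .sfs import fold_sfs
        shape = fold_sfs(shape)
    expectation = np.where(data.mask, 0.0, shape.data * fit.theta)
    rng = np.random.default_rng(seed)
    fixed = {n: v for n, v in fit.params.params.items() if n not in fit.free_names}
    if starts is None:
        starts = [
            {n: fit.params.params[n] / math.sqrt(10) for n in fit.free_names},
            {n: fit.params.params[n] * math.sqrt(10) for n in fit.free_names},
        ]
    draws: dict[str, list[float]] = {n: [] for n in fit.free_names}
    draws["theta"] = []
    failures = 0
    for _ in range(n_boot):
        resampled = JointSFS(rng.poisson(expectation).astype(float),
                             data.mask.copy(), data.folded)
        try:
            refit = fit_model(model_id, resampled, free=fit.free_names,
                              fixed=fixed, starts=starts, cfg=cfg,
                              engine=fit.engine)
        except (ValueError, RuntimeError):
            failures += 1
            continue
        if not refit.converged:
            failures += 1
            continue
        for n in fit.free_names:
            draws[n].append(refit.params.params[n])
        draws["theta"].append(refit.theta)
    if failures > max_failures * n_boot:
        raise RuntimeError(
            f"{failures}/{n_boot} bootstrap refits failed; "
            "check convergence settings before trusting intervals"
        )
    out = {}
    for name, values in draws.items():
        arr = np.sort(np.asarray(values))
        lo = float(np.quantile(arr, alpha / 2))
        hi = float(np.quantile(arr, 1 - alpha / 2))
        out[name] = (lo, hi)
    return out


def anscombe_residuals(model: JointSFS, data: JointSFS) -> np.ndarray:
    """Variance-stabilized Poisson residuals per unmasked cell.

    ``r = 1.5 * (S**(2/3) - M**(2/3)) / M**(1/6)``; cells with ``M = 0``
    are NaN (undefined), masked cells are NaN as well.
    """
    _check_compat(model, data)
    M = model.data
    S = data.data
    with np.errstate(divide="ignore", invalid="ignore"):
        r = 1.5 * (S ** (2.0 / 3.0) - M ** (2.0 / 3.0)) / M ** (1.0 / 6.0)
    r = np.where(data.mask | (M == 0), np.nan, r)
    return r
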