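"""Synthetic parameter-recovery experiment at the published best fit.

The study's genotype panel is not redistributable, so the pipeline is
validated by self-consistency: generate an expected joint SFS under the
best-fit double-bottleneck history, then refit individual parameters
with everything else held at its generating value and check that the
published quantities come back. Data and model spectra are evaluated
with the same Monte Carlo configuration (common random numbers), which
restores the determinism a diffusion-style expected-SFS solver would
have and makes the experiment a test of the fitting machinery rather
than of Monte Carlo noise; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .coalescent import CoalescentConfig, expected_joint_sfs
from .demography import (MAIZE_L, MAIZE_MU, ScaledParams, build_timeline,
                         maize_split5_bestfit, to_scaled)
from .likelihood import FitResult, fit_model
from .sfs import JointSFS

__all__ = ["RecoveryResult", "run_bestfit_recovery"]


@dataclass
class RecoveryResult:
    """Recovered physical-scale quantities from the constrained refits."""

    ancestral_size: float        # Na from profiling theta at the truth shape
    onset_total_size: float      # sum of post-split deme sizes, individuals
    ts_decline_pct: float        # tropical deme decline over the last stage, %
    nss_decline_pct: float       # temperate deme decline over the last stage, %
    bottleneck_size: float       # pre-split bottleneck size, individuals
    n_cells: int                 # unmasked SFS cells fitted
    seed: int
    replicates: int
    fits: dict[str, FitResult]


def _spread_starts(truth: ScaledParams, free: tuple[str, ...]) -> list[dict]:
    lo = {k: truth[k] / math.sqrt(10.0) for k in free}
    hi = {k: truth[k] * math.sqrt(10.0) for k in free}
    return [lo, hi]


def run_bestfit_recovery(seed: int, replicates: int = 100_000,
                         n1: int = 20, n2: int = 20,
                         mu: float = MAIZE_MU,
                         L: float = MAIZE_L) -> RecoveryResult:
    """Generate the synthetic spectrum and run the four constrained refits.

    The spectrum is projected to ``n1 x n2`` haplotypes with theta
    implied by ``4 * Na * mu * L``. Each refit frees only the
    parameter(s) of interest, profiles theta analytically, and starts
    from two points one order of magnitude apart.
    """
    phys = maize_split5_bestfit(mu, L)
    truth = to_scaled(phys)
    cfg = CoalescentConfig(replicates=replicates, seed=seed)
    data = expected_joint_sfs(build_timeline(truth), n1, n2, phys.theta, cfg)
    data = JointSFS(data.data, data.mask, data.folded)  # drop MC SE annotation
    fits: dict[str, FitResult] = {}

    def refit(free: tuple[str, ...]) -> FitResult:
        fixed = {k: v for k, v in truth.params.items() if k not in free}
        fit = fit_model("split5", data, free=free, fixed=fixed,
                        starts=_spread_starts(truth, free) if free else None,
                        cfg=cfg, fatol=1e-6, xatol=1e-4, maxfev=400)
        fits["+".join(free) or "theta"] = fit
        return fit

    def na_of(fit: FitResult) -> float:
        return fit.theta / (4.0 * mu * L)

    base = refit(())
    ancestral_size = na_of(base)

    onset = refit(("nu1", "nu2"))
    onset_total = (onset.params["nu1"] + onset.params["nu2"]) * na_of(onset)

    ts_end = refit(("nu1e",))
    ts_decline = 100.0 * (1.0 - ts_end.params["nu1e"] / truth["nu1"])

    nss_end = refit(("nu2e",))
    nss_decline = 100.0 * (1.0 - nss_end.params["nu2e"] / truth["nu2"])

    bott = refit(("nu_b",))
    bottleneck = bott.params["nu_b"] * na_of(bott)

    return RecoveryResult(
        ancestral_size=ancestral_size,
        onset_total_size=onset_total,
        ts_decline_pct=ts_decline,
        nss_decline_pct=nss_decline,
        bottleneck_size=bottleneck,
        n_cells=int((~data.mask).sum()),
        seed=seed,
        replicates=replicates,
        fits=fits,
    )
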