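"""Demographic models for the tropical-temperate maize split.

Models are expressed in diffusion-style scaled units: deme sizes are
relative to the ancestral effective size ``Na``, epoch durations are in
units of ``2*Na`` generations, and migration is carried as the scaled
rate ``M = 2*Na*m`` where ``m`` is the per-generation proportion of a
deme made up of new migrants.  ``theta = 4*Na*mu*L`` links a scaled fit
to physical units, with ``mu`` the substitution rate per bp per
generation and ``L`` the effective sequence length in bp.

Eight model parameterizations are provided: three single-population
histories (``neutral``, ``two_epoch``, ``three_epoch``) and five
two-population split histories (``split1`` ... ``split5``).  ``split5``
is the double-bottleneck history used for the maize analysis: a short,
severe domestication bottleneck, an instantaneous split into a tropical
(TS) and a temperate founder (NSS) deme that stay constant while the
populations re-establish, and a final stage during which both demes
shrink linearly towards the present, with gene flow allowed in both
post-split stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "MODEL_PARAMS",
    "SINGLE_POP_MODELS",
    "NESTING",
    "ScaledParams",
    "PhysicalParams",
    "SizeFunc",
    "Epoch",
    "DemographyTimeline",
    "build_timeline",
    "to_physical",
    "to_scaled",
    "n_free_params",
    "maize_split5_bestfit",
    "read_params",
    "write_params",
]

#: Ordered free-parameter names per model (theta is always profiled separately).
MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "neutral": (),
    "two_epoch": ("nu", "tau"),
    "three_epoch": ("nu_b", "nu_f", "tau_b", "tau_f"),
    "split1": ("nu1", "nu2", "tau_s", "m"),
    "split2": ("nu0", "tau0", "nu1", "nu2", "tau_s", "m"),
    "split3": ("nu1", "nu2a", "nu2b", "tau_a", "tau_b", "m"),
    "split4": ("nu_b", "tau_b", "nu1", "nu2", "tau_s", "m"),
    "split5": (
        "nu_b", "tau1", "nu1", "nu2", "tau2", "m1", "nu1e", "nu2e", "tau3", "m2",
    ),
}

SINGLE_POP_MODELS = frozenset({"neutral", "two_epoch", "three_epoch"})

#: Declared nesting graph: alternative model -> null models it strictly contains,
#: as parameterized here.  split3 (instantaneous post-split step) and split4
#: (exponential pre-split recovery) are not exact sub-models of split5's
#: linear-decline parameterization and are therefore not declared under it.
NESTING: dict[str, tuple[str, ...]] = {
    "two_epoch": ("neutral",),
    "three_epoch": ("neutral", "two_epoch"),
    "split2": ("split1",),
    "split3": ("split1",),
    "split4": ("split1",),
    "split5": ("split1", "split2"),
}


def n_free_params(model_id: str) -> int:
    """Number of free demographic parameters of a model (theta excluded)."""
    return len(MODEL_PARAMS[model_id])


def _check_model(model_id: str) -> None:
    if model_id not in MODEL_PARAMS:
        raise ValueError(f"unknown model_id: {model_id!r}")


@dataclass(frozen=True)
class ScaledParams:
    """Model parameters in scaled (diffusion) units.

    ``params`` maps parameter names (see :data:`MODEL_PARAMS`) to values.
    Names beginning with ``nu`` are relative deme sizes (units of Na),
    names beginning with ``tau`` are durations (units of 2*Na
    generations) and names beginning with ``m`` are scaled migration
    rates M = 2*Na*m.  ``theta`` is the scaled mutation supply
    4*Na*mu*L; it may be ``None`` when profiled out of a fit.
    """

    model_id: str
    params: dict[str, float] = field(default_factory=dict)
    theta: float | None = None

    def __post_init__(self) -> None:
        _check_model(self.model_id)
        names = MODEL_PARAMS[self.model_id]
        missing = set(names) - set(self.params)
        extra = set(self.params) - set(names)
        if missing or extra:
            raise ValueError(
                f"{self.model_id}: missing params {sorted(missing)}, "
                f"unexpected params {sorted(extra)}"
            )
        for name, value in self.params.items():
            if name.startswith("nu") and not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")
            if name.startswith("tau") and value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
            if name.startswith("m") and value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.theta is not None and not self.theta > 0:
            raise ValueError(f"theta must be > 0, got {self.theta}")

    def __getitem__(self, name: str) -> float:
        return self.params[name]

    def with_values(self, **updates: float) -> "ScaledParams":
        """Copy with some parameter values replaced."""
        new = dict(self.params)
        theta = updates.pop("theta", self.theta)
        new.update(updates)
        return ScaledParams(self.model_id, new, theta)


@dataclass(frozen=True)
class PhysicalParams:
    """Model parameters in physical units (individuals and years).

    ``sizes`` are deme sizes in individuals (one entry per ``nu``
    parameter), ``durations`` are epoch durations in years (one per
    ``tau``; the generation time is one year throughout, as for maize),
    and ``migration`` keeps the scaled rates M = 2*Na*m exactly as a
    scaled fit reports them; the per-generation migrant proportion m is
    exposed via :meth:`migrant_proportion`.
    """

    model_id: str
    Na: float
    mu: float
    L: float
    sizes: dict[str, float] = field(default_factory=dict)
    durations: dict[str, float] = field(default_factory=dict)
    migration: dict[str, float] = field(default_factory=dict)
    generation_time: float = 1.0

    def __post_init__(self) -> None:
        _check_model(self.model_id)
        if not (self.Na > 0 and self.mu > 0 and self.L > 0):
            raise ValueError("Na, mu and L must all be positive")

    @property
    def theta(self) -> float:
        """Scaled mutation supply theta = 4*Na*mu*L."""
        return 4.0 * self.Na * self.mu * self.L

    def migrant_proportion(self, name: str) -> float:
        """Per-generation migrant proportion m = M/(2*Na)."""
        return self.migration[name] / (2.0 * self.Na)


def to_physical(params: ScaledParams, mu: float, L: float,
                generation_time: float = 1.0) -> PhysicalParams:
    """Convert scaled parameters to physical units via theta = 4*Na*mu*L."""
    if params.theta is None:
        raise ValueError("theta is required to convert to physical units")
    if not (mu > 0 and L > 0):
        raise ValueError("mu and L must be positive")
    Na = params.theta / (4.0 * mu * L)
    sizes, durations, migration = {}, {}, {}
    for name, value in params.params.items():
        if name.startswith("nu"):
            sizes[name] = value * Na
        elif name.startswith("tau"):
            durations[name] = value * 2.0 * Na * generation_time
        else:
            migration[name] = value
    return PhysicalParams(params.model_id, Na, mu, L, sizes, durations,
                          migration, generation_time)


def to_scaled(params: PhysicalParams) -> ScaledParams:
    """Exact inverse of :func:`to_physical`."""
    scaled: dict[str, float] = {}
    for name, value in params.sizes.items():
        scaled[name] = value / params.Na
    for name, value in params.durations.items():
        scaled[name] = value / (2.0 * params.Na * params.generation_time)
    scaled.update(params.migration)
    return ScaledParams(params.model_id, scaled, params.theta)


# ---------------------------------------------------------------------------
# Timelines


@dataclass(frozen=True)
class SizeFunc:
    """Deme size over one epoch; ``start`` is the older end, ``end`` the recent end."""

    kind: str  # "constant" | "linear" | "exponential"
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "linear", "exponential"):
            raise ValueError(f"unknown size function kind: {self.kind!r}")
        if not (self.start > 0 and self.end > 0):
            raise ValueError("deme sizes must stay strictly positive over an epoch")
        if self.kind == "constant" and self.start != self.end:
            raise ValueError("constant size function with start != end")


@dataclass(frozen=True)
class Epoch:
    """One epoch of a timeline: duration (scaled), per-deme sizes, migration."""

    duration: float
    sizes: tuple[SizeFunc, ...]
    migration: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("epoch duration must be >= 0")
        d = len(self.sizes)
        if len(self.migration) != d or any(len(row) != d for row in self.migration):
            raise ValueError("migration matrix shape must match deme count")
        if any(rate < 0 for row in self.migration for rate in row):
            raise ValueError("migration rates must be >= 0")

    @property
    def n_demes(self) -> int:
        return len(self.sizes)


@dataclass(frozen=True)
class DemographyTimeline:
    """Epochs ordered past -> present; the first epoch is the infinite ancestral one."""

    epochs: tuple[Epoch, ...]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("timeline needs at least one epoch")
        if not math.isinf(self.epochs[0].duration):
            raise ValueError("the oldest epoch must have infinite duration")
        if any(math.isinf(e.duration) for e in self.epochs[1:]):
            raise ValueError("only the oldest epoch may be infinite")
        counts = [e.n_demes for e in self.epochs]
        splits = sum(1 for a, b in zip(counts, counts[1:]) if b > a)
        if any(b < a for a, b in zip(counts, counts[1:])):
            raise ValueError("deme count may not decrease towards the present")
        if splits > 1:
            raise ValueError("at most one split event is supported")

    @property
    def n_demes(self) -> int:
        """Deme count at the present."""
        return self.epochs[-1].n_demes


def _const(nu: float) -> SizeFunc:
    return SizeFunc("constant", nu, nu)


_NO_MIG_1 = ((0.0,),)


def _sym_mig(M: float) -> tuple[tuple[float, float], tuple[float, float]]:
    return ((0.0, M), (M, 0.0))


def build_timeline(params: ScaledParams) -> DemographyTimeline:
    """Expand a parameter set into its explicit epoch timeline.

    The returned epochs run past -> present, starting with the infinite
    ancestral epoch at relative size 1.
    """
    p = params.params
    mid = params.model_id
    ancestral = Epoch(math.inf, (_const(1.0),), _NO_MIG_1)
    epochs: list[Epoch] = [ancestral]
    if mid == "neutral":
        pass
    elif mid == "two_epoch":
        epochs.append(Epoch(p["tau"], (_const(p["nu"]),), _NO_MIG_1))
    elif mid == "three_epoch":
        epochs.append(Epoch(p["tau_b"], (_const(p["nu_b"]),), _NO_MIG_1))
        epochs.append(Epoch(p["tau_f"], (_const(p["nu_f"]),), _NO_MIG_1))
    elif mid == "split1":
        epochs.append(Epoch(p["tau_s"], (_const(p["nu1"]), _const(p["nu2"])),
                            _sym_mig(p["m"])))
    elif mid == "split2":
        epochs.append(Epoch(p["tau0"], (_const(p["nu0"]),), _NO_MIG_1))
        epochs.append(Epoch(p["tau_s"], (_const(p["nu1"]), _const(p["nu2"])),
                            _sym_mig(p["m"])))
    elif mid == "split3":
        epochs.append(Epoch(p["tau_a"], (_const(p["nu1"]), _const(p["nu2a"])),
                            _sym_mig(p["m"])))
        epochs.append(Epoch(p["tau_b"], (_const(p["nu1"]), _const(p["nu2b"])),
                            _sym_mig(p["m"])))
    elif mid == "split4":
        # Bottleneck that recovers exponentially to the ancestral size
        # before the split.
        epochs.append(Epoch(p["tau_b"],
                            (SizeFunc("exponential", p["nu_b"], 1.0),),
                            _NO_MIG_1))
        epochs.append(Epoch(p["tau_s"], (_const(p["nu1"]), _const(p["nu2"])),
                            _sym_mig(p["m"])))
    elif mid == "split5":
        epochs.append(Epoch(p["tau1"], (_const(p["nu_b"]),), _NO_MIG_1))
        epochs.append(Epoch(p["tau2"], (_const(p["nu1"]), _const(p["nu2"])),
                            _sym_mig(p["m1"])))
        epochs.append(Epoch(p["tau3"],
                            (SizeFunc("linear", p["nu1"], p["nu1e"]),
                             SizeFunc("linear", p["nu2"], p["nu2e"])),
                            _sym_mig(p["m2"])))
    else:  # pragma: no cover - guarded by ScaledParams validation
        raise ValueError(f"unknown model_id: {mid!r}")
    return DemographyTimeline(tuple(epochs))


# ---------------------------------------------------------------------------
# Published best-fit history

#: Printed substitution rate per bp per generation (synonymous sites).
MAIZE_MU = 2.230e-8
#: Effective sequence length after distance thinning, bp.
MAIZE_L = 3.8e6


def maize_split5_bestfit(mu: float = MAIZE_MU, L: float = MAIZE_L) -> PhysicalParams:
    """Best-fit double-bottleneck (split5) history for tropical/temperate maize.

    Ancestral size 24,162; domestication bottleneck of 142 individuals
    lasting 5 generations; split into a tropical deme of 9,434 (the
    10,746 onset total minus the founders) and a temperate founder deme
    of 1,312; 126 generations of constant-size divergence; then 4,832
    years of linear shrinking to 75% (TS) and 35% (NSS) of the onset
    sizes.  Migration (scaled M) is 4.3e-3 during the split-recovery
    stage and 1.2e-3 during the shrinking stage.
    """
    Na = 24_162.0
    ts_onset = 10_746.0 - 1_312.0  # TS onset size, derived from the printed total
    return PhysicalParams(
        model_id="split5",
        Na=Na,
        mu=mu,
        L=L,
        sizes={
            "nu_b": 142.0,
            "nu1": ts_onset,
            "nu2": 1_312.0,
            "nu1e": 0.75 * ts_onset,
            "nu2e": 0.35 * 1_312.0,
        },
        durations={"tau1": 5.0, "tau2": 126.0, "tau3": 4_832.0},
        migration={"m1": 4.3e-3, "m2": 1.2e-3},
    )


# ---------------------------------------------------------------------------
# Flat key-value parameter files


def write_params(path, params: ScaledParams | PhysicalParams) -> None:
    """Write a parameter set as flat `name value` lines with a units header."""
    lines = [f"model {params.model_id}"]
    if isinstance(params, ScaledParams):
        lines.append("units scaled")
        if params.theta is not None:
            lines.append(f"theta {float(params.theta)!r}")
        for name, value in params.params.items():
            lines.append(f"{name} {float(value)!r}")
    else:
        lines.append("units physical")
        lines.append(f"Na {float(params.Na)!r}")
        lines.append(f"mu {float(params.mu)!r}")
        lines.append(f"L {float(params.L)!r}")
        lines.append(f"generation_time {float(params.generation_time)!r}")
        for group in (params.sizes, params.durations, params.migration):
            for name, value in group.items():
                lines.append(f"{name} {float(value)!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_params(path) -> ScaledParams | PhysicalParams:
    """Read a parameter file written by :func:`write_params`."""
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, _, value = line.partition(" ")
            kv[name] = value.strip()
    model_id = kv.pop("model")
    units = kv.pop("units")
    _check_model(model_id)
    if units == "scaled":
        theta = float(kv.pop("theta")) if "theta" in kv else None
        return ScaledParams(model_id, {k: float(v) for k, v in kv.items()}, theta)
    if units != "physical":
        raise ValueError(f"units must be 'scaled' or 'physical', got {units!r}")
    Na = float(kv.pop("Na"))
    mu = float(kv.pop("mu"))
    L = float(kv.pop("L"))
    gen = float(kv.pop("generation_time", "1.0"))
    sizes, durations, migration = {}, {}, {}
    for name, value in kv.items():
        if name.startswith("nu"):
            sizes[name] = float(value)
        elif name.startswith("tau"):
            durations[name] = float(value)
        else:
            migration[name] = float(value)
    return PhysicalParams(model_id, Na, mu, L, sizes, durations, migration, gen)
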