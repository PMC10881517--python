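"""Synthetic force-clamp data with the statistical structure of AFM records.

Replaces the instrument for testing and validation: bond lifetimes are
drawn from the exact stochastic kinetics of the sliding-rebinding model
(optionally contaminated with the short-lived second component that
appears at high force in tetrameric complexes), clamp traces carry a
noisy force plateau with transient spikes and discrete height steps at
Bell-distributed unfolding times, and per-force unfolding counts follow
Poisson statistics with Bell-probability means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kinetics
from .clamp import ClampDataset, ClampTrace
from .params import KBT_ROOM, SlidingRebindingParams, UnfoldingClassParams

__all__ = [
    "TraceRecipe",
    "generate_lifetime_dataset",
    "generate_trace",
    "generate_unfolding_counts",
    "datasets_to_curve",
]

# Short-lived component observed at high clamp force for the tetrameric
# complex: time constant ~1 s, with a weight that grows with force.  The
# logistic midpoint/width are the generator's convention (the observation
# is only qualitative: the component appears above ~70 pN).
HIGH_FORCE_TAU = 1.0
HIGH_FORCE_MIDPOINT = 85.0
HIGH_FORCE_WIDTH = 8.0


def _short_component_weight(force: float) -> float:
    return 1.0 / (1.0 + np.exp(-(force - HIGH_FORCE_MIDPOINT) / HIGH_FORCE_WIDTH))


def generate_lifetime_dataset(
    params: SlidingRebindingParams,
    forces: np.ndarray,
    n_per_force: int,
    seed: int = 0,
    bi_exp_highforce: bool = False,
    max_duration: float = 10.0,
) -> list[ClampDataset]:
    """Per-force bond-lifetime samples from the kinetic model.

    Lifetimes are exact Gillespie first-passage times.  With
    ``bi_exp_highforce`` a short-lived (~1 s) exponential component is
    mixed in with a logistic force-dependent weight, mimicking the
    second decay channel of tetrameric complexes at high force.  Events
    outliving ``max_duration`` are right-censored at it.
    """
    if n_per_force < 1:
        raise ValueError("n_per_force must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for f in np.asarray(forces, dtype=float):
        lifetimes = kinetics.gillespie_lifetimes(params, f, n_per_force, rng)
        if bi_exp_highforce:
            w = _short_component_weight(f)
            short = rng.random(n_per_force) < w
            lifetimes = np.where(
                short, rng.exponential(HIGH_FORCE_TAU, n_per_force), lifetimes
            )
        censored = lifetimes >= max_duration
        lifetimes = np.minimum(lifetimes, max_duration)
        out.append(
            ClampDataset(
                clamp_force=float(f),
                lifetimes=lifetimes,
                censored=censored,
                max_duration=max_duration,
            )
        )
    return out


@dataclass
class TraceRecipe:
    """Everything needed to synthesise one clamp trace.

    ``step_classes`` lists the unfolding step populations as
    ``(mean_nm, sd_nm, UnfoldingClassParams)`` tuples; unfolding times
    are drawn from the Bell rate of each class at the clamp force.
    ``spike_depth`` is the transient force drop accompanying a step.
    """

    clamp_force: float
    kinetic_params: SlidingRebindingParams
    max_duration: float = 10.0
    sampling_rate: float = 1000.0
    force_noise_sd: float = 2.0
    height_noise_sd: float = 0.3
    step_classes: list = field(default_factory=list)
    spike_duration: float = 0.16
    spike_depth: float = 12.0
    max_events_per_class: int = 1
    kBT: float = KBT_ROOM

    def __post_init__(self) -> None:
        if self.max_duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("durations and rates must be positive")
        if self.spike_duration <= 0:
            raise ValueError("spike_duration must be positive")
        means = [c[0] for c in self.step_classes]
        if len(set(means)) != len(means):
            raise ValueError("step class means must be distinct")


def generate_trace(
    recipe: TraceRecipe, seed: int = 0, return_events: bool = False
):
    """Synthesise one force/height clamp trace.

    The trace holds the clamp force (plus Gaussian noise) until the bond
    dissociation time drawn from the kinetic model.  Each unfolding event
    adds a discrete height gain and a rectangular force dip of the
    recipe's spike duration.  Each step class fires at most
    ``max_events_per_class`` times (a domain unfolds once).  With
    ``return_events`` the injected ``(time, height_gain)`` ground truth is
    returned alongside the trace.
    """
    rng = np.random.default_rng(seed)
    t_diss = float(
        kinetics.gillespie_lifetimes(recipe.kinetic_params, recipe.clamp_force, 1, rng)[0]
    )
    t_end = min(t_diss, recipe.max_duration)
    n = max(int(np.ceil(t_end * recipe.sampling_rate)), 10)
    time = np.arange(n) / recipe.sampling_rate
    force = recipe.clamp_force + rng.normal(0.0, recipe.force_noise_sd, n)
    height = rng.normal(0.0, recipe.height_noise_sd, n)

    from .unfolding import unfolding_rate

    spike_n = max(int(round(recipe.spike_duration * recipe.sampling_rate)), 1)
    events = []
    for mean_nm, sd_nm, class_params in recipe.step_classes:
        rate = unfolding_rate(class_params, recipe.clamp_force, recipe.kBT)
        if rate <= 0:
            continue
        t = rng.exponential(1.0 / rate)
        fired = 0
        while t < t_end and fired < recipe.max_events_per_class:
            i = int(t * recipe.sampling_rate)
            gain = rng.normal(mean_nm, sd_nm)
            height[i:] += gain
            force[i:i + spike_n] -= recipe.spike_depth
            events.append((t, gain))
            fired += 1
            t += rng.exponential(1.0 / rate)
    trace = ClampTrace(
        time=time,
        force=force,
        height=height,
        setpoint=recipe.clamp_force,
        sampling_rate=recipe.sampling_rate,
    )
    if return_events:
        return trace, sorted(events)
    return trace


def generate_unfolding_counts(
    class_params: list[UnfoldingClassParams],
    forces: np.ndarray,
    exposure: float,
    seed: int = 0,
    t_obs: float = 1.0,
    kBT: float = KBT_ROOM,
) -> np.ndarray:
    """Poisson unfolding counts per class and force.

    Counts have means ``exposure * P_u(class, force)`` with the Bell
    unfolding probability evaluated at the observation window ``t_obs``.
    Returns an array of shape ``(n_forces, n_classes)``.
    """
    if exposure < 1:
        raise ValueError("exposure must be >= 1")
    from .unfolding import unfolding_probability, unfolding_rate

    rng = np.random.default_rng(seed)
    forces = np.asarray(forces, dtype=float)
    means = np.empty((forces.size, len(class_params)))
    for j, cp in enumerate(class_params):
        for i, f in enumerate(forces):
            means[i, j] = exposure * unfolding_probability(
                unfolding_rate(cp, f, kBT), t_obs
            )
    return rng.poisson(means)


def datasets_to_curve(
    datasets: list[ClampDataset],
    estimator: str = "expfit",
) -> kinetics.LifetimeForceCurve:
    """Reduce per-force lifetime samples to a lifetime-force curve.

    Mirrors the experimental chain: product-limit survival estimate per
    force, then a mono-exponential fit whose time constant is the mean
    lifetime (``estimator="expfit"``), or the censoring-naive sample mean
    (``estimator="mean"``).
    """
    from .clamp import empirical_survival, fit_exponential

    forces, taus, errs = [], [], []
    for ds in sorted(datasets, key=lambda d: d.clamp_force):
        forces.append(ds.clamp_force)
        if estimator == "expfit":
            fit = fit_exponential(empirical_survival(ds), order=1)
            taus.append(fit.taus[0])
            errs.append(
                fit.param_errors[0] if fit.param_errors is not None else np.nan
            )
        elif estimator == "mean":
            taus.append(float(np.mean(ds.lifetimes)))
            errs.append(float(np.std(ds.lifetimes) / np.sqrt(ds.n_events)))
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
    return kinetics.LifetimeForceCurve(
        forces=np.array(forces),
        mean_lifetimes=np.array(taus),
        errors=np.array(errs),
    )
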