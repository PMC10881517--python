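"""Force-clamp survival analysis and trace processing.

This module covers what an experimentalist does with clamp data: estimate
bond survival probabilities from rupture-time samples (with right
censoring at the clamp duration), fit mono- and bi-exponential decays and
pick between them with an F-test, fit Bell (slip) or constant (ideal)
models to lifetime-force curves over chosen force windows, detect
unfolding steps in time traces, and fit Gaussian mixtures to step-height
distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .kinetics import LifetimeForceCurve, SurvivalCurve

__all__ = [
    "ClampDataset",
    "ClampTrace",
    "ExpFit",
    "StepEvent",
    "BellSlipFit",
    "MixtureFit",
    "empirical_survival",
    "fit_exponential",
    "select_model_ftest",
    "fit_bell_slip",
    "detect_steps",
    "fit_step_height_mixture",
]


@dataclass
class ClampDataset:
    """Bond-lifetime samples recorded at one clamp force.

    ``censored[i]`` marks events that survived the full clamp window
    (``max_duration``, 10 s or 20 s depending on protocol) without
    dissociating; their recorded lifetime equals ``max_duration``.
    """

    clamp_force: float
    lifetimes: np.ndarray
    censored: np.ndarray | None = None
    max_duration: float = 10.0

    def __post_init__(self) -> None:
        self.lifetimes = np.asarray(self.lifetimes, dtype=float)
        if self.censored is None:
            self.censored = np.zeros(self.lifetimes.size, dtype=bool)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.censored.shape != self.lifetimes.shape:
            raise ValueError("censored flags must match lifetimes")
        if np.any(self.lifetimes <= 0):
            raise ValueError("lifetimes must be positive")
        if np.any(self.lifetimes > self.max_duration + 1e-9):
            raise ValueError("lifetimes cannot exceed max_duration")

    @property
    def n_events(self) -> int:
        return int(self.lifetimes.size)


@dataclass
class ClampTrace:
    """Columnar time/force/height record of one clamp attempt."""

    time: np.ndarray
    force: np.ndarray
    height: np.ndarray
    setpoint: float
    sampling_rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.height = np.asarray(self.height, dtype=float)
        if not (self.time.shape == self.force.shape == self.height.shape):
            raise ValueError("time, force, height must have equal shapes")


@dataclass
class ExpFit:
    """Mono- or bi-exponential fit of a survival curve."""

    order: int
    taus: np.ndarray  # ascending
    amplitudes: np.ndarray  # sum to 1
    rss: float
    dof: int
    param_errors: np.ndarray | None = None

    @property
    def mean_tau(self) -> float:
        """Amplitude-weighted mean time constant."""
        return float(np.dot(self.amplitudes, self.taus))


@dataclass
class StepEvent:
    """One unfolding step detected in a clamp trace."""

    time: float
    height_gain: float
    spike_duration: float


@dataclass
class BellSlipFit:
    """Bell-model (slip) or constant (ideal) fit over a force window."""

    tau0: float
    f_star: float  # inf flags an ideal (force-insensitive) fit
    fit_error_percent: float
    model: str = "slip"
    param_errors: tuple = (np.nan, np.nan)


@dataclass
class MixtureFit:
    """Gaussian mixture fit of a step-height distribution."""

    means: np.ndarray  # ascending
    sds: np.ndarray
    weights: np.ndarray
    mean_errors: np.ndarray
    converged: bool
    collapsed: bool


def empirical_survival(dataset: ClampDataset) -> SurvivalCurve:
    """Product-limit (Kaplan-Meier) survival estimate of bond lifetimes.

    Right-censored events (bond outlived the clamp window) contribute to
    the risk set without registering a rupture.  With no censoring this
    reduces to the naive fraction of bonds surviving beyond ``t``.
    """
    if dataset.n_events == 0:
        raise ValueError("empty dataset")
    if np.all(dataset.censored):
        raise ValueError("all events censored; survival curve undefined")
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(dataset.lifetimes, event_observed=~dataset.censored)
    times = np.asarray(km.survival_function_.index, dtype=float)
    surv = np.asarray(km.survival_function_.iloc[:, 0], dtype=float)
    if times[0] > 0:
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
    return SurvivalCurve(times=times, survival=surv)


def _biexp(t, a, tau1, tau2):
    return a * np.exp(-t / tau1) + (1 - a) * np.exp(-t / tau2)


def fit_exponential(survival: SurvivalCurve, order: int = 1) -> ExpFit:
    """Least-squares mono- or bi-exponential fit of a survival curve.

    Mirrors the experimental procedure of fitting the estimated survival
    probabilities rather than maximising a likelihood on raw lifetimes.
    For ``order=2`` the two time constants are returned in ascending
    order.
    """
    t, s = survival.times, survival.survival
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    # crude scale for initialisation: time at which S first drops below 1/e
    below = np.nonzero(s <= np.exp(-1.0))[0]
    tau_guess = float(t[below[0]]) if below.size else float(t[-1])
    tau_guess = max(tau_guess, 1e-6)

    # a time constant far beyond the observation window is unidentifiable
    tau_cap = 100.0 * max(float(t[-1]), 1e-6)

    if order == 1:
        popt, pcov = curve_fit(
            lambda tt, tau: np.exp(-tt / tau), t, s,
            p0=[min(tau_guess, tau_cap)], bounds=(1e-12, tau_cap),
            maxfev=10000,
        )
        resid = s - np.exp(-t / popt[0])
        return ExpFit(
            order=1,
            taus=np.array([popt[0]]),
            amplitudes=np.array([1.0]),
            rss=float(resid @ resid),
            dof=t.size - 1,
            param_errors=np.sqrt(np.diag(pcov)),
        )

    # seed one start from the mono-exponential solution (A = 1 makes the
    # bi-exponential collapse onto it), guaranteeing the nested fit never
    # ends up worse than order 1
    tau_mono = fit_exponential(survival, 1).taus[0]
    inits = [
        (1.0, tau_mono, min(tau_mono * 10, tau_cap)),
        (0.5, tau_guess / 4, tau_guess * 2),
        (0.3, tau_guess / 10, tau_guess),
        (0.7, tau_guess / 2, tau_guess * 5),
    ]
    best = None
    tried = []
    for p0 in inits:
        p0 = (p0[0], min(p0[1], tau_cap), min(p0[2], tau_cap))
        try:
            popt, pcov = curve_fit(
                _biexp, t, s, p0=p0,
                bounds=([0.0, 1e-12, 1e-12], [1.0, tau_cap, tau_cap]),
                maxfev=20000,
            )
        except RuntimeError:
            tried.append(p0)
            continue
        resid = s - _biexp(t, *popt)
        rss = float(resid @ resid)
        if best is None or rss < best[1]:
            best = (popt, rss, pcov)
    if best is None:
        raise RuntimeError(f"bi-exponential fit failed; initialisations tried: {inits}")
    popt, rss, pcov = best
    a, tau1, tau2 = popt
    amps = np.array([a, 1 - a])
    taus = np.array([tau1, tau2])
    idx = np.argsort(taus)
    return ExpFit(
        order=2,
        taus=taus[idx],
        amplitudes=amps[idx],
        rss=rss,
        dof=t.size - 3,
        param_errors=np.sqrt(np.diag(pcov)),
    )


def select_model_ftest(fit1: ExpFit, fit2: ExpFit, alpha: float = 0.05) -> int:
    """Pick mono- vs bi-exponential by an F-test on nested fits.

    Returns 1 or 2.  The bi-exponential is selected only when the
    residual reduction is significant at level ``alpha``.
    """
    if fit1.order != 1 or fit2.order != 2:
        raise ValueError("fit1 must be the order-1 fit, fit2 the order-2 fit")
    d_dof = fit1.dof - fit2.dof
    if fit2.rss <= 0:
        return 2 if fit1.rss > 0 else 1
    f_stat = ((fit1.rss - fit2.rss) / d_dof) / (fit2.rss / fit2.dof)
    if f_stat <= 0:
        return 1
    p = stats.f.sf(f_stat, d_dof, fit2.dof)
    return 2 if p < alpha else 1


def fit_bell_slip(
    curve: LifetimeForceCurve,
    force_window: tuple[float, float],
    model: str = "slip",
) -> BellSlipFit:
    """Fit ``<tau> = tau0 exp(-f/f*)`` (slip) or ``<tau> = tau0`` (ideal).

    The percent fit error is 100 x RMS residual / mean fitted value over
    the window.  A slip fit on force-insensitive data is flagged by
    ``f_star = inf``.
    """
    lo, hi = force_window
    mask = (curve.forces >= lo) & (curve.forces <= hi)
    f = curve.forces[mask]
    tau = curve.mean_lifetimes[mask]
    if f.size < 3:
        raise ValueError("need at least 3 points in the force window")
    if model == "ideal":
        tau0 = float(np.mean(tau))
        resid = tau - tau0
        err = 100.0 * np.sqrt(np.mean(resid**2)) / tau0
        return BellSlipFit(tau0=tau0, f_star=np.inf,
                           fit_error_percent=float(err), model="ideal")
    if model != "slip":
        raise ValueError("model must be 'slip' or 'ideal'")
    # log-linear estimate seeds the nonlinear fit
    slope, intercept = np.polyfit(f, np.log(tau), 1)
    if abs(slope) < 1e-12:
        tau0 = float(np.exp(intercept))
        return BellSlipFit(tau0=tau0, f_star=np.inf, fit_error_percent=0.0,
                           model="slip")
    p0 = [np.exp(intercept), -1.0 / slope]
    popt, pcov = curve_fit(
        lambda ff, tau0, fstar: tau0 * np.exp(-ff / fstar), f, tau,
        p0=p0, maxfev=20000,
    )
    fitted = popt[0] * np.exp(-f / popt[1])
    err = 100.0 * np.sqrt(np.mean((tau - fitted) ** 2)) / np.mean(fitted)
    return BellSlipFit(
        tau0=float(popt[0]),
        f_star=float(popt[1]),
        fit_error_percent=float(err),
        model="slip",
        param_errors=tuple(np.sqrt(np.diag(pcov))),
    )


def detect_steps(
    trace: ClampTrace,
    force_drop_sigma: float = 3.0,
    min_height_nm: float = 3.0,
    min_run: int = 3,
    window_s: float = 0.05,
    merge_gap_s: float = 0.01,
) -> list[StepEvent]:
    """Detect unfolding steps in a clamp trace.

    An unfolding event shows up as a brief force spike (the clamp force
    momentarily drops while the feedback catches up) accompanied by a
    discrete gain in tip-surface height.  Events are contiguous runs of
    at least ``min_run`` samples where the force falls below ``setpoint -
    force_drop_sigma * sigma``, paired with the difference of windowed
    height medians before and after the run.  The noise scale ``sigma``
    is estimated from the positive residuals only, because spikes pull
    the force down and would otherwise inflate the estimate.  Runs closer
    than ``merge_gap_s`` are merged; runs whose height gain falls below
    ``min_height_nm`` are discarded.
    """
    force = trace.force
    n = force.size
    if n < 10:
        raise ValueError("trace too short")
    resid = force - trace.setpoint
    pos = resid[resid >= 0]
    if pos.size < 5:
        raise ValueError("no clamp plateau near the setpoint in this trace")
    # median(|X|) = 0.6745 sigma for a half-normal
    sigma = np.median(pos) / 0.6745
    if sigma == 0:
        sigma = max(np.std(resid), 1e-12)
    # plateau sanity: a meaningful share of the trace near the setpoint
    in_band = np.abs(resid) < 5 * sigma + 1e-12
    if in_band.mean() < 0.3:
        raise ValueError("no clamp plateau near the setpoint in this trace")

    below = resid < -force_drop_sigma * sigma
    w = max(int(round(window_s * trace.sampling_rate)), 2)
    gap = max(int(round(merge_gap_s * trace.sampling_rate)), 1)

    # contiguous runs of below-threshold samples, merged across short gaps
    runs: list[list[int]] = []
    i = 0
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j < n and below[j]:
            j += 1
        if runs and i - runs[-1][1] <= gap:
            runs[-1][1] = j
        else:
            runs.append([i, j])
        i = j

    events: list[StepEvent] = []
    for i, j in runs:
        if j - i < min_run:
            continue
        pre = trace.height[max(0, i - w):i]
        post = trace.height[j:min(n, j + w)]
        if post.size < 2:
            # spike truncated by the end of the trace: the height has
            # already stepped, so read it inside the dip
            post = trace.height[min(i + 2, n - 2):n]
        if pre.size < 2 or post.size < 2:
            continue
        gain = float(np.median(post) - np.median(pre))
        if gain >= min_height_nm:
            events.append(
                StepEvent(
                    time=float(trace.time[i]),
                    height_gain=gain,
                    spike_duration=(j - i) / trace.sampling_rate,
                )
            )
    return events


def fit_step_height_mixture(
    heights: np.ndarray,
    n_components: int = 4,
    random_state: int = 0,
) -> MixtureFit:
    """Gaussian mixture fit of unfolding step heights.

    Returns component means in ascending order with standard errors
    (component SD over the square root of its effective sample count).
    Component collapse (two means closer than half the smaller SD) is
    flagged rather than silently accepted.
    """
    heights = np.asarray(heights, dtype=float).reshape(-1, 1)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if heights.size < 5 * n_components:
        raise ValueError("too few samples for the requested component count")
    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(
        n_components=n_components,
        n_init=10,
        random_state=random_state,
        covariance_type="full",
    ).fit(heights)
    if not gm.converged_:
        warnings.warn("Gaussian mixture EM did not converge")
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    n_eff = np.maximum(weights * heights.size, 1.0)
    errors = sds / np.sqrt(n_eff)
    gaps = np.diff(means)
    collapsed = bool(
        np.any(gaps < 0.5 * np.minimum(sds[:-1], sds[1:]))
    ) if n_components > 1 else False
    return MixtureFit(
        means=means, sds=sds, weights=weights, mean_errors=errors,
        converged=bool(gm.converged_), collapsed=collapsed,
    )
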