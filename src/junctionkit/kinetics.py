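"""Kinetic models for junction assembly, disassembly and spheroid compaction.

Three fitted models:

* ``baseline_linear`` — a constant baseline ``b`` up to a breakpoint
  ``t0``, then linear growth ``b + m (t - t0)``; the slope ``m`` is the
  junction assembly rate.  The breakpoint is profiled over the sample
  times (discrete exhaustive search) with a closed-form least-squares fit
  of ``(b, m)`` at each candidate.
* ``exp_decay`` — ``I(t) = I_inf + A exp(-(t - t_start)/tau)`` fitted from
  ``fit_start`` onward; ``tau`` is the disassembly time constant.  When the
  decay begins only after a lag (some genotypes hold their intensity for
  several minutes after chelation), ``fit_start`` is shifted accordingly.
* ``baseline_double_exp`` — a constant baseline up to ``t0`` followed by a
  fast + slow exponential approach to a plateau, fitted to roundness data
  up to ``t_max``; ``tau_fast`` is the reported formation time constant.

Exponential fits are initialisation-sensitive, so both nonlinear models use
multi-start initialisation over log-spaced time constants with best-RSS
selection (lmfit least squares underneath).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

from .errors import DegenerateDataError, InvalidParameterError

TAU_INIT_MULTIPLES = (1.0, 5.0, 20.0, 80.0)  # x sampling interval
MIN_TAU_RATIO = 1.05  # identifiability floor for tau_slow / tau_fast


@dataclass
class IntensityTrace:
    """A time-stamped scalar series with an optional event marker."""

    times: np.ndarray
    values: np.ndarray
    event_time: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise InvalidParameterError("times and values must be equal-length 1D")
        if not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("values must be finite")

    @property
    def n(self) -> int:
        return self.times.size


@dataclass
class FitResult:
    model: str
    params: dict[str, float] = field(default_factory=dict)
    rss: float = np.inf
    converged: bool = False
    message: str = ""

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "params": dict(self.params),
            "rss": self.rss,
            "converged": self.converged,
            "message": self.message,
        }


def normalize_to_baseline(trace: IntensityTrace, event_time: float | None = None) -> IntensityTrace:
    """Express the trace in percent of its pre-event mean."""
    event_time = trace.event_time if event_time is None else event_time
    if event_time is None:
        raise InvalidParameterError("an event time is required for normalisation")
    pre = trace.times <= event_time
    if pre.sum() < 2:
        raise InvalidParameterError("need at least 2 pre-event samples")
    mean = trace.values[pre].mean()
    if mean <= 0:
        raise DegenerateDataError("pre-event mean is not positive")
    return IntensityTrace(trace.times, 100.0 * trace.values / mean, event_time)


# ---------------------------------------------------------------------------
# Baseline + linear (assembly rate)
# ---------------------------------------------------------------------------

def fit_baseline_linear(
    trace: IntensityTrace, t0_candidates: np.ndarray | None = None
) -> FitResult:
    """Fit ``f(t) = b`` for ``t <= t0`` and ``b + m (t - t0)`` beyond.

    ``t0`` is profiled: for every candidate breakpoint (by default every
    sample time except the last two) the conditionally-linear pair
    ``(b, m)`` is solved in closed form and the lowest-RSS candidate wins.
    """
    t, y = trace.times, trace.values
    if t.size < 6:
        raise InvalidParameterError("need at least 6 samples")
    if t0_candidates is None:
        t0_candidates = t[:-2]
    best = FitResult(model="baseline_linear", message="no candidate improved fit")
    for t0 in np.asarray(t0_candidates, float):
        ramp = np.clip(t - t0, 0.0, None)
        A = np.stack([np.ones_like(t), ramp], axis=1)
        coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        if rank < 2:
            continue
        rss = float(np.sum((A @ coef - y) ** 2))
        if rss < best.rss - 1e-15:
            best = FitResult(
                model="baseline_linear",
                params={"baseline": float(coef[0]), "breakpoint": float(t0), "slope": float(coef[1])},
                rss=rss,
                converged=True,
            )
    return best


# ---------------------------------------------------------------------------
# Exponential decay (disassembly tau)
# ---------------------------------------------------------------------------

def fit_exp_decay(trace: IntensityTrace, fit_start: float | None = None) -> FitResult:
    """Fit ``I(t) = I_inf + A exp(-(t - fit_start)/tau)`` on ``t >= fit_start``.

    ``fit_start`` defaults to the trace's event time (the chelator
    addition).  Initial ``tau`` values are scanned over multiples of the
    sampling interval and the best-RSS solution kept.  A trace without a
    decaying component (flat, or monotonically increasing) is reported with
    ``converged=False``.
    """
    if fit_start is None:
        fit_start = trace.event_time if trace.event_time is not None else trace.times[0]
    sel = trace.times >= fit_start - 1e-9
    t = trace.times[sel] - fit_start
    y = trace.values[sel]
    if t.size < 4:
        raise InvalidParameterError("need at least 4 samples at t >= fit_start")
    dt = float(np.median(np.diff(t)))
    span = float(t[-1] - t[0])
    scale = float(np.std(y)) or 1.0

    def residual(params):
        return params["i_inf"] + params["amp"] * np.exp(-t / params["tau"]) - y

    best = None
    for mult in TAU_INIT_MULTIPLES:
        tau0 = min(mult * dt, 5 * span)
        p = Parameters()
        p.add("i_inf", value=float(y[-3:].mean()))
        p.add("amp", value=float(y[0] - y[-3:].mean()))
        p.add("tau", value=tau0, min=1e-3 * dt, max=50 * span)
        try:
            res = minimize(residual, p, method="leastsq")
        except Exception:
            continue
        rss = float(np.sum(res.residual**2))
        if best is None or rss < best[0]:
            best = (rss, res)
    if best is None:
        return FitResult(model="exp_decay", message="optimizer failed")
    rss, res = best
    amp = float(res.params["amp"].value)
    tau = float(res.params["tau"].value)
    result = FitResult(
        model="exp_decay",
        params={
            "i_inf": float(res.params["i_inf"].value),
            "amp": amp,
            "tau": tau,
            "fit_start": float(fit_start),
        },
        rss=rss,
        converged=True,
    )
    if amp <= 1e-6 * scale:
        result.converged = False
        result.message = "no decaying component (amplitude <= 0)"
    elif tau >= 45 * span:
        result.converged = False
        result.message = "tau unidentifiable (hit upper bound)"
    return result


# ---------------------------------------------------------------------------
# Baseline + double exponential (spheroid compaction)
# ---------------------------------------------------------------------------

def _double_exp_model(params, t, t0):
    r_inf = params["r_inf"]
    b = params["baseline"]
    frac = params["frac_fast"]
    tau_f = params["tau_fast"]
    tau_s = tau_f * params["tau_ratio"]
    amp = r_inf - b
    a_f = frac * amp
    a_s = amp - a_f
    dt = np.clip(t - t0, 0.0, None)
    rise = r_inf - a_f * np.exp(-dt / tau_f) - a_s * np.exp(-dt / tau_s)
    return np.where(t > t0, rise, b)


def fit_baseline_double_exp(
    trace: IntensityTrace,
    t_max: float | None = None,
    t0_candidates: np.ndarray | None = None,
) -> FitResult:
    """Fit a constant baseline followed by a fast + slow exponential rise.

    Only samples with ``t <= t_max`` enter the fit.  The breakpoint ``t0``
    is profiled over candidate sample times in the first half of the
    window; for each candidate the remaining five parameters are fitted
    with multi-start ``tau_fast`` initialisation.  Amplitude continuity at
    ``t0`` is built into the parametrisation.  Fits where the two time
    constants are within 5 % of each other are flagged unconverged
    (fast/slow decomposition unidentifiable).
    """
    sel = np.ones(trace.n, bool) if t_max is None else trace.times <= t_max + 1e-9
    t = trace.times[sel]
    y = trace.values[sel]
    if t.size < 10:
        raise InvalidParameterError("need at least 10 samples with t <= t_max")
    if t0_candidates is None:
        half = t[0] + 0.5 * (t[-1] - t[0])
        t0_candidates = t[(t >= t[0]) & (t <= half)][:-1]
    span = float(t[-1] - t[0])
    value_span = float(y.max() - y.min())
    scale = float(np.std(y)) or 1.0

    best = None
    for t0 in np.asarray(t0_candidates, float):
        pre = t <= t0
        b0 = float(y[pre].mean()) if pre.any() else float(y[0])
        for tau0 in (0.05 * span, 0.2 * span, 0.6 * span):
            p = Parameters()
            p.add("baseline", value=b0)
            p.add("r_inf", value=float(y[-3:].mean()))
            p.add("frac_fast", value=0.6, min=0.0, max=1.0)
            p.add("tau_fast", value=tau0, min=1e-4 * span, max=20 * span)
            p.add("tau_ratio", value=8.0, min=1.0, max=1e4)

            def residual(params):
                return _double_exp_model(params, t, t0) - y

            try:
                res = minimize(residual, p, method="leastsq")
            except Exception:
                continue
            rss = float(np.sum(res.residual**2))
            if best is None or rss < best[0]:
                best = (rss, res, float(t0))
    if best is None:
        return FitResult(model="baseline_double_exp", message="optimizer failed")
    rss, res, t0 = best
    pv = {k: float(v.value) for k, v in res.params.items()}
    tau_fast = pv["tau_fast"]
    tau_slow = tau_fast * pv["tau_ratio"]
    amp = pv["r_inf"] - pv["baseline"]
    result = FitResult(
        model="baseline_double_exp",
        params={
            "baseline": pv["baseline"],
            "breakpoint": t0,
            "r_inf": pv["r_inf"],
            "amp_fast": pv["frac_fast"] * amp,
            "amp_slow": (1 - pv["frac_fast"]) * amp,
            "tau_fast": tau_fast,
            "tau_slow": tau_slow,
        },
        rss=rss,
        converged=True,
    )
    if abs(amp) <= 1e-6 * scale or value_span <= 1e-9 * scale:
        result.converged = False
        result.message = "no rising component (flat trace)"
    elif tau_slow / tau_fast < MIN_TAU_RATIO:
        result.converged = False
        result.message = "tau_fast and tau_slow unidentifiable (ratio < 1.05)"
    return result
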