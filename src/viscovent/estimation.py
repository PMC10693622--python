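"""Inspiratory-pause analysis: landmarks, E1 drops, relaxation regression.

The analysis pipeline mirrors clinical inspiratory-pause mechanics:

1. :func:`segment_pause` locates the pause landmarks in one cycle —
   pause onset (t1), the instant flow reaches zero (t2), the peak pressure
   Ppeak, the pressure P1 at t2, and the plateau pressure P2. The
   decomposition Ppeak - P1 reflects airway resistance (Raw*Q) while
   P1 - P2 is the viscoelastic pressure drop, identified with the SLS
   modulus E1.
2. :func:`estimate_E1` averages per-replicate P1 - P2 drops, checks
   normality (D'Agostino-Pearson omnibus K^2) and runs a one-sample t-test
   against a hypothesised drop value.
3. :func:`fit_relaxation` fits the pause-window pressure with the SLS
   relaxation form P(t) = E0 + E1*exp(-E1*t/eta), with E1 held fixed at
   the value found in step 2, by nonlinear least squares over (E0, eta);
   a linearised log-regression variant is available for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .ventilator import PressureTrace

__all__ = [
    "NoPauseError",
    "PauseSegmentation",
    "E1Estimate",
    "RelaxationFit",
    "EstimationResult",
    "segment_pause",
    "segment_cycles",
    "estimate_E1",
    "fit_relaxation",
    "estimate_from_trace",
    "FLOW_EPSILON",
    "PLATEAU_FRACTION",
]

#: Zero-flow detection threshold, L/s.
FLOW_EPSILON = 1e-3
#: Fraction of the pause window averaged to read the plateau P2.
PLATEAU_FRACTION = 0.20


class NoPauseError(ValueError):
    """The trace contains no usable zero-flow inspiratory pause."""


@dataclass(frozen=True)
class PauseSegmentation:
    """Landmark set for one ventilatory cycle.

    Times are in trace-local seconds; ``pause_window`` is the
    ``(start, stop)`` sample index range (Python slice convention) of the
    zero-flow pause within the cycle.
    """

    t1: float
    t2: float
    Ppeak: float
    P1: float
    P2: float
    pause_window: tuple[int, int]
    degraded: bool = False

    @property
    def drop(self) -> float:
        """The viscoelastic pressure drop P1 - P2, cmH2O."""
        return self.P1 - self.P2

    @property
    def resistive_step(self) -> float:
        """The airway-resistance pressure step Ppeak - P1, cmH2O."""
        return self.Ppeak - self.P1


@dataclass(frozen=True)
class E1Estimate:
    mean: float
    sd: float
    n: int
    normality_p: float
    ttest_p: float
    null_value: float
    drops: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class RelaxationFit:
    E0_hat: float
    eta_hat: float
    E1_fixed: float
    R2: float
    residuals: np.ndarray = field(repr=False, default=None)
    method: str = "nls"

    @property
    def tau_hat(self) -> float:
        return self.eta_hat / self.E1_fixed


@dataclass(frozen=True)
class EstimationResult:
    """Full pipeline output for one condition."""

    e1: E1Estimate
    fit: RelaxationFit
    segmentations: tuple[PauseSegmentation, ...] = field(repr=False, default=())

    @property
    def E1_hat(self) -> float:
        return self.e1.mean

    @property
    def E0_hat(self) -> float:
        return self.fit.E0_hat

    @property
    def eta_hat(self) -> float:
        return self.fit.eta_hat

    @property
    def tau_hat(self) -> float:
        return self.fit.tau_hat


def segment_pause(
    trace: PressureTrace,
    cycle: int = 0,
    flow_epsilon: float = FLOW_EPSILON,
    plateau_fraction: float = PLATEAU_FRACTION,
    min_pause_s: float = 0.3,
) -> PauseSegmentation:
    """Extract the pause landmarks from one cycle of a trace.

    t2 is the first zero-flow sample after inspiratory flow; P1 the
    pressure there; P2 the mean pressure over the terminal
    ``plateau_fraction`` of the pause window (at least 5 samples, fewer —
    with a degraded-P2 warning — if the pause itself is shorter); Ppeak the
    maximum pressure in the cycle.
    """
    cyc = trace.cycle(cycle) if trace.n_cycles > 1 or cycle != 0 else trace
    flow = cyc.flow
    press = cyc.pressure
    time = cyc.time

    insp = np.flatnonzero(flow > flow_epsilon)
    if insp.size == 0:
        raise NoPauseError("no inspiratory flow found in cycle")
    last_insp = insp[-1]
    after = np.abs(flow[last_insp + 1 :]) < flow_epsilon
    if after.size == 0 or not after[0]:
        raise NoPauseError("flow never settles to zero after inspiration")
    start = last_insp + 1
    # Pause = run of zero-flow samples; ends at expiration (negative flow).
    nonzero = np.flatnonzero(~after)
    stop = start + (nonzero[0] if nonzero.size else after.size)

    duration = (stop - start - 1) / cyc.sampling_rate if stop > start else 0.0
    if stop - start < 2 or duration < min_pause_s:
        raise NoPauseError(
            f"zero-flow pause of {duration:.3f} s shorter than the "
            f"{min_pause_s} s minimum"
        )

    n_window = stop - start
    n_plateau = max(int(round(plateau_fraction * n_window)), 5)
    degraded = False
    if n_plateau > n_window:
        warnings.warn(
            "pause shorter than the plateau window; P2 degraded to the "
            "mean of the whole pause tail",
            stacklevel=2,
        )
        n_plateau = n_window
        degraded = True

    p2 = float(np.mean(press[stop - n_plateau : stop]))
    return PauseSegmentation(
        t1=float(time[last_insp]),
        t2=float(time[start]),
        Ppeak=float(press.max()),
        P1=float(press[start]),
        P2=p2,
        pause_window=(int(start), int(stop)),
        degraded=degraded,
    )


def segment_cycles(trace: PressureTrace, **kwargs) -> list[PauseSegmentation]:
    """Segment every cycle of a multi-cycle trace."""
    return [segment_pause(trace, cycle=i, **kwargs) for i in range(trace.n_cycles)]


def estimate_E1(
    drops,
    alpha: float = 0.05,
    null_value: float | None = None,
) -> E1Estimate:
    """Average per-replicate P1 - P2 drops with normality and t tests.

    The sample mean is the E1 estimate. Normality is assessed with the
    D'Agostino-Pearson omnibus K^2 test (requires n >= 8); the one-sample
    t-test compares the drops against ``null_value`` (default: the mean
    rounded to 2 decimals, i.e. the reported point estimate).
    """
    drops = np.asarray(drops, dtype=float)
    n = drops.size
    if n < 8:
        raise ValueError(
            f"D'Agostino-Pearson normality test needs n >= 8 drops, got {n}"
        )
    mean = float(drops.mean())
    sd = float(drops.std(ddof=1))
    if np.ptp(drops) == 0:
        warnings.warn("zero-variance drops: t-test undefined", stacklevel=2)
        return E1Estimate(
            mean=mean, sd=0.0, n=n, normality_p=float("nan"),
            ttest_p=float("nan"), null_value=float(mean), drops=drops,
        )
    _, normality_p = stats.normaltest(drops)
    if null_value is None:
        null_value = round(mean, 2)
    if sd == 0:  # pragma: no cover - degenerate, caught by ptp above
        warnings.warn("zero-variance drops: t-test undefined", stacklevel=2)
        ttest_p = float("nan")
    else:
        _, ttest_p = stats.ttest_1samp(drops, null_value)
    return E1Estimate(
        mean=mean,
        sd=sd,
        n=n,
        normality_p=float(normality_p),
        ttest_p=float(ttest_p),
        null_value=float(null_value),
        drops=drops,
    )


def _r2(y, yhat):
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def fit_relaxation(
    t,
    pressure,
    E1_fixed: float,
    method: str = "nls",
) -> RelaxationFit:
    """Fit P(t) = E0 + E1_fixed * exp(-E1_fixed * t / eta) over (E0, eta).

    ``t`` must start at 0 (the zero-flow instant t2). The default method is
    nonlinear least squares (initialised at E0 = last-sample pressure,
    eta = E1_fixed * quarter of the window duration). ``method="log-linear"``
    instead fixes E0 at the plateau-window mean and regresses
    log(P - E0) on t — the classical spreadsheet linearisation, kept for
    comparison.
    """
    t = np.asarray(t, dtype=float)
    p = np.asarray(pressure, dtype=float)
    if t.size != p.size:
        raise ValueError("t and pressure must have equal length")
    if t.size < 10:
        raise ValueError(f"need >= 10 samples to fit, got {t.size}")
    if not E1_fixed > 0:
        raise ValueError("E1_fixed must be positive")

    if np.ptp(p) == 0:
        warnings.warn(
            "constant pressure segment: no decay to fit; eta at lower bound",
            stacklevel=2,
        )
        return RelaxationFit(
            E0_hat=float(p[0]),
            eta_hat=0.0,
            E1_fixed=E1_fixed,
            R2=float("nan"),
            residuals=np.zeros_like(p),
            method=method,
        )

    if method == "nls":
        span = t[-1] - t[0]

        def model(tt, e0, eta):
            return e0 + E1_fixed * np.exp(-E1_fixed * tt / eta)

        p0 = (float(p[-1]), E1_fixed * span / 4.0)
        try:
            popt, _ = optimize.curve_fit(
                model,
                t,
                p,
                p0=p0,
                bounds=((0.0, 1e-9), (np.inf, np.inf)),
                maxfev=20000,
            )
        except RuntimeError as exc:
            raise RuntimeError(
                f"relaxation fit did not converge: {exc}; "
                f"residual trace at p0: {p - model(t, *p0)}"
            ) from exc
        e0_hat, eta_hat = float(popt[0]), float(popt[1])
        yhat = model(t, *popt)
    elif method == "log-linear":
        n_pl = max(int(round(PLATEAU_FRACTION * t.size)), 5)
        e0_hat = float(p[-n_pl:].mean())
        excess = p - e0_hat
        mask = excess > max(1e-9, 0.02 * E1_fixed)
        if mask.sum() < 3:
            raise RuntimeError("too few samples above plateau for log fit")
        slope, intercept = np.polyfit(t[mask], np.log(excess[mask]), 1)
        if slope >= 0:
            raise RuntimeError("non-decaying segment in log-linear fit")
        eta_hat = float(-E1_fixed / slope)
        yhat = e0_hat + np.exp(intercept) * np.exp(slope * t)
    else:
        raise ValueError(f"unknown fit method {method!r}")

    return RelaxationFit(
        E0_hat=e0_hat,
        eta_hat=eta_hat,
        E1_fixed=E1_fixed,
        R2=_r2(p, yhat),
        residuals=p - yhat,
        method=method,
    )


def estimate_from_trace(
    trace: PressureTrace,
    E1_fixed: float | None = None,
    null_value: float | None = None,
    fit_cycle: int = 0,
    method: str = "nls",
) -> EstimationResult:
    """Run the full pipeline on a multi-cycle trace.

    Segments every cycle, estimates E1 from the per-cycle drops (when the
    trace has >= 8 cycles; otherwise the drop mean is used directly without
    the tests), then fits the relaxation on ``fit_cycle``'s pause window
    with E1 fixed (default: the estimated mean drop).
    """
    segs = segment_cycles(trace)
    drops = np.array([s.drop for s in segs])
    if drops.size >= 8:
        e1 = estimate_E1(drops, null_value=null_value)
    else:
        e1 = E1Estimate(
            mean=float(drops.mean()),
            sd=float(drops.std(ddof=1)) if drops.size > 1 else 0.0,
            n=drops.size,
            normality_p=float("nan"),
            ttest_p=float("nan"),
            null_value=float("nan"),
            drops=drops,
        )
    e1_fix = E1_fixed if E1_fixed is not None else e1.mean
    seg = segs[fit_cycle]
    cyc = trace.cycle(fit_cycle)
    lo, hi = seg.pause_window
    t = cyc.time[lo:hi] - cyc.time[lo]
    fit = fit_relaxation(t, cyc.pressure[lo:hi], e1_fix, method=method)
    return EstimationResult(e1=e1, fit=fit, segmentations=tuple(segs))
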