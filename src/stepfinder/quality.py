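"""Counter fitting and the S-curve ("step fit spectrum").

The quality of a step fit with ``n`` breakpoints is judged against a
deliberately mis-placed *counter fit* with the same number of degrees of
freedom: within every plateau of the existing fit the next-best partition
point is located, the existing breakpoints are then discarded, and a new step
function is built on those positions alone.  Counter breakpoints therefore
interleave the fitted ones.  For a trace that genuinely contains steps, the
counter fit straddles every real step and its residual variance is much larger
than the fit's; for noise or smooth drift the two are comparable.

The S-curve

    S(n) = sigma^2_counter(n) / sigma^2_fit(n),   n = 1..max_steps

(whole-trace mean squared residuals) peaks sharply at the true number of
steps.  At the peak, with steps of size Delta over residual noise sigma_R, the
counter fit sits ~Delta/2 from every plateau, so

    S_max ~= 1 + P,   P = Delta^2 / (4 sigma_R^2).

Analytic approximations of the whole curve as a function of the relative fit
fraction f = n / n_s are provided for both the variance and the SAD error
signal; see :func:`analytic_s_curve_var`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    GreedyEngine,
    ParameterError,
    StepFit,
    Trace,
    best_split,
    best_split_sad,
    fit_from_breakpoints,
    segment_stats,
)

__all__ = [
    "SCurve",
    "AnalyticSCurveParams",
    "counter_fit",
    "s_curve",
    "pick_optimum",
    "analytic_s_curve_var",
    "analytic_s_curve_sad",
]


@dataclass(frozen=True)
class SCurve:
    """Per-iteration fit/counter-fit variances and their ratio S.

    ``s_values[k]`` corresponds to iteration ``iterations[k]`` (1-based count
    of inserted breakpoints).
    """

    iterations: np.ndarray
    s_values: np.ndarray
    fit_variance: np.ndarray
    counter_variance: np.ndarray

    @property
    def s_max(self) -> float:
        return float(np.max(self.s_values))

    @property
    def n_at_s_max(self) -> int:
        """Iteration attaining the global maximum (first occurrence on ties)."""
        return int(self.iterations[int(np.argmax(self.s_values))])

    def indicates_steps(self, threshold: float) -> bool:
        """True when the peak clears the acceptance margin: S_max >= 1 + threshold."""
        return self.s_max >= 1.0 + threshold

    def to_frame(self) -> pd.DataFrame:
        """Two-column table (iteration, S) plus the two variances, for export."""
        return pd.DataFrame(
            {
                "iteration": self.iterations,
                "S": self.s_values,
                "fit_variance": self.fit_variance,
                "counter_variance": self.counter_variance,
            }
        )


def counter_fit(trace: Trace, fit: StepFit, metric: str = "variance") -> StepFit:
    """Worst-case companion fit of ``fit``: same budget, interleaved positions.

    For every plateau of ``fit`` with at least two samples the next partition
    location is computed; the counter fit's breakpoints are exactly those
    locations, the existing ones being discarded.  Length-1 plateaus
    contribute no counter breakpoint.
    """
    splitter = best_split if metric == "variance" else best_split_sad
    edges = fit.plateau_edges()
    bps = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a >= 2:
            res = splitter(trace, segment_stats(trace, int(a), int(b)))
            bps.append(res.split_index)
    return fit_from_breakpoints(trace, sorted(bps))


def s_curve(
    trace: Trace,
    max_steps: int,
    metric: str = "variance",
    return_fit: bool = False,
):
    """Build the step fit spectrum S(n) for n = 1..max_steps.

    Replays the greedy insertion sequence; after each insertion records the
    whole-trace residual error of the fit and of its counter fit (mean squared
    residual for ``metric="variance"``, mean absolute deviation about plateau
    medians for ``metric="sad"``) and their ratio S.  The counter error is
    maintained incrementally — each insertion only touches the counter
    plateaus adjacent to the inserted breakpoint — so the whole spectrum costs
    little more than the fit itself.

    A constant trace yields a flat curve of S = 1 (the "no steps" signature).

    When ``return_fit`` is true, also returns the full-depth :class:`StepFit`
    whose ``insertion_order`` allows truncation to any point of the curve.
    """
    if max_steps < 1:
        raise ParameterError("max_steps must be >= 1")
    engine = GreedyEngine(trace, metric=metric)
    n = trace.n_samples
    fit_err, counter_err = [], []
    while len(fit_err) < max_steps:
        if engine.step() is None:
            break
        fit_err.append(engine.fit_error)
        counter_err.append(engine.counter_error)
    fit_err = np.asarray(fit_err)
    counter_err = np.asarray(counter_err)
    # Guard exact fits: once the fit error underflows to ~0 the ratio is
    # ill-defined; a vanishing counter error too means a degenerate
    # (step-free, noise-free) stretch and S is pinned at 1.
    tiny = 1e-12 * engine.initial_error / n + 1e-300
    s = np.where(
        (fit_err <= tiny) & (counter_err <= tiny),
        1.0,
        counter_err / np.maximum(fit_err, tiny),
    )
    curve = SCurve(
        iterations=np.arange(1, fit_err.size + 1),
        s_values=s,
        fit_variance=fit_err / n,
        counter_variance=counter_err / n,
    )
    if not return_fit:
        return curve
    full = fit_from_breakpoints(
        trace, sorted(engine.breakpoints), tuple(engine.insertion_order)
    )
    return curve, full


def pick_optimum(curve: SCurve, manual_n: int | None = None) -> int:
    """Iteration count to keep: the S-curve's global maximum.

    ``manual_n`` overrides the automatic choice (exploration of local maxima
    at other step-size scales); it is clipped to the available range.
    """
    if curve.iterations.size == 0:
        raise ParameterError("empty S-curve")
    if manual_n is not None:
        if manual_n < 1:
            raise ParameterError("manual iteration count must be >= 1")
        return min(manual_n, int(curve.iterations[-1]))
    return curve.n_at_s_max


@dataclass(frozen=True)
class AnalyticSCurveParams:
    """Parameters of the closed-form S-curve approximations.

    ``delta``           step size (a.u.)
    ``sigma_r``         residual noise SD (a.u.), variance version
    ``omega``           residual noise scale for the SAD version: the mean
                        absolute deviation of the noise (a.u.)
    ``n_s``             true number of steps
    ``plateau_length``  average plateau length at f = 1 (samples, N_w)
    """

    delta: float
    sigma_r: float
    n_s: int
    plateau_length: float
    omega: float | None = None

    @property
    def p(self) -> float:
        """Peak counter-to-fit variance excess: P = Delta^2 / (4 sigma_R^2)."""
        return self.delta**2 / (4.0 * self.sigma_r**2)

    @property
    def p_omega(self) -> float:
        """SAD counterpart: P_omega = Delta / (2 omega)."""
        if self.omega is None:
            raise ParameterError("omega is required for the SAD S-curve")
        return self.delta / (2.0 * self.omega)


def _analytic_curve(f, p: float, plateau_length: float, n_f_weight: float):
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ParameterError("relative fit fraction f must be positive")
    # Under-fitting branch (f < 1): rational rise to the peak, built to give
    # S(1) = 1 + p and S ~ 1 for p -> 0.
    under = (p * (2.0 + f) / 3.0 + 1.0) / (p * (1.0 - f) / 2.0 + 1.0)
    # Over-fitting branch (f > 1): spurious breakpoints dilute the counter
    # fit's excess; the average plateau shrinks as N_f = N_w / f.
    with np.errstate(divide="ignore"):
        n_f = plateau_length / f
        over = 1.0 + p / (f + n_f_weight * n_f * (1.0 - 1.0 / f))
    s = np.where(f < 1.0, under, over)
    return s if s.ndim else float(s)


def analytic_s_curve_var(params: AnalyticSCurveParams, f):
    """Closed-form approximation of the variance S-curve at fit fraction(s) f.

    The two branches are continuous at f = 1 where S = 1 + P, and S -> 1 as
    f -> infinity; with P = 0 (no steps) the curve is flat at 1.  The printed
    source forms of these expressions are not typographically recoverable, so
    the implemented branches are the simplest rational forms satisfying those
    constraints (see the methods note).
    """
    return _analytic_curve(f, params.p, params.plateau_length, 4.0)


def analytic_s_curve_sad(params: AnalyticSCurveParams, f):
    """SAD analogue of :func:`analytic_s_curve_var`, peaking at S = 1 + P_omega."""
    return _analytic_curve(f, params.p_omega, params.plateau_length, 2.0)
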