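"""The full automated driver: dual-pass step fitting with acceptance gating.

Round 1 fits the trace greedily, builds the S-curve and keeps the fit
truncated at the curve's global maximum -- the most prominent step scale.
When steps of widely different sizes coexist, the S-curve of the raw trace
peaks at the large-step scale only; the small steps survive in the residual.
Round 2 therefore refits the residual (data minus round-1 fit) the same way.
A round is accepted only when its S-curve peak clears the acceptance margin,
S_max >= 1 + tau: a flat spectrum (S ~ 1) is the signature of a step-free
signal and contributes no breakpoints.  The final fit merges the breakpoints
of the accepted rounds and recomputes plateau means on the original data.
Two rounds suffice in practice; no third round is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bootstrap import BootstrapResult, bootstrap_cis
from .core import (
    ParameterError,
    StepFit,
    Trace,
    default_max_steps,
    fit_from_breakpoints,
)
from .quality import SCurve, pick_optimum, s_curve

__all__ = ["Config", "FinalResult", "run_round", "autostepfinder", "build_step_table"]

logger = logging.getLogger(__name__)

#: Columns of the step table, in output order.
STEP_TABLE_COLUMNS = [
    "step_index",
    "step_time",
    "level_before",
    "level_after",
    "step_size",
    "dwell_before_samples",
    "dwell_after_samples",
    "dwell_before_time",
    "dwell_after_time",
    "ci95_size_low",
    "ci95_size_high",
    "ci95_dwell_low",
    "ci95_dwell_high",
]


@dataclass(frozen=True)
class Config:
    """Run configuration of the dual-pass fitter.

    ``max_steps``             iteration budget per round; ``None`` picks
                              min(N/10, 10 000), deep enough to overshoot the
                              optimum.
    ``acceptance_threshold``  tau: a round is kept only if S_max >= 1 + tau.
    ``n_bootstrap``           bootstrap replicates for the CI columns
                              (0 disables them).
    ``manual_n_round1/2``     optional manual iteration counts overriding the
                              S-curve maximum (local-peak exploration).
    ``error_metric``          "variance" (default) or "sad".
    ``seed``                  seed for the bootstrap resampler.
    """

    max_steps: int | None = None
    acceptance_threshold: float = 0.6
    n_bootstrap: int = 0
    manual_n_round1: int | None = None
    manual_n_round2: int | None = None
    error_metric: str = "variance"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.acceptance_threshold < 0:
            raise ParameterError("acceptance_threshold must be >= 0")
        if self.n_bootstrap < 0:
            raise ParameterError("n_bootstrap must be >= 0")
        if self.error_metric not in ("variance", "sad"):
            raise ParameterError(f"unknown error metric {self.error_metric!r}")

    def resolve_max_steps(self, n_samples: int) -> int:
        if self.max_steps is not None:
            if self.max_steps < 1:
                raise ParameterError("max_steps must be >= 1")
            return self.max_steps
        return default_max_steps(n_samples)


@dataclass(frozen=True)
class FinalResult:
    """Outcome of a dual-pass run.

    ``fit`` is the merged final fit (zero steps when nothing was accepted);
    ``round2`` is ``None`` whenever the second round was rejected or never
    run.  ``bootstrap`` carries the raw CI arrays when bootstrapping was on.
    """

    fit: StepFit
    round1: tuple[StepFit, SCurve]
    round2: tuple[StepFit, SCurve] | None
    step_table: pd.DataFrame
    accepted_rounds: int
    bootstrap: BootstrapResult | None = None


def run_round(trace: Trace, config: Config,
              manual_n: int | None = None) -> tuple[StepFit, SCurve, bool]:
    """One fitting round: S-curve, optimum pick, truncation, acceptance test.

    Returns the fit truncated to the first n* greedy insertions, the S-curve,
    and whether the round clears S_max >= 1 + tau.
    """
    max_steps = config.resolve_max_steps(trace.n_samples)
    curve, full = s_curve(trace, max_steps, metric=config.error_metric,
                          return_fit=True)
    n_opt = pick_optimum(curve, manual_n)
    kept = sorted(bp for _, bp, _ in full.insertion_order[:n_opt])
    fit = fit_from_breakpoints(trace, kept, full.insertion_order[:n_opt])
    accepted = curve.indicates_steps(config.acceptance_threshold)
    return fit, curve, accepted


def autostepfinder(trace: Trace, config: Config | None = None) -> FinalResult:
    """Run the full dual-pass procedure on one trace.

    Round 1 fits the raw data; if accepted, its fit is subtracted and round 2
    fits the residual.  Breakpoints of accepted rounds are merged (sorted
    union) and plateau levels recomputed on the original trace.  Traces
    shorter than 3 samples are refused.
    """
    if config is None:
        config = Config()
    if trace.n_samples < 3:
        raise ParameterError("trace too short for step fitting (need >= 3 samples)")

    fit1, curve1, accepted1 = run_round(trace, config, config.manual_n_round1)
    logger.info(
        "round 1: S_max=%.3f at n=%d, %s",
        curve1.s_max, curve1.n_at_s_max, "accepted" if accepted1 else "rejected",
    )

    round2: tuple[StepFit, SCurve] | None = None
    breakpoints: set[int] = set()
    accepted_rounds = 0
    if accepted1:
        accepted_rounds = 1
        breakpoints.update(fit1.breakpoints.tolist())
        residual = Trace(trace.signal - fit1.fitted_signal(), trace.time)
        fit2, curve2, accepted2 = run_round(residual, config, config.manual_n_round2)
        logger.info(
            "round 2: S_max=%.3f at n=%d, %s",
            curve2.s_max, curve2.n_at_s_max, "accepted" if accepted2 else "rejected",
        )
        if accepted2:
            accepted_rounds = 2
            round2 = (fit2, curve2)
            breakpoints.update(fit2.breakpoints.tolist())

    merged = fit_from_breakpoints(trace, sorted(breakpoints))
    boot = None
    if config.n_bootstrap > 0 and merged.n_steps > 0:
        boot = bootstrap_cis(trace, merged, config.n_bootstrap, config.seed)
    table = build_step_table(trace, merged, boot)
    return FinalResult(
        fit=merged,
        round1=(fit1, curve1),
        round2=round2,
        step_table=table,
        accepted_rounds=accepted_rounds,
        bootstrap=boot,
    )


def build_step_table(trace: Trace, fit: StepFit,
                     bootstrap: BootstrapResult | None = None) -> pd.DataFrame:
    """One row per fitted step: location, levels, size, dwells and 95% CIs.

    Dwells are reported both in samples and in the trace's time units
    (samples times the sample interval); ``step_time`` is the time stamp of
    the first sample of the new plateau.  CI columns are NaN without a
    bootstrap result.
    """
    if fit.n_steps == 0:
        return pd.DataFrame(columns=STEP_TABLE_COLUMNS)
    times = trace.sample_times()
    dt = trace.dt
    dwells = fit.dwell_samples()
    table = pd.DataFrame(
        {
            "step_index": fit.breakpoints,
            "step_time": times[fit.breakpoints],
            "level_before": fit.levels[:-1],
            "level_after": fit.levels[1:],
            "step_size": fit.step_sizes(),
            "dwell_before_samples": dwells[:-1],
            "dwell_after_samples": dwells[1:],
            "dwell_before_time": dwells[:-1] * dt,
            "dwell_after_time": dwells[1:] * dt,
        }
    )
    if bootstrap is not None:
        table["ci95_size_low"] = bootstrap.ci_size[:, 0]
        table["ci95_size_high"] = bootstrap.ci_size[:, 1]
        table["ci95_dwell_low"] = bootstrap.ci_dwell[:, 0]
        table["ci95_dwell_high"] = bootstrap.ci_dwell[:, 1]
    else:
        for col in STEP_TABLE_COLUMNS[-4:]:
            table[col] = np.nan
    return table[STEP_TABLE_COLUMNS]
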