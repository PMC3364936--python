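"""Free-energy estimation from per-window alchemical samples.

An alchemical transformation (e.g. decoupling an anesthetic from its
environment) is split into windows along a coupling parameter lambda.
In each window ``[lambda_low, lambda_high]`` two ensembles are sampled
and the potential-energy difference ``dU = U(lambda_high) - U(lambda_low)``
is recorded:

* ``forward_du`` -- dU evaluated on configurations from the
  ``lambda_low`` ensemble (forward work samples);
* ``backward_du`` -- dU evaluated on configurations from the
  ``lambda_high`` ensemble (so the reverse work is ``-backward_du``).

Both directions therefore estimate the *same* window free energy
``dG = G(lambda_high) - G(lambda_low)``; the Bennett acceptance ratio
(BAR) combines them optimally.  Window estimates are summed along the
schedule, and independently run decoupling/recoupling stages are merged
with the half-difference error convention used when each stage is run
once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .exceptions import ConvergenceError, DomainError, ValidationError
from .thermo import ThermoContext

_GRID_TOL = 1e-9


@dataclass(frozen=True)
class LambdaSchedule:
    """Ordered grid of coupling-parameter values on [0, 1].

    The grid is fine (default step 0.025) inside ``fine_region`` and
    coarse (default 0.05) outside; the default fine region [0, 0.25]
    yields 25 windows per stage, matching one 1-ns window per ns of a
    25-ns decoupling or recoupling stage.
    """

    values: tuple
    fine_region: Optional[tuple] = None
    fine_step: float = 0.025
    coarse_step: float = 0.05

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size < 2 or abs(v[0]) > _GRID_TOL or abs(v[-1] - 1.0) > _GRID_TOL:
            raise ValidationError("schedule must start at 0 and end at 1")
        if np.any(np.diff(v) <= 0):
            raise ValidationError("schedule values must be strictly increasing")

    @property
    def n_windows(self) -> int:
        return len(self.values) - 1

    def windows(self) -> list:
        """Consecutive (lambda_low, lambda_high) pairs."""
        return list(zip(self.values[:-1], self.values[1:]))


def make_lambda_schedule(
    fine_region: Optional[Sequence[float]] = (0.0, 0.25),
    fine_step: float = 0.025,
    coarse_step: float = 0.05,
) -> LambdaSchedule:
    """Build a lambda grid with a finely spaced sub-interval.

    Parameters
    ----------
    fine_region : (float, float) or None
        Closed sub-interval of [0, 1] sampled with ``fine_step``; the
        rest of [0, 1] uses ``coarse_step``.  ``None`` or a zero-length
        interval gives a uniform coarse grid.  Steps must divide the
        segment lengths to 1e-9.
    """
    if fine_region is not None:
        lo, hi = float(fine_region[0]), float(fine_region[1])
        if lo == hi:
            fine_region = None
        elif not (0.0 <= lo < hi <= 1.0):
            raise ValidationError(f"fine_region must lie within [0, 1], got {fine_region}")
    if fine_region is None:
        segments = [(0.0, 1.0, coarse_step)]
    else:
        lo, hi = float(fine_region[0]), float(fine_region[1])
        segments = [(0.0, lo, coarse_step), (lo, hi, fine_step), (hi, 1.0, coarse_step)]
        segments = [s for s in segments if s[1] - s[0] > _GRID_TOL]

    grid = [0.0]
    for start, stop, step in segments:
        if step <= 0:
            raise ValidationError("step sizes must be positive")
        n = (stop - start) / step
        if abs(n - round(n)) > _GRID_TOL / step:
            raise ValidationError(
                f"step {step} does not divide segment [{start}, {stop}] evenly"
            )
        n = int(round(n))
        grid.extend(start + step * (i + 1) for i in range(n))
    grid[-1] = 1.0
    return LambdaSchedule(
        values=tuple(grid),
        fine_region=tuple(fine_region) if fine_region is not None else None,
        fine_step=fine_step,
        coarse_step=coarse_step,
    )


@dataclass
class WindowSamples:
    """Energy-difference samples for one lambda window.

    ``forward_du`` and ``backward_du`` both store
    ``dU = U(lambda_high) - U(lambda_low)`` in kcal/mol, sampled in the
    low- and high-lambda ensembles respectively.
    """

    lambda_low: float
    lambda_high: float
    forward_du: np.ndarray = field(default_factory=lambda: np.empty(0))
    backward_du: np.ndarray = field(default_factory=lambda: np.empty(0))
    direction_label: str = "decoupling"

    def __post_init__(self) -> None:
        self.forward_du = np.asarray(self.forward_du, dtype=float)
        self.backward_du = np.asarray(self.backward_du, dtype=float)
        if not self.lambda_low < self.lambda_high:
            raise ValidationError("require lambda_low < lambda_high")
        if self.forward_du.size == 0 and self.backward_du.size == 0:
            raise ValidationError("at least one direction must carry samples")

    def reversed(self) -> "WindowSamples":
        """The same window viewed as the reverse transformation.

        Forward samples of the reversed window are the negated backward
        samples of this one (and vice versa); the BAR estimate of the
        reversed window is the negative of the original.
        """
        return WindowSamples(
            lambda_low=self.lambda_low,
            lambda_high=self.lambda_high,
            forward_du=-self.backward_du,
            backward_du=-self.forward_du,
            direction_label=self.direction_label,
        )


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """A free-energy difference with its standard error (kcal/mol)."""

    delta_g: float
    stderr: float
    method: str
    n_windows: int = 1
    lambda_low: Optional[float] = None
    lambda_high: Optional[float] = None
    warnings: tuple = ()

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValidationError("stderr must be >= 0")


def _exp_average(log_weights_arg: np.ndarray, kt: float) -> tuple:
    """-kT ln <exp(arg)> with a delta-method stderr; arg = +-dU/kT."""
    n = log_weights_arg.size
    shift = np.max(log_weights_arg)
    w = np.exp(log_weights_arg - shift)
    mean = w.mean()
    log_mean = shift + math.log(mean)
    if n > 1:
        stderr = kt * w.std(ddof=1) / (mean * math.sqrt(n))
    else:
        stderr = 0.0
    return log_mean, stderr


def exp_estimator(
    samples: WindowSamples,
    direction: str = "forward",
    ctx: ThermoContext = ThermoContext(),
) -> FreeEnergyEstimate:
    """One-directional exponential (Zwanzig) estimator for a window.

    Forward: ``dG = -kT ln <exp(-dU/kT)>`` over the low-lambda samples.
    Backward: ``dG = +kT ln <exp(+dU/kT)>`` over the high-lambda
    samples, i.e. the reverse perturbation mapped back onto the forward
    free energy so that both directions estimate the same quantity.
    """
    kt = ctx.kt
    if direction == "forward":
        du = samples.forward_du
        if du.size == 0:
            raise ValidationError("no forward samples")
        log_mean, stderr = _exp_average(-du / kt, kt)
        dg = -kt * log_mean
    elif direction == "backward":
        du = samples.backward_du
        if du.size == 0:
            raise ValidationError("no backward samples")
        log_mean, stderr = _exp_average(du / kt, kt)
        dg = kt * log_mean
    else:
        raise ValidationError(f"direction must be 'forward' or 'backward', got {direction!r}")
    return FreeEnergyEstimate(
        delta_g=dg,
        stderr=stderr,
        method="exp",
        lambda_low=samples.lambda_low,
        lambda_high=samples.lambda_high,
    )


def _log_sum_fermi(x: np.ndarray) -> float:
    # log sum_i 1/(1+exp(x_i)), numerically stable
    return logsumexp(-np.logaddexp(0.0, x))


def bar_estimator(
    samples: WindowSamples,
    ctx: ThermoContext = ThermoContext(),
    tol: float = 1e-8,
    max_iter: int = 500,
) -> FreeEnergyEstimate:
    """Bennett acceptance ratio estimate for one window.

    Solves the implicit acceptance-ratio equation on its log-ratio form
    by bisection (start bracket [-50, +50] kcal/mol, expanded if
    needed), to ``tol`` kcal/mol.  The standard error is the standard
    BAR asymptotic variance evaluated at the solution.  Windows whose
    forward and backward sample ranges do not overlap at all are flagged
    with a ``"poor_overlap"`` warning on the returned estimate.
    """
    if samples.forward_du.size == 0 or samples.backward_du.size == 0:
        raise ValidationError("BAR requires samples in both directions")
    kt = ctx.kt
    u_f = samples.forward_du / kt          # reduced forward work
    u_r = -samples.backward_du / kt        # reduced reverse work
    n_f, n_r = u_f.size, u_r.size
    m = math.log(n_f / n_r)

    def g(c: float) -> float:
        # root of g gives the self-consistent BAR solution c = dG/kT
        return _log_sum_fermi(m + u_f - c) - _log_sum_fermi(-m + u_r + c)

    lo, hi = -50.0 / kt, 50.0 / kt
    g_lo, g_hi = g(lo), g(hi)
    expansions = 0
    while g_lo * g_hi > 0:
        expansions += 1
        if expansions > 10:
            raise ConvergenceError(
                "BAR bracket expansion failed", bracket=(lo * kt, hi * kt)
            )
        lo, hi = lo * 2, hi * 2
        g_lo, g_hi = g(lo), g(hi)

    c_tol = tol / kt
    n_iter = 0
    while hi - lo > c_tol:
        n_iter += 1
        if n_iter > max_iter:
            raise ConvergenceError(
                f"BAR bisection did not reach tol={tol} in {max_iter} iterations",
                bracket=(lo * kt, hi * kt),
            )
        mid = 0.5 * (lo + hi)
        if g(lo) * g(mid) <= 0:
            hi = mid
        else:
            lo = mid
    c = 0.5 * (lo + hi)

    # Standard BAR asymptotic variance (delta method on the two Fermi
    # averages, evaluated at the self-consistent solution).
    f_f = 1.0 / (1.0 + np.exp(m + u_f - c))
    f_r = 1.0 / (1.0 + np.exp(-m + u_r + c))
    var = ((f_f**2).mean() / f_f.mean() ** 2 - 1.0) / n_f
    var += ((f_r**2).mean() / f_r.mean() ** 2 - 1.0) / n_r
    stderr = kt * math.sqrt(max(var, 0.0))

    warnings = ()
    fwd, bwd = samples.forward_du, samples.backward_du
    if fwd.min() > bwd.max() or bwd.min() > fwd.max():
        warnings = ("poor_overlap",)

    return FreeEnergyEstimate(
        delta_g=c * kt,
        stderr=stderr,
        method="bar",
        lambda_low=samples.lambda_low,
        lambda_high=samples.lambda_high,
        warnings=warnings,
    )


def combine_windows(per_window: Sequence[FreeEnergyEstimate]) -> FreeEnergyEstimate:
    """Sum contiguous window estimates along one schedule.

    ``dG = sum dG_i``; ``stderr = sqrt(sum stderr_i^2)`` (windows are
    sampled independently).  If the estimates carry lambda bounds they
    must tile an interval without gaps or overlaps.
    """
    estimates = list(per_window)
    if not estimates:
        raise ValidationError("no window estimates to combine")
    has_lambda = [e.lambda_low is not None and e.lambda_high is not None for e in estimates]
    lo = hi = None
    if all(has_lambda):
        estimates.sort(key=lambda e: e.lambda_low)
        for a, b in zip(estimates[:-1], estimates[1:]):
            if abs(a.lambda_high - b.lambda_low) > _GRID_TOL:
                kind = "gap" if b.lambda_low > a.lambda_high else "overlap"
                raise ValidationError(
                    f"{kind} in lambda coverage between {a.lambda_high} and {b.lambda_low}"
                )
        lo, hi = estimates[0].lambda_low, estimates[-1].lambda_high
    elif any(has_lambda):
        raise ValidationError("either all or none of the estimates may carry lambda bounds")
    dg = sum(e.delta_g for e in estimates)
    stderr = math.sqrt(sum(e.stderr**2 for e in estimates))
    warnings = tuple(sorted({w for e in estimates for w in e.warnings}))
    method = estimates[0].method if len({e.method for e in estimates}) == 1 else "mixed"
    return FreeEnergyEstimate(
        delta_g=dg,
        stderr=stderr,
        method=method,
        n_windows=sum(e.n_windows for e in estimates),
        lambda_low=lo,
        lambda_high=hi,
        warnings=warnings,
    )


def bidirectional_combine(
    decoupling: FreeEnergyEstimate, recoupling: FreeEnergyEstimate
) -> FreeEnergyEstimate:
    """Merge independently run decoupling and recoupling stages.

    Both estimates must already be oriented in the binding direction.
    The combined value is their mean; with a single run per stage, the
    standard error is taken as half the absolute difference between the
    two stages.
    """
    dg = 0.5 * (decoupling.delta_g + recoupling.delta_g)
    stderr = 0.5 * abs(decoupling.delta_g - recoupling.delta_g)
    return FreeEnergyEstimate(
        delta_g=dg,
        stderr=stderr,
        method=f"bidirectional({decoupling.method})",
        n_windows=max(decoupling.n_windows, recoupling.n_windows),
        warnings=tuple(sorted(set(decoupling.warnings) | set(recoupling.warnings))),
    )


def pool_runs(runs: Iterable[WindowSamples]) -> WindowSamples:
    """Concatenate samples of repeated runs of the same window."""
    runs = list(runs)
    if not runs:
        raise ValidationError("no runs to pool")
    first = runs[0]
    for r in runs[1:]:
        if (
            abs(r.lambda_low - first.lambda_low) > _GRID_TOL
            or abs(r.lambda_high - first.lambda_high) > _GRID_TOL
        ):
            raise ValidationError("pooled runs must share the same lambda window")
    return replace(
        first,
        forward_du=np.concatenate([r.forward_du for r in runs]),
        backward_du=np.concatenate([r.backward_du for r in runs]),
    )


def estimate_stage(
    windows: Sequence[WindowSamples],
    method: str = "bar",
    ctx: ThermoContext = ThermoContext(),
) -> FreeEnergyEstimate:
    """Estimate every window and sum along the schedule.

    ``method`` is ``"bar"`` (both directions required) or
    ``"exp-forward"`` / ``"exp-backward"``.
    """
    if method == "bar":
        per_window = [bar_estimator(w, ctx) for w in windows]
    elif method in ("exp-forward", "exp-backward"):
        direction = method.split("-")[1]
        per_window = [exp_estimator(w, direction, ctx) for w in windows]
    else:
        raise ValidationError(f"unknown method {method!r}")
    return combine_windows(per_window)
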