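"""Regression models relating anesthetic depth and emergence to temperature.

Three model families:

* ordinary least squares, ``y = slope·x + intercept`` — ambient vs. core
  temperature, BSR vs. core temperature;
* one-phase exponential decay, ``y = A·exp(-k·x) + C`` — emergence latency
  (RORR) vs. core temperature at cessation, with ``k >= 0`` enforced
  (latency cannot increase with temperature in this family);
* segmented (breakpoint) model, ``y = b1·(x < b2)·(x − b2) + b3`` — a sloped
  segment joined continuously to a plateau at the inflection temperature b2,
  fitted by profiling b2 on a fine grid with conditional linear least squares
  and a local continuous polish.

Between-group comparisons use the extra-sum-of-squares F test on nested
models: parallel lines then elevation for linear fits, shared vs. separate
decay rate k for one-phase decay fits.  All fits are unweighted.

Note on parameterisation: spreadsheet packages express the one-phase decay as
(Y0, plateau, K) with the curve starting at Y0 when x = 0; the equivalent
(A, k, C) used here maps as A = Y0 − plateau, C = plateau, k = K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    sse: float
    df: int
    n: int
    p_slope: float


@dataclass
class DecayFit:
    amplitude: float  # A
    rate: float  # k, 1/(x units)
    plateau: float  # C
    r_squared: float
    sse: float
    n: int
    converged: bool
    iterations: int = 0

    def predict(self, x):
        return self.amplitude * np.exp(-self.rate * np.asarray(x, float)) + self.plateau


@dataclass
class BreakpointFit:
    b1: float  # pre-break slope
    b2: float  # breakpoint (x units); nan if unidentifiable
    b3: float  # plateau level
    r_squared: float
    sse: float
    n: int
    identifiable: bool

    def predict(self, x):
        x = np.asarray(x, float)
        return self.b1 * (x < self.b2) * (x - self.b2) + self.b3


@dataclass
class ComparisonResult:
    test: str
    null: str
    statistic: float
    df: tuple[float, float]
    p_value: float
    converged: bool = True


def _as_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    return x, y


def fit_linear(x, y) -> LinearFit:
    """Ordinary least squares with R² = 1 − SSE/SST and the slope's t-test
    p-value (reported as nan below n = 3)."""
    x, y = _as_xy(x, y)
    if x.size < 2:
        raise ValueError("need at least two points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is undefined")
    res = stats.linregress(x, y)
    pred = res.slope * x + res.intercept
    sse = float(np.sum((y - pred) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=max(0.0, min(1.0, r2)),
        sse=sse,
        df=x.size - 2,
        n=x.size,
        p_slope=float(res.pvalue) if x.size >= 3 else float("nan"),
    )


# ---------------------------------------------------------------------------
# One-phase decay
# ---------------------------------------------------------------------------


def _decay(x, a, k, c):
    return a * np.exp(-k * x) + c


def _loglinear_init(x, y, c0):
    """(A0, k0) from log-linear regression of log(y − C0) on x."""
    z = y - c0
    if np.any(z <= 0):
        return None
    coef = np.polyfit(x, np.log(z), 1)
    k0 = max(-coef[0], 1e-8)
    a0 = math.exp(coef[1])
    return a0, k0


def fit_one_phase_decay(x, y, init=None, c0_candidates: int = 5) -> DecayFit:
    """Least-squares fit of ``y = A·exp(-k·x) + C`` with k bounded at 0.

    Initialisation: C0 candidates just below min(y) at several margins; for
    each, a log-linear regression of log(y − C0) on x seeds (A0, k0); the
    best-SSE solution over all starts is kept.  A constant response returns
    the documented degenerate fit (A = 0, k = 0, C = mean).  Non-convergence
    of every start yields ``converged=False`` rather than a silent answer.
    """
    x, y = _as_xy(x, y)
    if x.size < 4:
        raise ValueError("need at least four points for a three-parameter fit")
    if np.ptp(x) == 0:
        raise ValueError("x range must be positive")

    sst = float(np.sum((y - y.mean()) ** 2))
    span = float(np.ptp(y))
    if span == 0.0:
        return DecayFit(
            amplitude=0.0, rate=0.0, plateau=float(y.mean()),
            r_squared=1.0, sse=0.0, n=x.size, converged=True,
        )

    margins = np.array([1e-3, 0.02, 0.1, 0.3, 1.0])[:c0_candidates]
    starts = []
    if init is not None:
        starts.append(tuple(init))
    for m in margins:
        c0 = float(y.min() - m * span)
        ini = _loglinear_init(x, y, c0)
        if ini is not None:
            starts.append((ini[0], ini[1], c0))
    if not starts:
        starts.append((span, 1.0 / max(np.ptp(x), 1.0), float(y.min())))

    best = None
    n_ok = 0
    for p0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                _decay, x, y, p0=p0,
                bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((y - _decay(x, *popt)) ** 2))
        n_ok += 1
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        return DecayFit(
            amplitude=float("nan"), rate=float("nan"), plateau=float("nan"),
            r_squared=0.0, sse=float("inf"), n=x.size, converged=False,
        )
    (a, k, c), sse = best
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return DecayFit(
        amplitude=float(a), rate=float(k), plateau=float(c),
        r_squared=max(0.0, min(1.0, r2)), sse=sse, n=x.size,
        converged=True, iterations=n_ok,
    )


# ---------------------------------------------------------------------------
# Breakpoint (segmented) model
# ---------------------------------------------------------------------------


def conditional_breakpoint_fit(x, y, b2: float) -> tuple[float, float, float]:
    """(b1, b3, SSE) of the conditional linear least-squares fit at fixed b2."""
    x, y = _as_xy(x, y)
    design = np.column_stack([(x < b2) * (x - b2), np.ones_like(x)])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    sse = float(np.sum((y - design @ coef) ** 2))
    return float(coef[0]), float(coef[1]), sse


def fit_breakpoint(x, y, grid_step: float = 0.01) -> BreakpointFit:
    """Profile fit of ``y = b1·(x < b2)·(x − b2) + b3``.

    For each candidate b2 on a grid over the interior of x (at least two
    points on each side), the conditional (b1, b3) are solved in closed form;
    the SSE-minimising b2 (ties broken toward the smallest) is then polished
    by bounded continuous optimisation within one grid step.  Data with no
    resolvable break (flat response) are flagged unidentifiable, with
    b3 = mean(y).
    """
    x, y = _as_xy(x, y)
    if x.size < 5:
        raise ValueError("need at least five points")
    xs = np.sort(x)
    lo, hi = xs[1], xs[-2]  # >= 2 points strictly below, >= 2 at/above
    if hi <= lo:
        raise ValueError("x range too narrow for a breakpoint search")
    grid = np.arange(lo + grid_step, hi + grid_step / 2, grid_step)
    if grid.size == 0:
        grid = np.array([(lo + hi) / 2])

    sses = np.empty(grid.size)
    for i, b2 in enumerate(grid):
        _, _, sses[i] = conditional_breakpoint_fit(x, y, b2)
    i_best = int(np.argmin(sses))  # first minimum -> smallest b2 on ties
    b2_best, sse_best = float(grid[i_best]), float(sses[i_best])

    sst = float(np.sum((y - y.mean()) ** 2))
    if np.ptp(sses) <= 1e-10 * max(sst, 1.0):
        return BreakpointFit(
            b1=0.0, b2=float("nan"), b3=float(y.mean()),
            r_squared=0.0 if sst > 0 else 1.0, sse=sst, n=x.size, identifiable=False,
        )

    res = optimize.minimize_scalar(
        lambda b: conditional_breakpoint_fit(x, y, b)[2],
        bounds=(max(lo, b2_best - grid_step), min(hi, b2_best + grid_step)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    if res.success and res.fun <= sse_best:
        b2_best, sse_best = float(res.x), float(res.fun)
    b1, b3, sse_best = conditional_breakpoint_fit(x, y, b2_best)
    if np.sum(x < b2_best) < 2:
        return BreakpointFit(
            b1=b1, b2=float("nan"), b3=b3, r_squared=0.0,
            sse=sse_best, n=x.size, identifiable=False,
        )
    r2 = 1.0 - sse_best / sst if sst > 0 else 1.0
    return BreakpointFit(
        b1=b1, b2=b2_best, b3=b3,
        r_squared=max(0.0, min(1.0, r2)), sse=sse_best, n=x.size, identifiable=True,
    )


# ---------------------------------------------------------------------------
# Between-group model comparisons (extra-sum-of-squares F tests)
# ---------------------------------------------------------------------------


def _lstsq_sse(design: np.ndarray, y: np.ndarray) -> float:
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("singular pooled design matrix")
    return float(np.sum((y - design @ coef) ** 2))


def _f_test(sse_reduced, sse_full, df_num, df_den) -> tuple[float, float]:
    if df_den <= 0:
        raise ValueError("not enough observations for the F test")
    f = max(0.0, (sse_reduced - sse_full) / df_num / (sse_full / df_den)) \
        if sse_full > 0 else (0.0 if sse_reduced <= sse_full + 1e-300 else math.inf)
    p = float(stats.f.sf(f, df_num, df_den)) if math.isfinite(f) else 0.0
    return float(f), p


def compare_linear_fits(group_a, group_b) -> tuple[ComparisonResult, ComparisonResult]:
    """Classical parallel-lines then elevation tests for two linear fits.

    ``group_a``/``group_b`` are (x, y) pairs.  Returns the slope test
    (common slope vs. separate slopes) and, given a common slope, the
    intercept test (common vs. separate intercepts).
    """
    xa, ya = _as_xy(*group_a)
    xb, yb = _as_xy(*group_b)
    if xa.size < 3 or xb.size < 3:
        raise ValueError("each group needs at least three points")
    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    ga = np.concatenate([np.ones_like(xa), np.zeros_like(xb)])
    gb = 1.0 - ga
    n = x.size

    sse_full = _lstsq_sse(np.column_stack([ga, gb, x * ga, x * gb]), y)
    sse_cs = _lstsq_sse(np.column_stack([ga, gb, x]), y)
    sse_one = _lstsq_sse(np.column_stack([np.ones_like(x), x]), y)

    f_slope, p_slope = _f_test(sse_cs, sse_full, 1, n - 4)
    f_int, p_int = _f_test(sse_one, sse_cs, 1, n - 3)
    return (
        ComparisonResult(
            test="extra-SS F", null="equal slopes",
            statistic=f_slope, df=(1.0, float(n - 4)), p_value=p_slope,
        ),
        ComparisonResult(
            test="extra-SS F", null="equal intercepts given equal slopes",
            statistic=f_int, df=(1.0, float(n - 3)), p_value=p_int,
        ),
    )


def _shared_k_sse(xa, ya, xb, yb, init) -> tuple[float, bool]:
    """SSE of the joint five-parameter fit (A1, C1, A2, C2, shared k)."""

    def resid(theta):
        a1, c1, a2, c2, k = theta
        return np.concatenate(
            [ya - _decay(xa, a1, k, c1), yb - _decay(xb, a2, k, c2)]
        )

    lower = [-np.inf, -np.inf, -np.inf, -np.inf, 0.0]
    upper = [np.inf] * 5
    x0 = np.asarray(init, dtype=float)
    x0[4] = max(x0[4], 1e-12)
    res = optimize.least_squares(resid, x0, bounds=(lower, upper), max_nfev=20000)
    return float(np.sum(res.fun**2)), bool(res.success)


def compare_decay_rates(group_a, group_b) -> ComparisonResult:
    """Extra-sum-of-squares F test of a shared decay rate k.

    Fits both groups separately (6 parameters) and jointly with a shared k
    (5 parameters); the F statistic has (1, n − 6) degrees of freedom.  A
    non-convergent joint fit is returned flagged rather than raising.
    """
    xa, ya = _as_xy(*group_a)
    xb, yb = _as_xy(*group_b)
    fa = fit_one_phase_decay(xa, ya)
    fb = fit_one_phase_decay(xb, yb)
    if not (fa.converged and fb.converged):
        return ComparisonResult(
            test="extra-SS F", null="equal decay rate k",
            statistic=float("nan"), df=(1.0, float(xa.size + xb.size - 6)),
            p_value=float("nan"), converged=False,
        )
    sse_sep = fa.sse + fb.sse
    # multi-start the shared-k fit from each group's k and their mean
    inits = [
        (fa.amplitude, fa.plateau, fb.amplitude, fb.plateau, k0)
        for k0 in {fa.rate, fb.rate, 0.5 * (fa.rate + fb.rate)}
    ]
    best_sse, any_ok = math.inf, False
    for ini in inits:
        sse, ok = _shared_k_sse(xa, ya, xb, yb, ini)
        any_ok = any_ok or ok
        best_sse = min(best_sse, sse)
    if not any_ok:
        return ComparisonResult(
            test="extra-SS F", null="equal decay rate k",
            statistic=float("nan"), df=(1.0, float(xa.size + xb.size - 6)),
            p_value=float("nan"), converged=False,
        )
    n = xa.size + xb.size
    # the shared fit can beat the separate fits by a numerical hair; clamp at 0
    f, p = _f_test(max(best_sse, sse_sep), sse_sep, 1, n - 6)
    return ComparisonResult(
        test="extra-SS F", null="equal decay rate k",
        statistic=f, df=(1.0, float(n - 6)), p_value=p,
    )
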