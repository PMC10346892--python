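"""Polack-Ribiere conjugate gradients with a Wolfe-condition line search.

A classical full-batch nonlinear CG minimizer in the style of the widely used
``fmincg``/``minimize`` routine: each iteration performs a line search by
quadratic/cubic interpolation and cubic extrapolation until the step satisfies

* sufficient decrease (Armijo): ``f(x + a d) <= f(x) + c1 a g.d``, and
* strong curvature: ``|g(x + a d).d| <= c2 |g.d|``,

then updates the search direction with the Polack-Ribiere formula.  On
line-search failure the direction is reset to steepest descent; two
consecutive failures terminate.  The accepted-iteration cost sequence is
non-increasing by construction, and the minimizer returns the best parameters
seen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

_TINY = np.finfo(float).tiny


@dataclass
class OptimTrace:
    """Per-accepted-iteration diagnostics of the CG run."""

    cost: list[float] = field(default_factory=list)
    grad_norm: list[float] = field(default_factory=list)
    step: list[float] = field(default_factory=list)
    n_evals: list[float] = field(default_factory=list)
    armijo_margin: list[float] = field(default_factory=list)
    curvature_margin: list[float] = field(default_factory=list)
    n_failures: int = 0

    def append(self, cost, grad_norm, step, n_evals, armijo, curvature) -> None:
        self.cost.append(float(cost))
        self.grad_norm.append(float(grad_norm))
        self.step.append(float(step))
        self.n_evals.append(int(n_evals))
        self.armijo_margin.append(float(armijo))
        self.curvature_margin.append(float(curvature))


def _finite_eval(fun, x):
    f, g = fun(x)
    f = float(f)
    g = np.asarray(g, dtype=float)
    if not math.isfinite(f) or not np.all(np.isfinite(g)):
        return math.inf, g, math.inf  # poisons the Armijo test
    return f, g, None


def minimize(
    fun,
    x0: np.ndarray,
    max_iters: int,
    c1: float = 0.01,
    c2: float = 0.5,
    int_limit: float = 0.1,
    ext: float = 3.0,
    max_evals: int = 20,
    ratio: float = 100.0,
    debug_checks: bool = False,
) -> tuple[np.ndarray, OptimTrace]:
    """Minimize ``fun(x) -> (cost, grad)`` starting from ``x0``.

    ``max_iters`` counts accepted line searches; ``max_evals`` bounds function
    evaluations per line search; ``int_limit`` keeps interpolated steps away
    from the bracket ends; ``ext`` bounds extrapolation; ``ratio`` caps the
    slope ratio used to guess the next initial step.  With
    ``debug_checks=True`` both Wolfe inequalities are asserted at every
    accepted step.
    """
    if not 0 < c1 < c2 < 1:
        raise ValueError("need 0 < c1 < c2 < 1")
    x = np.asarray(x0, dtype=float).copy()
    trace = OptimTrace()

    f1, g1 = fun(x)
    f1 = float(f1)
    g1 = np.asarray(g1, dtype=float)
    if not math.isfinite(f1):
        raise FloatingPointError("objective is non-finite at the starting point")

    d = -g1
    slope1 = -float(d @ d)
    step = 1.0 / (1.0 - slope1)
    best_f, best_x = f1, x.copy()
    ls_failed = False
    it = 0
    while it < max_iters:
        it += 1
        x_prev, f_prev, g_prev = x.copy(), f1, g1.copy()
        x = x + step * d
        f2, g2, bad = _finite_eval(fun, x)
        slope2 = math.inf if bad else float(g2 @ d)
        evals = 1
        f3, slope3, rem = f1, slope1, -step
        budget = max_evals
        limit = -1.0
        success = False

        while True:
            while (
                (f2 > f1 + step * c1 * slope1) or (slope2 > -c2 * slope1)
            ) and budget > 0:
                limit = step
                if f2 > f1:
                    # quadratic fit through the bracket
                    denom = slope3 * rem + f2 - f3
                    incr = rem / 2 if denom == 0 else rem - (0.5 * slope3 * rem * rem) / denom
                else:
                    # cubic fit
                    A = 6 * (f2 - f3) / rem + 3 * (slope2 + slope3)
                    B = 3 * (f3 - f2) - rem * (slope3 + 2 * slope2)
                    disc = B * B - A * slope2 * rem * rem
                    if disc < 0 or A == 0 or not math.isfinite(disc):
                        incr = math.nan
                    else:
                        incr = (math.sqrt(disc) - B) / A
                if not math.isfinite(incr):
                    incr = rem / 2
                incr = max(min(incr, int_limit * rem), (1 - int_limit) * rem)
                step += incr
                x = x + incr * d
                f2, g2, bad = _finite_eval(fun, x)
                slope2 = math.inf if bad else float(g2 @ d)
                evals += 1
                budget -= 1
                rem -= incr

            if f2 > f1 + step * c1 * slope1 or slope2 > -c2 * slope1:
                break  # line-search failure
            if slope2 > c2 * slope1:
                success = True  # strong Wolfe pair satisfied
                break
            if budget == 0:
                break

            # cubic extrapolation beyond the current point
            A = 6 * (f2 - f3) / rem + 3 * (slope2 + slope3)
            B = 3 * (f3 - f2) - rem * (slope3 + 2 * slope2)
            disc = B * B - A * slope2 * rem * rem
            if disc < 0 or not math.isfinite(disc) or (B + math.sqrt(disc)) == 0:
                incr = math.nan
            else:
                incr = -slope2 * rem * rem / (B + math.sqrt(disc))
            if not math.isfinite(incr) or incr < 0:
                incr = (ext - 1) * step if limit < -0.5 else (limit - step) / 2
            elif limit > -0.5 and incr + step > limit:
                incr = (limit - step) / 2
            elif limit < -0.5 and incr + step > step * ext:
                incr = (ext - 1) * step
            elif incr < -rem * int_limit:
                incr = -rem * int_limit
            elif limit > -0.5 and incr < (limit - step) * (1 - int_limit):
                incr = (limit - step) * (1 - int_limit)

            f3, slope3, rem = f2, slope2, -incr
            step += incr
            x = x + incr * d
            f2, g2, bad = _finite_eval(fun, x)
            slope2 = math.inf if bad else float(g2 @ d)
            evals += 1
            budget -= 1

        if success:
            armijo = (f1 + step * c1 * slope1) - f2
            curvature = c2 * abs(slope1) - abs(slope2)
            if debug_checks:
                assert armijo >= 0.0, "Armijo condition violated at accepted step"
                assert curvature >= 0.0, "curvature condition violated at accepted step"
            f1 = f2
            trace.append(f1, np.linalg.norm(g2), step, evals, armijo, curvature)
            if f1 < best_f:
                best_f, best_x = f1, x.copy()
            # Polack-Ribiere direction update
            beta = float(g2 @ g2 - g1 @ g2) / float(g1 @ g1)
            d = beta * d - g2
            g1 = g2
            slope2 = float(g1 @ d)
            if slope2 > 0:  # not a descent direction: reset
                d = -g1
                slope2 = -float(d @ d)
            step = step * min(ratio, slope1 / (slope2 - _TINY))
            slope1 = slope2
            ls_failed = False
        else:
            x, f1, g1 = x_prev, f_prev, g_prev
            trace.n_failures += 1
            if ls_failed:
                break  # two consecutive failures: give up
            d = -g1
            slope1 = -float(d @ d)
            step = 1.0 / (1.0 - slope1)
            ls_failed = True

    return best_x, trace
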