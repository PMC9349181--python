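"""Alternating controller/filter optimisation to a fixed point.

With multiplicative noise the controller and filter problems are coupled:
the optimal ``L`` depends on ``K`` (through the state-dependent
observation-noise term in the cost-to-go) and the optimal ``K`` depends on
``L`` (through the control-dependent noise feeding the error moment).
Neither pass alone is optimal, so the two are alternated — coordinate
descent in the space of gain sequences — until the total expected cost
stabilises.

Each iteration first updates the filter for the current controller and
then the controller for the new filter, so the expected cost evaluated by
the backward pass always belongs to the mutually consistent gain pair
``(L_k, K_k)`` that the iteration holds.  The very first filter pass runs
against ``L = 0``, i.e. it starts from the classic Kalman filter of the
uncontrolled system (for the reaching task this still gives ``K_1 = 0``
since the initial belief is exact).  Convergence is declared when the
absolute relative change of the expected cost between successive
iterations falls below ``tol`` (default ``1e-15``, effectively machine
precision for this quantity).  In the classic-LQG limit (no
multiplicative noise) neither pass depends on the other's gains, so the
second iteration reproduces the first bit-identically and the loop
terminates after two iterations with exactly zero cost change — the
separation principle recovered numerically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .control_synthesis import ControlSolution, backward_pass
from .filter_synthesis import FilterSolution, forward_pass
from .model import SystemModel

__all__ = ["SolverResult", "solve"]


@dataclass
class SolverResult:
    """Converged (or capped) gain sequences with the cost trace."""

    control: ControlSolution
    filter: FilterSolution
    cost_trace: list[float]
    n_iterations: int
    converged: bool


def solve(
    model: SystemModel,
    tol: float = 1e-15,
    max_iter: int = 500,
    L_init: Sequence[np.ndarray] | None = None,
) -> SolverResult:
    """Alternate filter and controller passes until the cost settles.

    Each iteration recomputes the filter for the current control gains,
    then the controller for the new filter gains, and evaluates the total
    expected cost of that pair.  ``L_init`` overrides the zero
    initialisation (any fixed point must be insensitive to it).

    Returns ``converged=False`` (with the full cost trace) when
    ``max_iter`` is reached; raises ``FloatingPointError`` on a
    non-finite cost.
    """
    n = model.n_steps
    if L_init is None:
        L = [np.zeros((model.nu, model.nx)) for _ in range(n - 1)]
    else:
        L = [np.asarray(Li, dtype=float) for Li in L_init]

    cost_trace: list[float] = []
    control: ControlSolution | None = None
    filt: FilterSolution | None = None
    converged = False
    k = 0

    for k in range(1, max_iter + 1):
        filt = forward_pass(model, L)
        control = backward_pass(model, filt.K)
        L = control.L
        J = control.expected_cost
        if not math.isfinite(J):
            raise FloatingPointError(f"expected cost non-finite at iteration {k}")
        cost_trace.append(J)

        if len(cost_trace) >= 2:
            J_prev = cost_trace[-2]
            if J_prev == 0.0:
                rel = 0.0 if J == 0.0 else math.inf
            else:
                rel = abs(J - J_prev) / abs(J_prev)
            if rel < tol:
                converged = True
                break

    assert control is not None and filt is not None
    return SolverResult(
        control=control,
        filter=filt,
        cost_trace=cost_trace,
        n_iterations=k,
        converged=converged,
    )
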