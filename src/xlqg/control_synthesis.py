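"""Backward-in-time synthesis of the optimal feedback control law.

Given fixed filter gains ``K_t``, the optimal control is linear in the
state estimate, ``u_t = -L_t xhat_t``, and the gains are obtained by a
backward recursion over two cost-to-go matrices: ``S^x`` (cost attached to
the true state) and ``S^e`` (cost attached to the estimation error), plus
a scalar ``s`` that accumulates the noise-driven cost floor:

    L_t   = {R + B' S^x_{t+1} B + sum_i C_i'(S^x_{t+1} + S^e_{t+1})C_i}^{-1}
            B' S^x_{t+1} A
    S^x_t = Q_t + A' S^x_{t+1}(A - B L_t) + sum_i D_i' K_t' S^e_{t+1} K_t D_i
    S^e_t = A' S^x_{t+1} B L_t + (A - K_t H)' S^e_{t+1} (A - K_t H)
    s_t   = tr{S^x_{t+1} Omega_xi
              + S^e_{t+1}(Omega_xi + Omega_eta + K_t Omega_omega K_t')} + s_{t+1}

initialised with ``S^x_n = Q_n``, ``S^e_n = 0``, ``s_n = 0``.  The total
expected cost of the closed loop is

    J = xhat_1' S^x_1 xhat_1 + tr{(S^x_1 + S^e_1) Sigma_1} + s_1.

The control-dependent noise term in the gain denominator is what couples
the controller to the filter: larger planned controls inject more noise,
which the cost-to-go matrices feel through ``C_i'(S^x + S^e)C_i``.  With
no multiplicative noise the recursion collapses to the classic
discrete-time LQR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import SystemModel

__all__ = ["ControlSolution", "backward_pass", "expected_total_cost"]

# reciprocal-condition floor below which the gain system is treated as singular
_RCOND_MIN = 1e-15


def _sym(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + M.T)


@dataclass
class ControlSolution:
    """Control gains and cost-to-go quantities from one backward pass.

    ``L[t]`` applies at step ``t`` (0-based, ``t = 0..n-2``); ``Sx``,
    ``Se`` and ``s`` are defined at all ``n`` time points.
    """

    L: list[np.ndarray]
    Sx: list[np.ndarray]
    Se: list[np.ndarray]
    s: np.ndarray
    expected_cost: float


def backward_pass(model: SystemModel, K_seq: Sequence[np.ndarray]) -> ControlSolution:
    """Compute optimal control gains for fixed filter gains ``K_seq``.

    The bracketed gain matrix is solved as a linear system rather than
    explicitly inverted, and ``S^x``, ``S^e`` are re-symmetrised after
    every update to suppress floating-point asymmetry.

    Raises
    ------
    numpy.linalg.LinAlgError
        If the gain system matrix is singular to working precision
        (cannot happen for a valid model with positive-definite ``R``).
    """
    n = model.n_steps
    nx, ny = model.nx, model.ny
    A, B, H, R = model.A, model.B, model.H, model.R
    Om_xi, Om_om, Om_eta = model.Omega_xi, model.Omega_omega, model.Omega_eta

    if len(K_seq) != n - 1:
        raise ValueError(f"K_seq must have {n - 1} entries, got {len(K_seq)}")

    Sx: list[np.ndarray] = [np.empty(0)] * n
    Se: list[np.ndarray] = [np.empty(0)] * n
    s = np.zeros(n)
    L: list[np.ndarray] = [np.empty(0)] * (n - 1)

    Sx[n - 1] = _sym(model.Q_list[n - 1])
    Se[n - 1] = np.zeros((nx, nx))

    for t in range(n - 2, -1, -1):
        Sx1, Se1 = Sx[t + 1], Se[t + 1]
        K = np.asarray(K_seq[t], dtype=float)
        if K.shape != (nx, ny):
            raise ValueError(f"K_seq[{t}] has shape {K.shape}, expected {(nx, ny)}")

        M = R + B.T @ Sx1 @ B
        for C in model.C_list:
            M = M + C.T @ (Sx1 + Se1) @ C
        M = _sym(M)
        if np.linalg.cond(M) > 1.0 / _RCOND_MIN:
            raise np.linalg.LinAlgError(
                f"gain system matrix singular to working precision at step {t}"
            )
        Lt = np.linalg.solve(M, B.T @ Sx1 @ A)
        L[t] = Lt

        Sx_t = model.Q_list[t] + A.T @ Sx1 @ (A - B @ Lt)
        for D in model.D_list:
            KD = K @ D
            Sx_t = Sx_t + KD.T @ Se1 @ KD
        AmKH = A - K @ H
        Se_t = A.T @ Sx1 @ B @ Lt + AmKH.T @ Se1 @ AmKH
        Sx[t] = _sym(Sx_t)
        Se[t] = _sym(Se_t)
        s[t] = (
            np.trace(Sx1 @ Om_xi)
            + np.trace(Se1 @ (Om_xi + Om_eta + K @ Om_om @ K.T))
            + s[t + 1]
        )

    sol = ControlSolution(L=L, Sx=Sx, Se=Se, s=s, expected_cost=0.0)
    sol.expected_cost = expected_total_cost(model, sol)
    return sol


def expected_total_cost(model: SystemModel, sol: ControlSolution) -> float:
    """Total expected cost of the closed loop defined by ``sol``."""
    xh1 = model.xhat1
    return float(
        xh1 @ sol.Sx[0] @ xh1
        + np.trace((sol.Sx[0] + sol.Se[0]) @ model.Sigma1)
        + sol.s[0]
    )
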