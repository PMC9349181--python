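"""Forward-in-time synthesis of the adaptive state-estimation filter.

Given fixed control gains ``L_t``, the optimal filter gain is a
Kalman-like expression driven by three second-moment matrices: the
estimation-error second moment ``Sigma^e``, the estimate second moment
``Sigma^xhat = E[xhat xhat']`` (NOT the central covariance), and their
cross moment ``Sigma^xhat_e``:

    K_t = A Sigma^e_t H' { H Sigma^e_t H' + Omega_omega
            + sum_i D_i (Sigma^e_t + Sigma^xhat_t + Sigma^xhat_e_t
                         + Sigma^xhat_e_t') D_i' }^+

    Sigma^e_{t+1}      = Omega_xi + Omega_eta + (A - K_t H) Sigma^e_t A'
                         + sum_i C_i L_t Sigma^xhat_t L_t' C_i'
    Sigma^xhat_{t+1}   = Omega_eta + K_t H Sigma^e_t A'
                         + (A - B L_t) Sigma^xhat_t (A - B L_t)'
                         + (A - B L_t) Sigma^xhat_e_t H' K_t'
                         + K_t H Sigma^xhat_e_t' (A - B L_t)'
    Sigma^xhat_e_{t+1} = (A - B L_t) Sigma^xhat_e_t (A - K_t H)' - Omega_eta

initialised with ``Sigma^e_1 = Sigma_1``, ``Sigma^xhat_1 = xhat_1 xhat_1'``
and ``Sigma^xhat_e_1 = 0``.  The state-dependent observation-noise term in
the innovation moment is what couples the filter back to the controller.

``{...}^+`` denotes the Moore-Penrose pseudoinverse.  The innovation
second moment can be exactly singular — e.g. with zero additive
observation noise and rank-deficient ``Sigma^e`` — so a plain inverse is
not defined.  Because the gain numerator ``A Sigma^e H'`` shares its range
with ``Sigma^e``, the pseudoinverse yields the least-squares-optimal gain
on the observable subspace and reduces to the ordinary inverse whenever
the innovation moment is nonsingular.  The singular-value cutoff is
relative (default ``1e-12`` of the largest singular value); results should
be, and are tested to be, insensitive to cutoffs in ``[1e-14, 1e-10]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import SystemModel

__all__ = ["FilterSolution", "forward_pass"]

#: relative singular-value cutoff for the innovation pseudoinverse
PINV_RCOND = 1e-12

#: most negative eigenvalue tolerated in Sigma^e before declaring divergence
_EIG_FLOOR = -1e-8


def _sym(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + M.T)


@dataclass
class FilterSolution:
    """Filter gains and second-moment matrices from one forward pass.

    ``K[t]`` applies at step ``t`` (0-based, ``t = 0..n-2``); the moment
    sequences are defined at all ``n`` time points.  ``Sigma_e_xhat`` is
    not stored: it is the transpose of ``Sigma_xhat_e``.
    """

    K: list[np.ndarray]
    Sigma_e: list[np.ndarray]
    Sigma_xhat: list[np.ndarray]
    Sigma_xhat_e: list[np.ndarray]


def forward_pass(
    model: SystemModel,
    L_seq: Sequence[np.ndarray],
    pinv_rcond: float = PINV_RCOND,
) -> FilterSolution:
    """Compute optimal filter gains for fixed control gains ``L_seq``.

    Raises
    ------
    FloatingPointError
        If ``Sigma^e`` develops an eigenvalue below ``-1e-8`` relative to
        its own scale, signalling divergence or invalid inputs.
    """
    n = model.n_steps
    nx, nu, ny = model.nx, model.nu, model.ny
    A, B, H = model.A, model.B, model.H
    Om_xi, Om_om, Om_eta = model.Omega_xi, model.Omega_omega, model.Omega_eta

    if len(L_seq) != n - 1:
        raise ValueError(f"L_seq must have {n - 1} entries, got {len(L_seq)}")

    Sig_e: list[np.ndarray] = [np.empty(0)] * n
    Sig_xh: list[np.ndarray] = [np.empty(0)] * n
    Sig_xe: list[np.ndarray] = [np.empty(0)] * n
    K: list[np.ndarray] = [np.empty(0)] * (n - 1)

    Sig_e[0] = _sym(model.Sigma1)
    Sig_xh[0] = np.outer(model.xhat1, model.xhat1)
    Sig_xe[0] = np.zeros((nx, nx))

    for t in range(n - 1):
        L = np.asarray(L_seq[t], dtype=float)
        if L.shape != (nu, nx):
            raise ValueError(f"L_seq[{t}] has shape {L.shape}, expected {(nu, nx)}")

        Se_t, Sxh_t, Sxe_t = Sig_e[t], Sig_xh[t], Sig_xe[t]

        innov = H @ Se_t @ H.T + Om_om
        total = Se_t + Sxh_t + Sxe_t + Sxe_t.T
        for D in model.D_list:
            innov = innov + D @ total @ D.T
        Kt = A @ Se_t @ H.T @ np.linalg.pinv(_sym(innov), rcond=pinv_rcond, hermitian=True)
        K[t] = Kt

        AmKH = A - Kt @ H
        AmBL = A - B @ L

        Se_next = Om_xi + Om_eta + AmKH @ Se_t @ A.T
        for C in model.C_list:
            CL = C @ L
            Se_next = Se_next + CL @ Sxh_t @ CL.T
        Se_next = _sym(Se_next)

        Sxh_next = (
            Om_eta
            + Kt @ H @ Se_t @ A.T
            + AmBL @ Sxh_t @ AmBL.T
            + AmBL @ Sxe_t @ H.T @ Kt.T
            + Kt @ H @ Sxe_t.T @ AmBL.T
        )
        Sxe_next = AmBL @ Sxe_t @ AmKH.T - Om_eta

        w = np.linalg.eigvalsh(Se_next)
        if w.min() < _EIG_FLOOR * max(1.0, float(w.max())):
            raise FloatingPointError(
                f"Sigma^e developed eigenvalue {w.min():.3e} at step {t + 1}; "
                "filter recursion is diverging"
            )

        Sig_e[t + 1] = Se_next
        Sig_xh[t + 1] = _sym(Sxh_next)
        Sig_xe[t + 1] = Sxe_next

    return FilterSolution(K=K, Sigma_e=Sig_e, Sigma_xhat=Sig_xh, Sigma_xhat_e=Sig_xe)
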