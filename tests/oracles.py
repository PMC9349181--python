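"""Independent textbook recursions used as oracles.

These deliberately use the standard Riccati / Kalman algebraic forms
(Schur-complement style), not the package's own recursions, so agreement
is a genuine cross-check in the no-multiplicative-noise limit.
"""

import numpy as np


def lqr_gains(A, B, Q_list, R):
    """Finite-horizon discrete LQR gains via the standard Riccati recursion.

    S_t = Q_t + A'S_{t+1}A - A'S_{t+1}B (R + B'S_{t+1}B)^{-1} B'S_{t+1}A
    """
    n = len(Q_list)
    S = 0.5 * (Q_list[-1] + Q_list[-1].T)
    L = [None] * (n - 1)
    for t in range(n - 2, -1, -1):
        G = R + B.T @ S @ B
        BtSA = B.T @ S @ A
        L[t] = np.linalg.solve(G, BtSA)
        S = Q_list[t] + A.T @ S @ A - BtSA.T @ np.linalg.solve(G, BtSA)
        S = 0.5 * (S + S.T)
    return L


def kalman_gains(A, H, Om_xi, Om_om, Sigma1, n):
    """Time-varying Kalman gains (A-premultiplied form) and a-priori error
    covariances for the system (A, H, Om_xi, Om_om).

    P_{t+1} = A (P - P H'(H P H' + Om_om)^{-1} H P) A' + Om_xi
    K_t     = A P H' (H P H' + Om_om)^{-1}
    """
    P = 0.5 * (Sigma1 + Sigma1.T)
    Ks, Ps = [], [P.copy()]
    for _ in range(n - 1):
        Sinn = H @ P @ H.T + Om_om
        Sinn_inv = np.linalg.pinv(Sinn)
        K = A @ P @ H.T @ Sinn_inv
        P = A @ (P - P @ H.T @ Sinn_inv @ H @ P) @ A.T + Om_xi
        P = 0.5 * (P + P.T)
        Ks.append(K)
        Ps.append(P.copy())
    return Ks, Ps
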