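"""Sample-path Monte Carlo simulator of the closed-loop system.

This is the brute-force counterpart of
:mod:`xlqg.moment_propagation`: it simulates the plant, sensor and filter
equations trial by trial and estimates the same nine moment sequences
empirically.  It exists purely as a verification oracle — the analytic
update equations are the product; agreement of the two routes (within
Monte Carlo error) is the core correctness check of the package.

Draw order is fixed and documented for bit-reproducibility.  With a
``numpy.random.default_rng(seed)`` generator:

1. the initial states of all trials, ``x_1 ~ N(xhat_1, Sigma_1)``;
2. then per time step, in this order: state noise ``xi``, observation
   noise ``omega``, estimation noise ``eta``, the ``c`` scalar
   control-noise draws ``eps``, the ``d`` scalar observation-noise draws
   ``eps'`` (each as an ``(n_trials, k)`` standard-normal block).

Covariance square roots are taken via symmetric eigendecomposition with
negative eigenvalues clipped at ``-1e-12`` (relative); the noise
covariances are frequently exactly singular by design (zero rows for
deterministic state components), which plain Cholesky would reject.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import SystemModel
from .moment_propagation import MomentTrajectory

__all__ = ["EmpiricalMoments", "simulate_trials", "compare_moments"]

_CLIP_TOL = 1e-12


def _psd_sqrt(M: np.ndarray) -> np.ndarray:
    """Symmetric square root with small-negative-eigenvalue clipping."""
    Ms = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(Ms)
    scale = max(1.0, float(np.abs(w).max()) if w.size else 1.0)
    if w.min() < -_CLIP_TOL * scale:
        raise ValueError(
            f"covariance square-root failed PSD tolerance (min eig {w.min():.3e})"
        )
    w = np.clip(w, 0.0, None)
    return (V * np.sqrt(w)) @ V.T


@dataclass
class EmpiricalMoments:
    """Empirical means/covariances across trials, with standard errors.

    Shapes mirror :class:`~xlqg.moment_propagation.MomentTrajectory`.
    ``se_mean_*`` are per-component standard errors of the empirical
    means; ``se_sd_*`` are standard errors of the per-component empirical
    standard deviations, computed distribution-free from the fourth
    central moment: ``SE(s^2) = sqrt((m4 - s^4 (N-3)/(N-1)) / N)`` and
    ``SE(s) = SE(s^2) / (2 s)``.  The Gaussian shortcut
    ``s / sqrt(2(N-1))`` would badly underestimate the error here:
    multiplicative noise makes the closed-loop state strongly leptokurtic
    (excess kurtosis of several dozen is typical for the reaching task).
    ``mean_cost`` / ``se_cost`` give the per-trial realized quadratic cost
    summed over the horizon.
    """

    mean_x: np.ndarray
    mean_xhat: np.ndarray
    mean_e: np.ndarray
    var_x: np.ndarray
    var_xhat: np.ndarray
    var_e: np.ndarray
    cov_x_xhat: np.ndarray
    cov_x_e: np.ndarray
    cov_xhat_e: np.ndarray
    se_mean_x: np.ndarray
    se_mean_xhat: np.ndarray
    se_mean_e: np.ndarray
    se_sd_x: np.ndarray
    se_sd_xhat: np.ndarray
    se_sd_e: np.ndarray
    mean_cost: float
    se_cost: float
    n_trials: int
    seed: int


def simulate_trials(
    model: SystemModel,
    L_seq: Sequence[np.ndarray],
    K_seq: Sequence[np.ndarray],
    n_trials: int,
    seed: int,
) -> EmpiricalMoments:
    """Simulate ``n_trials`` closed-loop trials and return empirical moments.

    All trials are advanced in lock-step as vectorised ``(n_trials, nx)``
    blocks; empirical covariances use the unbiased ``1/(n_trials - 1)``
    normalisation.  Same seed, same output — bit-identical.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    n, nx, ny = model.n_steps, model.nx, model.ny
    A, B, H = model.A, model.B, model.H
    if len(L_seq) != n - 1 or len(K_seq) != n - 1:
        raise ValueError(f"gain sequences must have length {n - 1}")

    sq_xi = _psd_sqrt(model.Omega_xi)
    sq_om = _psd_sqrt(model.Omega_omega)
    sq_eta = _psd_sqrt(model.Omega_eta)
    sq_S1 = _psd_sqrt(model.Sigma1)
    c, d = len(model.C_list), len(model.D_list)

    rng = np.random.default_rng(seed)
    N = int(n_trials)

    X = model.xhat1 + rng.standard_normal((N, nx)) @ sq_S1.T
    Xh = np.tile(model.xhat1, (N, 1))
    cost = np.zeros(N)

    mean = {k: np.zeros((n, nx)) for k in ("x", "xhat", "e")}
    var = {k: np.zeros((n, nx, nx)) for k in ("x", "xhat", "e")}
    cov = {k: np.zeros((n, nx, nx)) for k in ("x_xhat", "x_e", "xhat_e")}
    se_mean = {k: np.zeros((n, nx)) for k in ("x", "xhat", "e")}
    se_sd = {k: np.zeros((n, nx)) for k in ("x", "xhat", "e")}

    def record(t: int) -> None:
        E = X - Xh
        blocks = {"x": X, "xhat": Xh, "e": E}
        centered = {}
        for k, V in blocks.items():
            # centre on the first trial before averaging so that exactly
            # identical trials (degenerate noise-free case) give exactly
            # zero residuals and variances
            W = V - V[0]
            mw = W.mean(axis=0)
            mean[k][t] = V[0] + mw
            centered[k] = W - mw
        for k, Vc in centered.items():
            var[k][t] = Vc.T @ Vc / (N - 1)
            v2 = np.clip(np.diag(var[k][t]), 0.0, None)
            sd = np.sqrt(v2)
            se_mean[k][t] = sd / np.sqrt(N)
            m4 = np.mean(Vc**4, axis=0)
            se_var = np.sqrt(np.clip(m4 - v2**2 * (N - 3) / (N - 1), 0.0, None) / N)
            with np.errstate(divide="ignore", invalid="ignore"):
                se_sd[k][t] = np.where(sd > 0.0, se_var / (2.0 * sd), 0.0)
        cov["x_xhat"][t] = centered["x"].T @ centered["xhat"] / (N - 1)
        cov["x_e"][t] = centered["x"].T @ centered["e"] / (N - 1)
        cov["xhat_e"][t] = centered["xhat"].T @ centered["e"] / (N - 1)

    record(0)
    for t in range(n - 1):
        xi = rng.standard_normal((N, nx)) @ sq_xi.T
        om = rng.standard_normal((N, ny)) @ sq_om.T
        eta = rng.standard_normal((N, nx)) @ sq_eta.T
        eps_c = rng.standard_normal((N, c)) if c else np.zeros((N, 0))
        eps_d = rng.standard_normal((N, d)) if d else np.zeros((N, 0))

        L = np.asarray(L_seq[t], dtype=float)
        K = np.asarray(K_seq[t], dtype=float)
        U = -(Xh @ L.T)

        Qt = model.Q_list[t]
        cost += np.einsum("ij,jk,ik->i", X, Qt, X)
        cost += np.einsum("ij,jk,ik->i", U, model.R, U)

        X_next = X @ A.T + U @ B.T + xi
        for i, C in enumerate(model.C_list):
            X_next += eps_c[:, i, None] * (U @ C.T)

        Y = X @ H.T + om
        for i, D in enumerate(model.D_list):
            Y += eps_d[:, i, None] * (X @ D.T)

        Xh = Xh @ A.T + U @ B.T + (Y - Xh @ H.T) @ K.T + eta
        X = X_next
        record(t + 1)

    Qn = model.Q_list[n - 1]
    cost += np.einsum("ij,jk,ik->i", X, Qn, X)

    return EmpiricalMoments(
        mean_x=mean["x"],
        mean_xhat=mean["xhat"],
        mean_e=mean["e"],
        var_x=var["x"],
        var_xhat=var["xhat"],
        var_e=var["e"],
        cov_x_xhat=cov["x_xhat"],
        cov_x_e=cov["x_e"],
        cov_xhat_e=cov["xhat_e"],
        se_mean_x=se_mean["x"],
        se_mean_xhat=se_mean["xhat"],
        se_mean_e=se_mean["e"],
        se_sd_x=se_sd["x"],
        se_sd_xhat=se_sd["xhat"],
        se_sd_e=se_sd["e"],
        mean_cost=float(cost.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(N)),
        n_trials=N,
        seed=int(seed),
    )


def compare_moments(
    traj: MomentTrajectory,
    emp: EmpiricalMoments,
    n_sigma: float = 4.0,
    atol: float = 1e-9,
) -> dict[str, float]:
    """Worst deviation (in units of Monte Carlo SEs) between the analytic
    moments and the empirical ones.

    For every mean component and every per-component SD, the deviation is
    ``|analytic - empirical| / (n_sigma * SE + atol * (1 + |analytic|))``;
    values <= 1 are within the ``n_sigma`` band (the absolute floor keeps
    exactly-deterministic components, whose SE is zero, comparable).
    Returns the maximum normalised deviation per sequence, plus
    ``"worst"`` over all sequences.
    """
    out: dict[str, float] = {}

    def ratio(a: np.ndarray, b: np.ndarray, se: np.ndarray) -> float:
        denom = n_sigma * se + atol * (1.0 + np.abs(a))
        return float(np.max(np.abs(a - b) / denom))

    out["mean_x"] = ratio(traj.mean_x, emp.mean_x, emp.se_mean_x)
    out["mean_xhat"] = ratio(traj.mean_xhat, emp.mean_xhat, emp.se_mean_xhat)
    out["mean_e"] = ratio(traj.mean_e, emp.mean_e, emp.se_mean_e)

    for name, se in (("x", emp.se_sd_x), ("xhat", emp.se_sd_xhat), ("e", emp.se_sd_e)):
        a = np.sqrt(np.clip(np.diagonal(getattr(traj, f"var_{name}"), axis1=1, axis2=2), 0, None))
        b = np.sqrt(np.clip(np.diagonal(getattr(emp, f"var_{name}"), axis1=1, axis2=2), 0, None))
        out[f"sd_{name}"] = ratio(a, b, se)

    out["worst"] = max(out.values())
    return out
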