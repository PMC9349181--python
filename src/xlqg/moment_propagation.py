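"""Deterministic propagation of state-variable means and (co)variances.

For a fixed pair of gain sequences ``(L_t, K_t)`` the closed loop formed
by the plant, the feedback law ``u = -L xhat`` and the filter is itself a
linear stochastic system in the joint variables ``(x, xhat, e)`` with
``e = x - xhat`` the estimation error.  Its first and second moments
therefore obey closed-form update equations — no sampling required:

means::

    E[x_{t+1}]    = A E[x_t] - B L_t E[xhat_t]
    E[xhat_{t+1}] = (A - B L_t) E[xhat_t] + K_t H E[e_t]
    E[e_{t+1}]    = (A - K_t H) E[e_t]

(co)variances (writing ``AmBL = A - B L_t``, ``AmKH = A - K_t H``)::

    var[x_{t+1}]       = A var[x] A' - A cov[x,xhat] L'B' - BL cov[xhat,x] A'
                         + BL var[xhat] L'B' + Omega_xi + sum_i C_i L Sig^xhat L'C_i'
    cov[x,xhat]_{t+1}  = A cov[x,xhat] AmBL' + A cov[x,e] H'K'
                         - BL var[xhat] AmBL' - BL cov[xhat,e] H'K'
    var[xhat_{t+1}]    = AmBL var[xhat] AmBL' + AmBL cov[xhat,e] H'K'
                         + KH cov[e,xhat] AmBL' + KH var[e] H'K'
                         + K Omega_omega K' + Omega_eta + sum_i K D_i Sig^x D_i'K'
    cov[x,e]_{t+1}     = A cov[x,e] AmKH' - BL cov[xhat,e] AmKH'
                         + Omega_xi + sum_i C_i L Sig^xhat L'C_i'
    cov[xhat,e]_{t+1}  = AmBL cov[xhat,e] AmKH' + KH var[e] AmKH'
                         - K Omega_omega K' - Omega_eta - sum_i K D_i Sig^x D_i'K'
    var[e_{t+1}]       = AmKH var[e] AmKH' + Omega_xi + K Omega_omega K'
                         + Omega_eta + sum_i C_i L Sig^xhat L'C_i'
                         + sum_i K D_i Sig^x D_i'K'

where ``Sig^xhat = var[xhat] + E[xhat]E[xhat]'`` and
``Sig^x = var[x] + E[x]E[x]'`` are the raw second moments, recomputed at
every step from the propagated quantities so the recursion is exact for
arbitrary — even suboptimal — gain sequences.  The multiplicative-noise
sums are what distinguish these updates from plain linear covariance
propagation: control-dependent noise injects the *second moment* of the
planned control, state-dependent observation noise the second moment of
the observed state.

Initial conditions: the initial estimate is deterministic and the initial
error carries the prior covariance, i.e. ``E[x_1] = E[xhat_1] = xhat_1``,
``E[e_1] = 0``, ``var[x_1] = var[e_1] = cov[x,e]_1 = Sigma_1`` and
``var[xhat_1] = cov[x,xhat]_1 = cov[xhat,e]_1 = 0``.

Two identities hold at every step and serve as live consistency checks
(the three mean recursions, and the variance recursions, are mutually
redundant): ``E[x] = E[xhat] + E[e]`` and
``var[x] = var[xhat] + var[e] + cov[xhat,e] + cov[xhat,e]'``.

The module also derives the observable movement summaries: the mean speed
profile ``E[p_dot]`` and the positional standard deviation
``sqrt(var[p])`` across (virtual) trials — the two panels conventionally
plotted for reaching movements.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import SystemModel

__all__ = [
    "MomentTrajectory",
    "MovementProfiles",
    "propagate_moments",
    "profiles",
    "profiles_to_csv",
    "profiles_from_csv",
]


def _sym(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + M.T)


@dataclass
class MomentTrajectory:
    """Time-indexed means and (co)variances of ``x``, ``xhat`` and ``e``.

    Mean arrays have shape ``(n, nx)``; (co)variance arrays have shape
    ``(n, nx, nx)``.  ``cov_x_xhat[t]`` is ``cov[x_t, xhat_t]`` (rows
    index ``x``); the reversed orderings are the transposes.
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


@dataclass
class MovementProfiles:
    """Speed and positional-variability time series with peak summaries."""

    time: np.ndarray          # seconds
    speed: np.ndarray         # m/s, mean velocity E[p_dot]
    pos_sd: np.ndarray        # metres, sqrt(var[p])
    speed_peak_time: float    # seconds
    sd_peak_time: float       # seconds
    end_speed: float          # m/s at the final step
    end_pos_mean: float       # metres, E[p] at the final step


def propagate_moments(
    model: SystemModel,
    L_seq: Sequence[np.ndarray],
    K_seq: Sequence[np.ndarray],
) -> MomentTrajectory:
    """Propagate the nine moment sequences through the closed loop.

    Raises ``FloatingPointError`` if any moment becomes non-finite
    (divergent gain sequences).
    """
    n, nx = model.n_steps, model.nx
    A, B, H = model.A, model.B, model.H
    Om_xi, Om_om, Om_eta = model.Omega_xi, model.Omega_omega, model.Omega_eta
    if len(L_seq) != n - 1 or len(K_seq) != n - 1:
        raise ValueError(f"gain sequences must have length {n - 1}")

    m_x = np.zeros((n, nx))
    m_xh = np.zeros((n, nx))
    m_e = np.zeros((n, nx))
    v_x = np.zeros((n, nx, nx))
    v_xh = np.zeros((n, nx, nx))
    v_e = np.zeros((n, nx, nx))
    c_xxh = np.zeros((n, nx, nx))
    c_xe = np.zeros((n, nx, nx))
    c_xhe = np.zeros((n, nx, nx))

    m_x[0] = model.xhat1
    m_xh[0] = model.xhat1
    v_x[0] = model.Sigma1
    v_e[0] = model.Sigma1
    c_xe[0] = model.Sigma1

    for t in range(n - 1):
        L = np.asarray(L_seq[t], dtype=float)
        K = np.asarray(K_seq[t], dtype=float)
        BL = B @ L
        AmBL = A - BL
        KH = K @ H
        AmKH = A - KH

        # raw second moments entering the multiplicative-noise terms
        Sig_xh = v_xh[t] + np.outer(m_xh[t], m_xh[t])
        Sig_x = v_x[t] + np.outer(m_x[t], m_x[t])

        cdn = np.zeros((nx, nx))      # control-dependent noise injection
        for C in model.C_list:
            CL = C @ L
            cdn += CL @ Sig_xh @ CL.T
        sdn = np.zeros((nx, nx))      # state-dependent observation-noise injection
        for D in model.D_list:
            KD = K @ D
            sdn += KD @ Sig_x @ KD.T
        KOK = K @ Om_om @ K.T

        m_x[t + 1] = A @ m_x[t] - BL @ m_xh[t]
        m_xh[t + 1] = AmBL @ m_xh[t] + KH @ m_e[t]
        m_e[t + 1] = AmKH @ m_e[t]

        v_x[t + 1] = _sym(
            A @ v_x[t] @ A.T
            - A @ c_xxh[t] @ BL.T
            - BL @ c_xxh[t].T @ A.T
            + BL @ v_xh[t] @ BL.T
            + Om_xi
            + cdn
        )
        c_xxh[t + 1] = (
            A @ c_xxh[t] @ AmBL.T
            + A @ c_xe[t] @ KH.T
            - BL @ v_xh[t] @ AmBL.T
            - BL @ c_xhe[t] @ KH.T
        )
        v_xh[t + 1] = _sym(
            AmBL @ v_xh[t] @ AmBL.T
            + AmBL @ c_xhe[t] @ KH.T
            + KH @ c_xhe[t].T @ AmBL.T
            + KH @ v_e[t] @ KH.T
            + KOK
            + Om_eta
            + sdn
        )
        c_xe[t + 1] = (
            A @ c_xe[t] @ AmKH.T
            - BL @ c_xhe[t] @ AmKH.T
            + Om_xi
            + cdn
        )
        c_xhe[t + 1] = (
            AmBL @ c_xhe[t] @ AmKH.T
            + KH @ v_e[t] @ AmKH.T
            - KOK
            - Om_eta
            - sdn
        )
        v_e[t + 1] = _sym(
            AmKH @ v_e[t] @ AmKH.T
            + Om_xi
            + KOK
            + Om_eta
            + cdn
            + sdn
        )

        if not np.isfinite(v_x[t + 1]).all() or not np.isfinite(m_x[t + 1]).all():
            raise FloatingPointError(f"moment propagation diverged at step {t + 1}")

    return MomentTrajectory(
        mean_x=m_x,
        mean_xhat=m_xh,
        mean_e=m_e,
        var_x=v_x,
        var_xhat=v_xh,
        var_e=v_e,
        cov_x_xhat=c_xxh,
        cov_x_e=c_xe,
        cov_xhat_e=c_xhe,
    )


def profiles(moments: MomentTrajectory, dt: float) -> MovementProfiles:
    """Derive speed / positional-SD profiles from a moment trajectory.

    Assumes a reaching-type state layout with position as the first state
    component and velocity as the second.  Speed is the signed mean
    velocity ``E[p_dot]`` (the task is one-dimensional and essentially
    monotone).  Peaks are located by arg-max with earliest-index
    tie-breaking.
    """
    if moments.mean_x.shape[1] < 2:
        raise ValueError("profiles require at least position and velocity states")
    n = moments.mean_x.shape[0]
    time = np.arange(n) * dt
    speed = moments.mean_x[:, 1].copy()
    pos_var = moments.var_x[:, 0, 0]
    pos_sd = np.sqrt(np.clip(pos_var, 0.0, None))

    return MovementProfiles(
        time=time,
        speed=speed,
        pos_sd=pos_sd,
        speed_peak_time=float(time[int(np.argmax(speed))]),
        sd_peak_time=float(time[int(np.argmax(pos_sd))]),
        end_speed=float(speed[-1]),
        end_pos_mean=float(moments.mean_x[-1, 0]),
    )


def profiles_to_csv(prof: MovementProfiles, path: str | Path) -> None:
    """Write the profile time series as CSV (columns time_s, speed_mps,
    pos_sd_m).  Values are serialised with Python's shortest round-trip
    repr, so a re-read reproduces them bit-exactly."""
    lines = ["time_s,speed_mps,pos_sd_m"]
    for t, s, sd in zip(prof.time, prof.speed, prof.pos_sd):
        lines.append(f"{float(t)!r},{float(s)!r},{float(sd)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def profiles_from_csv(path: str | Path) -> MovementProfiles:
    """Re-read a profile CSV; peak summaries are recomputed."""
    df = pd.read_csv(path, float_precision="round_trip")
    time = df["time_s"].to_numpy()
    speed = df["speed_mps"].to_numpy()
    pos_sd = df["pos_sd_m"].to_numpy()
    return MovementProfiles(
        time=time,
        speed=speed,
        pos_sd=pos_sd,
        speed_peak_time=float(time[int(np.argmax(speed))]),
        sd_peak_time=float(time[int(np.argmax(pos_sd))]),
        end_speed=float(speed[-1]),
        end_pos_mean=float("nan"),
    )
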