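"""Problem definition for extended LQG optimal control.

The extended linear-quadratic-Gaussian (LQG) setting generalises the
classic LQG problem to biologically motivated noise sources.  The plant is
a discrete-time linear system

    x_{t+1} = A x_t + B u_t + xi_t + sum_i eps_t^i C_i u_t

where ``xi`` is additive (state-independent) Gaussian state noise and the
``eps^i C_i u`` terms are control-dependent (signal-dependent,
multiplicative) noise: scalar standard-normal draws ``eps^i`` scale the
matrices ``C_i`` applied to the control.  Observations carry both additive
and state-dependent noise,

    y_t = H x_t + omega_t + sum_i eps_t^i D_i x_t

and the internal state estimate is corrupted by additive estimation noise
``eta`` with covariance ``Omega_eta``.  Per-step cost is
``x' Q_t x + u' R u``.

This module defines the problem container :class:`SystemModel`, validation
diagnostics, YAML configuration I/O, and the constructor for the standard
single-joint point-to-point reaching task used throughout the package: a
unit point mass driven through a second-order muscle-like low-pass filter,
with a constant fifth state carrying the target position so that the
terminal cost can penalise the position error ``p - p*`` through a linear
form.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SystemModel",
    "ReachingParams",
    "build_reaching_model",
    "validate_model",
    "save_params",
    "load_params",
    "save_model",
    "load_model",
]

#: eigenvalue slack below zero still accepted as numerically PSD
PSD_TOL = 1e-12


def _mat(M) -> np.ndarray:
    return np.array(M, dtype=float)


def _sym_defect(M: np.ndarray) -> float:
    scale = max(1.0, float(np.abs(M).max()))
    return float(np.abs(M - M.T).max()) / scale


def _min_eig(M: np.ndarray) -> float:
    return float(np.linalg.eigvalsh(0.5 * (M + M.T)).min())


@dataclass
class SystemModel:
    """All matrices, noise covariances/scalings, costs, horizon and initial
    belief of one extended-LQG problem.

    States are defined at the ``n_steps`` discrete time points
    ``t = 1..n``; controls, control gains and filter gains exist at
    ``t = 1..n-1``.  The terminal state cost is ``Q_list[-1]``.
    """

    n_steps: int
    A: np.ndarray
    B: np.ndarray
    C_list: list[np.ndarray]
    H: np.ndarray
    D_list: list[np.ndarray]
    Omega_xi: np.ndarray
    Omega_omega: np.ndarray
    Omega_eta: np.ndarray
    Q_list: list[np.ndarray]
    R: np.ndarray
    xhat1: np.ndarray
    Sigma1: np.ndarray

    def __post_init__(self) -> None:
        self.n_steps = int(self.n_steps)
        self.A = _mat(self.A)
        self.B = _mat(self.B)
        self.C_list = [_mat(C) for C in self.C_list]
        self.H = _mat(self.H)
        self.D_list = [_mat(D) for D in self.D_list]
        self.Omega_xi = _mat(self.Omega_xi)
        self.Omega_omega = _mat(self.Omega_omega)
        self.Omega_eta = _mat(self.Omega_eta)
        self.Q_list = [_mat(Q) for Q in self.Q_list]
        self.R = _mat(self.R)
        self.xhat1 = np.array(self.xhat1, dtype=float).reshape(-1)
        self.Sigma1 = _mat(self.Sigma1)

    @property
    def nx(self) -> int:
        return self.A.shape[0]

    @property
    def nu(self) -> int:
        return self.B.shape[1] if self.B.ndim == 2 else 1

    @property
    def ny(self) -> int:
        return self.H.shape[0]


def validate_model(model: SystemModel) -> list[str]:
    """Return one diagnostic message per violated model invariant.

    An empty list means the model is well formed.  The model is never
    mutated; failures are reported, not raised, so callers can present
    all problems at once.
    """
    msgs: list[str] = []
    nx, nu, ny = model.nx, model.nu, model.ny

    if model.n_steps < 2:
        msgs.append(f"n_steps must be >= 2, got {model.n_steps}")

    def shape(name: str, M: np.ndarray, want: tuple[int, ...]) -> bool:
        if M.shape != want:
            msgs.append(f"{name} has shape {M.shape}, expected {want}")
            return False
        return True

    shape("A", model.A, (nx, nx))
    shape("B", model.B, (nx, nu))
    shape("H", model.H, (ny, nx))
    for i, C in enumerate(model.C_list):
        shape(f"C_list[{i}]", C, (nx, nu))
    for i, D in enumerate(model.D_list):
        shape(f"D_list[{i}]", D, (ny, nx))
    shape("xhat1", model.xhat1, (nx,))

    if len(model.Q_list) != model.n_steps:
        msgs.append(
            f"Q_list has {len(model.Q_list)} entries, expected n_steps = {model.n_steps}"
        )

    for name, M, dim in [
        ("Omega_xi", model.Omega_xi, nx),
        ("Omega_omega", model.Omega_omega, ny),
        ("Omega_eta", model.Omega_eta, nx),
        ("Sigma1", model.Sigma1, nx),
    ] + [(f"Q_list[{i}]", Q, nx) for i, Q in enumerate(model.Q_list)]:
        if not shape(name, M, (dim, dim)):
            continue
        if _sym_defect(M) > 1e-9:
            msgs.append(f"{name} is not symmetric")
        elif _min_eig(M) < -PSD_TOL:
            msgs.append(f"{name} is not positive semidefinite (min eig {_min_eig(M):.3e})")

    if shape("R", model.R, (nu, nu)):
        if _sym_defect(model.R) > 1e-9:
            msgs.append("R is not symmetric")
        elif _min_eig(model.R) <= 0.0:
            msgs.append(f"R is not positive definite (min eig {_min_eig(model.R):.3e})")

    return msgs


@dataclass
class ReachingParams:
    """Parameters of the point-to-point reaching task.

    Time constants are in seconds (``tau1 = tau2 = 0.04`` s, i.e. 40 ms
    muscle filters), distances in metres, mass in kg.  The ``sigma_*``
    factors scale the five noise sources: control-dependent (``sigma_c``),
    additive state (``sigma_xi``), additive observation (``sigma_omega``),
    state-dependent observation (``sigma_d``) and internal estimation
    (``sigma_eta``).  The default set switches on only control-dependent
    noise (``sigma_c = 1.5``) with a nearly negligible control-cost weight
    ``r = 1e-10``, so accuracy at the target dominates the objective.
    """

    dt: float = 0.01
    m: float = 1.0
    tau1: float = 0.04
    tau2: float = 0.04
    t_end: float = 0.5
    p_star: float = 0.2
    omega_p: float = 0.02
    omega_v: float = 0.2
    omega_f: float = 1.0
    sigma_c: float = 1.5
    sigma_xi: float = 0.0
    sigma_omega: float = 0.0
    sigma_d: float = 0.0
    sigma_eta: float = 0.0
    r: float = 1e-10

    def check(self) -> None:
        """Raise ``ValueError`` on any invalid field."""
        for name in ("dt", "m", "tau1", "tau2", "t_end", "r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("sigma_c", "sigma_xi", "sigma_omega", "sigma_d", "sigma_eta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)}")
        ratio = self.t_end / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"t_end/dt = {ratio} is not an integer number of time steps"
            )

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt)) + 1


def build_reaching_model(params: ReachingParams) -> SystemModel:
    """Construct the 5-state reaching model for the given parameters.

    State vector: ``[p, p_dot, f, f_dot, p*]`` — hand position and velocity,
    muscle force and its derivative, and the (constant) target position.
    The control drives the force through a cascade of two first-order
    filters with time constants ``tau1``, ``tau2``.  The sensor reports
    position, velocity and force.  Only the terminal step carries state
    cost: ``Q_n = p p' + v v' + f f'`` with ``p = [1,0,0,0,-1]'``
    (position-minus-target error), ``v = [0,0.2,0,0,0]'`` (end velocity)
    and ``f = [0,0,0.02,0,0]'`` (end force).
    """
    params.check()
    dt, m, tau1, tau2 = params.dt, params.m, params.tau1, params.tau2
    n = params.n_steps

    A = np.array(
        [
            [1.0, dt, 0.0, 0.0, 0.0],
            [0.0, 1.0, dt / m, 0.0, 0.0],
            [0.0, 0.0, 1.0 - dt / tau2, dt / tau2, 0.0],
            [0.0, 0.0, 0.0, 1.0 - dt / tau1, 0.0],
            [0.0, 0.0, 0.0, 0.0, 1.0],
        ]
    )
    B = np.array([[0.0], [0.0], [0.0], [dt / tau1], [0.0]])
    C_list = [B * params.sigma_c]

    H = np.eye(3, 5)
    obs_scales = [params.omega_p, params.omega_v, params.omega_f]
    D_list = []
    for i, w in enumerate(obs_scales):
        D = np.zeros((3, 5))
        D[i, i] = params.sigma_d * w
        D_list.append(D)

    Omega_xi = params.sigma_xi**2 * np.eye(5)
    Omega_omega = np.diag([(params.sigma_omega * w) ** 2 for w in obs_scales])
    Omega_eta = params.sigma_eta**2 * np.eye(5)

    p = np.array([1.0, 0.0, 0.0, 0.0, -1.0])
    v = np.array([0.0, 0.2, 0.0, 0.0, 0.0])
    f = np.array([0.0, 0.0, 0.02, 0.0, 0.0])
    Q_n = np.outer(p, p) + np.outer(v, v) + np.outer(f, f)
    Q_list = [np.zeros((5, 5)) for _ in range(n - 1)] + [Q_n]

    return SystemModel(
        n_steps=n,
        A=A,
        B=B,
        C_list=C_list,
        H=H,
        D_list=D_list,
        Omega_xi=Omega_xi,
        Omega_omega=Omega_omega,
        Omega_eta=Omega_eta,
        Q_list=Q_list,
        R=np.array([[params.r]]),
        xhat1=np.array([0.0, 0.0, 0.0, 0.0, params.p_star]),
        Sigma1=np.zeros((5, 5)),
    )


# ---------------------------------------------------------------------------
# YAML configuration I/O.  Floats are serialised via Python's shortest
# round-trip repr, so write -> read reproduces every entry bit-exactly.

def save_params(params: ReachingParams, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(dataclasses.asdict(params), sort_keys=False)
    )


def load_params(path: str | Path) -> ReachingParams:
    data = yaml.safe_load(Path(path).read_text())
    return ReachingParams(**{k: float(v) for k, v in data.items()})


def save_model(model: SystemModel, path: str | Path) -> None:
    data = {
        "n_steps": model.n_steps,
        "A": model.A.tolist(),
        "B": model.B.tolist(),
        "C_list": [C.tolist() for C in model.C_list],
        "H": model.H.tolist(),
        "D_list": [D.tolist() for D in model.D_list],
        "Omega_xi": model.Omega_xi.tolist(),
        "Omega_omega": model.Omega_omega.tolist(),
        "Omega_eta": model.Omega_eta.tolist(),
        "Q_list": [Q.tolist() for Q in model.Q_list],
        "R": model.R.tolist(),
        "xhat1": model.xhat1.tolist(),
        "Sigma1": model.Sigma1.tolist(),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_model(path: str | Path) -> SystemModel:
    data = yaml.safe_load(Path(path).read_text())
    return SystemModel(**data)
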