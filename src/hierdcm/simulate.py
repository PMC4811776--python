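"""Forward simulation: bilinear neural dynamics -> balloon model -> noisy BOLD.

The neural model is the bilinear state equation
``dx/dt = [A + sum_j u_j B(j)] x + C u`` with driving inputs treated as
unit-weight Dirac impulses (instantaneous increments ``x += C w``) and
modulatory inputs as 0/1 epochs.  Synaptic activity is mapped to BOLD with
a standard balloon model (vasodilatory signal -> inflow -> volume and
deoxyhemoglobin -> observation equation), producing percent signal change
around a zero baseline.  Integration is fixed-step RK4 on a microtime grid
(default TR/16 = 0.125 s at TR = 2 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .design import Design, InputTimeline, build_input_timeline
from .regions import REGIONS


class SimulationDivergedError(RuntimeError):
    """Neural state exceeded the stability guard during integration."""


@dataclass
class DCMParameters:
    """Fixed connectivity A, modulations B(j), and input weights C.

    ``A`` is (n, n) in Hz with ``A[i, j]`` the influence of region j on
    region i; the diagonal must be strictly negative.  ``B`` maps each
    modulatory-channel name to an (n, n) matrix; ``C`` is (n, n_drive) in
    units of instantaneous state increment per unit-weight impulse.
    """

    regions: tuple[str, ...]
    A: np.ndarray
    B: dict[str, np.ndarray] = field(default_factory=dict)
    C: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.regions)
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (n, n):
            raise ValueError(f"A must be {(n, n)}, got {self.A.shape}")
        if np.any(np.diag(self.A) >= 0):
            raise ValueError("A diagonal must be strictly negative (stability)")
        self.B = {k: np.asarray(v, dtype=float) for k, v in self.B.items()}
        for k, v in self.B.items():
            if v.shape != (n, n):
                raise ValueError(f"B[{k!r}] must be {(n, n)}")
        if self.C is None:
            self.C = np.zeros((n, 0))
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim != 2 or self.C.shape[0] != n:
            raise ValueError("C must have one row per region")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def b_stack(self, mod_names: tuple[str, ...]) -> np.ndarray:
        """B matrices stacked in timeline channel order (zeros if absent)."""
        n = self.n_regions
        stack = np.zeros((len(mod_names), n, n))
        for j, name in enumerate(mod_names):
            if name in self.B:
                stack[j] = self.B[name]
        return stack


@dataclass
class HemodynamicParams:
    """Balloon-model constants (canonical values; not estimated here).

    kappa: vasodilatory signal decay (1/s); gamma: flow autoregulation
    (1/s); tau: mean transit time (s); alpha: vessel stiffness exponent;
    E0: resting oxygen extraction fraction; epsilon: per-region
    neurovascular efficacy (scalar or length-n array); V0: resting venous
    blood volume fraction.
    """

    kappa: float = 0.64
    gamma: float = 0.32
    tau: float = 2.0
    alpha: float = 0.32
    E0: float = 0.4
    epsilon: float | np.ndarray = 1.0
    V0: float = 0.04

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma", "tau", "E0", "V0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        eps = np.atleast_1d(np.asarray(self.epsilon, dtype=float))
        if np.any(eps <= 0):
            raise ValueError("epsilon must be strictly positive")

    def epsilon_vector(self, n: int) -> np.ndarray:
        eps = np.atleast_1d(np.asarray(self.epsilon, dtype=float))
        if eps.size == 1:
            return np.full(n, eps[0])
        if eps.size != n:
            raise ValueError("epsilon must be scalar or one value per region")
        return eps.astype(float)


@dataclass
class StateTrajectory:
    """Neural state on the microtime grid (post-impulse at each bin)."""

    dt: float
    x: np.ndarray  # (T, n)
    regions: tuple[str, ...]

    @property
    def n_steps(self) -> int:
        return self.x.shape[0]


@dataclass
class ContinuousBOLD:
    """Noise-free percent-signal-change BOLD on the microtime grid."""

    dt: float
    values: np.ndarray  # (T, n)
    regions: tuple[str, ...]


@dataclass
class ROITimeSeries:
    """Sampled ROI BOLD: one column per region, one row per scan."""

    tr: float
    data: np.ndarray  # (scans, n)
    regions: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.regions):
            raise ValueError("data must be (scans, regions)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ROI time series contains non-finite values")

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, columns=list(self.regions))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, tr: float = 2.0) -> "ROITimeSeries":
        df = pd.read_csv(path)
        return cls(tr=tr, data=df.to_numpy(dtype=float), regions=tuple(df.columns))


STABILITY_GUARD = 1e6


def integrate_neural(
    params: DCMParameters,
    timeline: InputTimeline,
    dt: float | None = None,
    x0: np.ndarray | None = None,
) -> StateTrajectory:
    """Integrate the bilinear neural ODE over a timeline with RK4.

    ``dt`` may refine the timeline grid (it must divide the timeline dt);
    the result is deterministic given the inputs.  Divergence beyond the
    stability guard (|x| > 1e6) raises SimulationDivergedError.
    """
    if dt is not None and dt > timeline.dt + 1e-12:
        raise ValueError("integration dt must not exceed the timeline dt")
    tl = timeline if dt is None else timeline.resample(dt)
    n = params.n_regions
    if x0 is None:
        x0 = np.zeros(n)
    x0 = np.asarray(x0, dtype=float)
    C = params.C
    if C.shape[1] != tl.drive.shape[1]:
        if np.allclose(C, 0.0) or C.shape[1] == 0:
            C = np.zeros((n, tl.drive.shape[1]))
        else:
            raise ValueError("C column count does not match driving channels")
    X, status = _kernels.neural_rk4(
        np.ascontiguousarray(params.A),
        np.ascontiguousarray(params.b_stack(tl.mod_names)),
        np.ascontiguousarray(C),
        np.ascontiguousarray(tl.drive),
        np.ascontiguousarray(tl.mod),
        x0,
        tl.dt,
        STABILITY_GUARD,
    )
    if status != 0:
        raise SimulationDivergedError(
            "neural state exceeded the stability guard; effective connectivity is unstable"
        )
    return StateTrajectory(dt=tl.dt, x=X, regions=params.regions)


def hemodynamic_response(
    traj: StateTrajectory,
    hemo: HemodynamicParams | None = None,
) -> ContinuousBOLD:
    """Map a neural trajectory through the balloon model to BOLD."""
    hemo = hemo or HemodynamicParams()
    n = traj.x.shape[1]
    Y = _kernels.hemo_rk4(
        np.ascontiguousarray(traj.x),
        traj.dt,
        hemo.kappa,
        hemo.gamma,
        hemo.tau,
        hemo.alpha,
        hemo.E0,
        hemo.epsilon_vector(n),
        hemo.V0,
    )
    return ContinuousBOLD(dt=traj.dt, values=Y, regions=traj.regions)


def sample_bold(
    bold: ContinuousBOLD,
    tr: float = 2.0,
    noise_sd: float = 0.0,
    noise_model: str = "white",
    ar_phi: float = 0.3,
    seed: int | None = None,
) -> ROITimeSeries:
    """Decimate continuous BOLD to the TR grid and add observation noise.

    ``noise_model`` is "white" (iid Gaussian) or "ar1" (stationary AR(1)
    with lag-1 autocorrelation ``ar_phi`` and marginal sd ``noise_sd``).
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be nonnegative")
    ratio = tr / bold.dt
    decim = int(round(ratio))
    if abs(ratio - decim) > 1e-9 or decim < 1:
        raise ValueError("TR must be an integer multiple of the microtime dt")
    data = bold.values[::decim].copy()
    data = _add_noise(data, noise_sd, noise_model, ar_phi, seed)
    return ROITimeSeries(tr=tr, data=data, regions=bold.regions)


def _add_noise(data: np.ndarray, noise_sd: float, noise_model: str, ar_phi: float, seed) -> np.ndarray:
    if noise_sd == 0:
        return data
    rng = np.random.default_rng(seed)
    if noise_model == "white":
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    elif noise_model == "ar1":
        if not (-1.0 < ar_phi < 1.0):
            raise ValueError("AR(1) phi must lie in (-1, 1)")
        innov_sd = noise_sd * np.sqrt(1.0 - ar_phi**2)
        e = rng.normal(0.0, innov_sd, size=data.shape)
        e[0] = rng.normal(0.0, noise_sd, size=data.shape[1])
        for t in range(1, data.shape[0]):
            e[t] += ar_phi * e[t - 1]
        data = data + e
    else:
        raise ValueError(f"unknown noise model {noise_model!r}")
    return data


def simulate_dataset(
    params: DCMParameters,
    hemo: HemodynamicParams | None = None,
    design: Design | None = None,
    timeline: InputTimeline | None = None,
    noise_sd: float = 0.0,
    noise_model: str = "white",
    ar_phi: float = 0.3,
    seed: int | None = None,
    dt: float = 0.125,
    tr: float = 2.0,
    trial_soa: float = 2.0,
) -> ROITimeSeries:
    """Full forward chain: design -> inputs -> neural -> BOLD -> sampling.

    Uses the joint neural-hemodynamic integrator (the same forward model
    the estimator inverts), then decimates to the TR grid and adds noise.
    """
    if timeline is None:
        if design is None:
            raise ValueError("either a design or a timeline is required")
        timeline = build_input_timeline(design, dt=dt, trial_soa=trial_soa)
    hemo = hemo or HemodynamicParams()
    ratio = tr / timeline.dt
    decim = int(round(ratio))
    if abs(ratio - decim) > 1e-9 or decim < 1:
        raise ValueError("TR must be an integer multiple of the microtime dt")
    n = params.n_regions
    C = params.C
    if C.shape[1] != timeline.drive.shape[1]:
        if np.allclose(C, 0.0) or C.shape[1] == 0:
            C = np.zeros((n, timeline.drive.shape[1]))
        else:
            raise ValueError("C column count does not match driving channels")
    bold, status = fast_forward(params.A, params.b_stack(timeline.mod_names), C, timeline, hemo, decim)
    if status != 0:
        raise SimulationDivergedError(
            "neural state exceeded the stability guard; effective connectivity is unstable"
        )
    data = _add_noise(bold.copy(), noise_sd, noise_model, ar_phi, seed)
    return ROITimeSeries(tr=tr, data=data, regions=params.regions)


def fast_forward(
    A: np.ndarray,
    Bstack: np.ndarray,
    C: np.ndarray,
    timeline: InputTimeline,
    hemo: HemodynamicParams,
    decim: int,
) -> tuple[np.ndarray, int]:
    """Low-level forward model used by the estimator's objective.

    Returns (bold at scan times, status flag); no exceptions are raised on
    divergence so optimizers can penalize unstable parameter proposals.
    """
    n = A.shape[0]
    return _kernels.simulate_bold_kernel(
        np.ascontiguousarray(A),
        np.ascontiguousarray(Bstack),
        np.ascontiguousarray(C),
        np.ascontiguousarray(timeline.drive),
        np.ascontiguousarray(timeline.mod),
        np.zeros(n),
        timeline.dt,
        decim,
        hemo.kappa,
        hemo.gamma,
        hemo.tau,
        hemo.alpha,
        hemo.E0,
        hemo.epsilon_vector(n),
        hemo.V0,
        STABILITY_GUARD,
    )


def fast_forward_jac(
    A: np.ndarray,
    Bstack: np.ndarray,
    C: np.ndarray,
    timeline: InputTimeline,
    hemo: HemodynamicParams,
    decim: int,
    directions: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, int]:
    """Forward model plus its exact Jacobian along encoded directions.

    ``directions`` is the (ptype, pri, prj, pmod, pcoef) encoding produced
    by the estimator's parameter map; the Jacobian is exact for the
    discrete integration scheme (forward-mode tangents).
    """
    n = A.shape[0]
    ptype, pri, prj, pmod, pcoef = directions
    return _kernels.simulate_bold_jac(
        np.ascontiguousarray(A),
        np.ascontiguousarray(Bstack),
        np.ascontiguousarray(C),
        np.ascontiguousarray(timeline.drive),
        np.ascontiguousarray(timeline.mod),
        np.zeros(n),
        timeline.dt,
        decim,
        hemo.kappa,
        hemo.gamma,
        hemo.tau,
        hemo.alpha,
        hemo.E0,
        hemo.epsilon_vector(n),
        hemo.V0,
        STABILITY_GUARD,
        ptype,
        pri,
        prj,
        pmod,
        pcoef,
    )


def default_regions() -> tuple[str, ...]:
    return REGIONS
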