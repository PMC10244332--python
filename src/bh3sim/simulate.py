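"""ODE integration, pre-treatment steady states, and the MOMP death readout.

Time is measured in hours throughout.  The permeabilization (MOMP) signal is
the summed concentration of pore species — the effector tetramers that
puncture the mitochondrial outer membrane.  Downstream caspase events are
treated as an inevitable consequence of crossing a MOMP threshold and are
not modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .network import NetworkModel

RTOL = 1e-6
ATOL = 1e-9


class IntegrationError(RuntimeError):
    """Integration failed; ``last_time`` carries the last successful time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last successful t={last_time:.4g} h)")
        self.last_time = last_time


class SteadyStateError(RuntimeError):
    """Run-to-convergence did not reach a steady state within ``t_max``."""


@dataclass
class Trajectory:
    """Time course of the full state: ``states[i]`` is the state at ``times[i]``."""

    times: np.ndarray  # hours, strictly increasing
    states: np.ndarray  # (time, species)
    model: NetworkModel

    def momp(self) -> np.ndarray:
        """MOMP signal (summed pore concentration) along the trajectory."""
        idx = self.model.pore_indices()
        if idx.size == 0:
            return np.zeros(len(self.times))
        return self.states[:, idx].sum(axis=1)

    def final_state(self) -> np.ndarray:
        return self.states[-1]


@dataclass
class SteadyState:
    state: np.ndarray
    residual_norm: float  # max-norm of the scaled RHS at ``state``
    momp_baseline: float


def momp_signal(model: NetworkModel, state: np.ndarray) -> float:
    """Total pore concentration (BAX tetramer + BAK tetramer) in ``state``."""
    idx = model.pore_indices()
    state = np.asarray(state, dtype=float)
    if idx.size == 0:
        return 0.0
    return float(state[idx].sum())


def _solver_kwargs(model: NetworkModel, rtol: float, atol: float) -> dict:
    f = model.rhs()
    jac = model.jacobian()
    return dict(
        fun=lambda t, x: f(np.maximum(x, 0.0)),
        jac=lambda t, x: jac(np.maximum(x, 0.0)),
        rtol=rtol,
        atol=atol,
    )


#: stiff methods tried in order; LSODA occasionally aborts on sharp
#: permeabilization transients where BDF succeeds.
_METHODS = ("LSODA", "BDF")


def simulate(
    model: NetworkModel,
    initial: np.ndarray,
    t_end: float,
    t_eval: np.ndarray | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate from ``initial`` over [0, t_end] with a stiff solver.

    The returned trajectory is deterministic given inputs; its first row is
    the supplied initial condition.  Small negative solver excursions are
    clipped to zero in the reported states.
    """
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (model.n_species,):
        raise ValueError(
            f"initial state must have length {model.n_species}, got {initial.shape}"
        )
    if np.any(initial < 0):
        raise ValueError("initial state must be nonnegative")
    kw = _solver_kwargs(model, rtol, atol)
    sol = None
    for method in _METHODS:
        with warnings.catch_warnings():
            # LSODA emits a UserWarning when it aborts; the BDF retry handles it
            warnings.filterwarnings("ignore", message="lsoda:")
            sol = solve_ivp(
                t_span=(0.0, float(t_end)), y0=initial, t_eval=t_eval, method=method, **kw
            )
        if sol.success:
            break
    if sol is None or not sol.success:
        last = sol.t[-1] if sol.t.size else 0.0
        raise IntegrationError(f"integration failed: {sol.message}", last)
    states = np.clip(sol.y.T, 0.0, None)
    states[0] = initial
    return Trajectory(times=sol.t, states=states, model=model)


def _scaled_residual(model: NetworkModel, x: np.ndarray) -> float:
    dx = model.rhs()(x)
    return float(np.max(np.abs(dx) / np.maximum(np.abs(x), 1.0)))


def steady_state(
    model: NetworkModel,
    initial: np.ndarray,
    tol: float = 1e-8,
    t_max: float = 1e6,
    t_chunk: float = 200.0,
) -> SteadyState:
    """Integrate to convergence: max|dx/dt| / max(|x|, 1) < ``tol``.

    Integration proceeds in geometrically growing chunks until the scaled
    residual drops below ``tol`` or ``t_max`` hours elapse.  Systems with
    unbalanced synthesis (zero degradation for a produced species) never
    converge and raise :class:`SteadyStateError`.
    """
    x = np.asarray(initial, dtype=float)
    t = 0.0
    chunk = t_chunk
    while t < t_max:
        traj = simulate(model, x, min(chunk, t_max - t), t_eval=None)
        x_new = traj.final_state()
        t += traj.times[-1]
        res = _scaled_residual(model, x_new)
        if res < tol:
            return SteadyState(
                state=x_new, residual_norm=res, momp_baseline=momp_signal(model, x_new)
            )
        # diverging state is a parameter pathology (e.g. no degradation)
        if not np.all(np.isfinite(x_new)):
            raise SteadyStateError("state diverged during equilibration")
        x = x_new
        chunk *= 2.0
    raise SteadyStateError(
        f"no steady state within t_max={t_max:g} h (residual {res:.3g}); "
        "check for species with synthesis but no matching removal"
    )
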