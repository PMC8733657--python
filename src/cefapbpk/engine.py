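"""Simulation orchestration and noncompartmental analysis.

``simulate`` integrates the 16-state disposition system — coupled, for oral
dosing, to the 20-state gut model — with a stiff-capable initial-value
solver (LSODA) at tight tolerances, and returns a dense :class:`SimResult`.
``pk_metrics`` derives the standard noncompartmental quantities: Cmax and
Tmax from the grid maximum, AUC by the trapezoid rule, AUC(0-inf) by adding
C_last/lambda_z with the terminal slope fitted log-linearly on the last
four points, MRT from the AUMC/AUC ratio, and for IV bolus runs
CL = Dose/AUC(0-inf) and Vss = Dose * AUMC / AUC^2.

Concentrations are reported in mg/L, numerically identical to ug/mL; the
two labels are used interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .params import DoseEvent, TISSUE_NAMES
from .systemic import (
    DispositionModel,
    IDX_ARTERIAL,
    IDX_ELIMINATED,
    IDX_VENOUS,
    N_SYSTEMIC,
    build_systemic_rhs,
    systemic_initial_state,
    tissue_index,
)
from . import gut as gut_mod
from .gut import GutModel, N_GUT, build_gut_rhs, gut_initial_state

__all__ = ["SimResult", "PKMetrics", "simulate", "pk_metrics"]


class SimulationError(RuntimeError):
    """Solver failure, annotated with the run's parameter context."""


@dataclass
class SimResult:
    """Dense simulated trajectory.

    ``states`` is (n_times, n_states); the first 16 columns are the
    systemic compartments, any further columns the gut state.
    """

    time: np.ndarray
    states: np.ndarray
    model: DispositionModel
    dose: DoseEvent
    gut: GutModel | None = None

    @property
    def plasma(self) -> np.ndarray:
        """Venous plasma concentration (mg/L == ug/mL)."""
        return self.states[:, IDX_VENOUS]

    @property
    def arterial(self) -> np.ndarray:
        return self.states[:, IDX_ARTERIAL]

    def tissue(self, name: str) -> np.ndarray:
        return self.states[:, tissue_index(name)]

    @property
    def eliminated(self) -> np.ndarray:
        return self.states[:, IDX_ELIMINATED]

    @property
    def gut_states(self) -> np.ndarray:
        if self.states.shape[1] <= N_SYSTEMIC:
            raise ValueError("not an oral simulation: no gut trajectory")
        return self.states[:, N_SYSTEMIC:]

    def compartment(self, name: str) -> np.ndarray:
        if name in ("plasma", "venous"):
            return self.plasma
        if name == "arterial":
            return self.arterial
        return self.tissue(name)

    def to_frame(self):
        """Long-format profile table: time_h, compartment, conc_ug_per_ml."""
        import pandas as pd

        frames = []
        for name in ("plasma", "arterial", *TISSUE_NAMES):
            frames.append(
                pd.DataFrame(
                    {
                        "time_h": self.time,
                        "compartment": name,
                        "conc_ug_per_ml": self.compartment(name),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def gut_to_frame(self):
        """Per-segment lumen time course: segment, time_h, dissolved_mg,
        undissolved_mg."""
        import pandas as pd

        g = self.gut_states
        n = len(gut_mod.SEGMENT_NAMES)
        frames = []
        for i, name in enumerate(gut_mod.SEGMENT_NAMES):
            frames.append(
                pd.DataFrame(
                    {
                        "segment": name,
                        "time_h": self.time,
                        "dissolved_mg": g[:, n + i],
                        "undissolved_mg": g[:, i],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def simulate(
    model: DispositionModel,
    gut: GutModel | None = None,
    dose: DoseEvent | None = None,
    t_end: float = 24.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_points: int | None = None,
) -> SimResult:
    """Run one IV-bolus or oral simulation and return the dense trajectory.

    IV doses are deposited in the venous pool at t = 0; oral doses in the
    stomach (dissolved for instant release, solid for first-order release).
    """
    if dose is None:
        raise ValueError("a DoseEvent is required")
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if dose.route == "oral" and gut is None:
        raise ValueError("oral dosing requires a gut model")

    sys_rhs = build_systemic_rhs(model)
    if dose.route == "iv_bolus":
        y0 = systemic_initial_state(model, iv_dose_mg=dose.amount)

        def rhs(t, y):
            return sys_rhs(t, y)

    else:
        g_rhs = build_gut_rhs(gut)
        y0 = np.concatenate(
            [systemic_initial_state(model), gut_initial_state(gut, dose.amount)]
        )

        def rhs(t, y):
            dg, absorbed_flux = g_rhs(t, y[N_SYSTEMIC:])
            dy = sys_rhs(t, y[:N_SYSTEMIC], gut_inflow_mg_h=absorbed_flux)
            return np.concatenate([dy, dg])

    # log-spaced grid: the distribution phase after an IV bolus is orders of
    # magnitude faster than the terminal phase, and the trapezoid AUC needs
    # both resolved
    if n_points is None:
        n_points = 501
    t_eval = np.concatenate([[0.0], np.geomspace(1e-4, t_end, n_points - 1)])
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(
            f"solver failed ({sol.message}) for {model.physiology.species} "
            f"{dose.route} {dose.amount} mg, t_end={t_end} h"
        )
    states = sol.y.T
    # tolerate solver-scale negative overshoot, fail on genuinely negative states
    floor = max(atol * 1e3, 1e-9 * float(np.max(np.abs(states))))
    if np.min(states) < -floor:
        raise SimulationError(
            f"negative state encountered (min {np.min(states):.3g}) for "
            f"{model.physiology.species} {dose.route} {dose.amount} mg"
        )
    return SimResult(time=sol.t, states=np.maximum(states, 0.0), model=model,
                     dose=dose, gut=gut)


# ---------------------------------------------------------------------------
# noncompartmental analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PKMetrics:
    """Noncompartmental summary of one concentration–time curve."""

    cmax: float
    tmax: float
    auc_0_t: float
    auc_0_inf: float
    mrt: float
    lambda_z: float | None
    extrapolated_fraction: float
    cl_nca: float | None = None
    vss_nca: float | None = None

    def __post_init__(self) -> None:
        if self.auc_0_inf + 1e-12 < self.auc_0_t:
            raise ValueError("AUC(0-inf) cannot be smaller than AUC(0-t)")


def _terminal_slope(t: np.ndarray, c: np.ndarray, n_points: int = 4):
    """lambda_z (1/h) by log-linear least squares on the last points with
    positive concentration; None when there is no terminal decline."""
    mask = c > 0
    t, c = t[mask], c[mask]
    if len(t) < n_points:
        return None
    t_fit, c_fit = t[-n_points:], np.log(c[-n_points:])
    slope = np.polyfit(t_fit, c_fit, 1)[0]
    if slope >= 0:
        return None
    return -slope


def pk_metrics(
    result_or_curve,
    compartment: str = "plasma",
    dose_mg: float | None = None,
    iv: bool | None = None,
) -> PKMetrics:
    """NCA metrics for a simulated result or a bare (time, conc) pair.

    CL and Vss are filled in only for IV-bolus curves (they require the full
    dose to reach the sampled circulation).  If the terminal slope cannot be
    estimated the extrapolation is refused and AUC(0-inf) = AUC(0-t) with
    ``lambda_z = None``.
    """
    if isinstance(result_or_curve, SimResult):
        t = result_or_curve.time
        c = result_or_curve.compartment(compartment)
        if dose_mg is None:
            dose_mg = result_or_curve.dose.amount
        if iv is None:
            iv = result_or_curve.dose.route == "iv_bolus"
    else:
        t, c = (np.asarray(x, dtype=float) for x in result_or_curve)
        iv = bool(iv)
    if len(t) < 2:
        raise ValueError("need at least two time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")

    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])
    auc_t = float(np.trapezoid(c, t))
    aumc_t = float(np.trapezoid(c * t, t))

    lam = _terminal_slope(t, c)
    if lam is None:
        auc_inf, aumc_inf, extrap = auc_t, aumc_t, 0.0
    else:
        c_last, t_last = float(c[-1]), float(t[-1])
        auc_inf = auc_t + c_last / lam
        aumc_inf = aumc_t + c_last * t_last / lam + c_last / lam**2
        extrap = (auc_inf - auc_t) / auc_inf if auc_inf > 0 else 0.0

    mrt = aumc_inf / auc_inf if auc_inf > 0 else float("nan")
    cl = vss = None
    if iv and dose_mg and auc_inf > 0:
        cl = dose_mg / auc_inf  # mg / (mg/L * h) = L/h
        vss = dose_mg * aumc_inf / auc_inf**2
    return PKMetrics(
        cmax=cmax,
        tmax=tmax,
        auc_0_t=auc_t,
        auc_0_inf=auc_inf,
        mrt=mrt,
        lambda_z=lam,
        extrapolated_fraction=extrap,
        cl_nca=cl,
        vss_nca=vss,
    )
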