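"""Perfusion-limited whole-body disposition model.

The body is 16 compartments: venous and arterial blood pools, lung, and 13
well-stirred tissues, each limited by its blood perfusion rate.  With a
blood:plasma concentration ratio of 1, blood and plasma concentrations
coincide throughout.  For each ordinary tissue

    V_t dC_t/dt = Q_t (C_art - C_t / Kp_t)

the venous outflow leaves at the tissue's unbound-equilibrium concentration
C_t/Kp_t.  The lung sits between the venous and arterial pools and sees the
whole cardiac output.  The spleen and the gut (portal) flow drain through
the liver; the hepatic artery makes up the difference to the tabulated total
liver outflow.  Orally absorbed drug enters the liver with the portal blood.
The kidney is the only eliminating organ.  The fitted renal clearance is a
*plasma* clearance (it was estimated as Dose/AUC from plasma profiles), so
it is applied to the mixed venous plasma pool the profiles are read from:
elimination rate = CL_renal * C_venous.  This makes the IV identity
AUC(0-inf) = Dose / CL_renal hold exactly for venous and arterial plasma
alike, and keeps every concentration non-negative for any clearance value
(a clearance flux drawn from a tissue compartment at rate CL * C_art would
drive that tissue negative as soon as CL exceeded its blood flow, which the
10x clearance sensitivity sweep does in all three species).

State layout (concentrations in mg/L == ug/mL, amounts in mg):
index 0 venous, 1 arterial, 2..14 the 13 tissues in ``TISSUE_NAMES`` order
(lung first), 15 cumulative amount eliminated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import DrugProperties, SpeciesPhysiology, TISSUE_NAMES

__all__ = [
    "N_SYSTEMIC",
    "IDX_VENOUS",
    "IDX_ARTERIAL",
    "IDX_ELIMINATED",
    "DispositionModel",
    "build_systemic_rhs",
    "mass_balance_check",
    "systemic_initial_state",
]

IDX_VENOUS = 0
IDX_ARTERIAL = 1
IDX_TISSUE0 = 2  # lung
IDX_ELIMINATED = 15
N_SYSTEMIC = 16

_ML_S_TO_L_H = 3.6  # mL/s -> L/h


def tissue_index(name: str) -> int:
    """State-vector index of a tissue concentration."""
    return IDX_TISSUE0 + TISSUE_NAMES.index(name)


@dataclass(frozen=True)
class DispositionModel:
    """A species physiology + drug pairing ready for simulation."""

    physiology: SpeciesPhysiology
    drug: DrugProperties

    @property
    def renal_clearance(self) -> float:
        return self.drug.renal_clearance

    @property
    def hepatic_artery_flow(self) -> float:
        return self.physiology.hepatic_artery_flow


def _arrays(model: DispositionModel):
    """Precompute flow/volume/Kp arrays in L and L/h."""
    phys = model.physiology
    v = np.array([t.volume for t in phys.tissues]) / 1000.0
    q = np.array([t.blood_flow for t in phys.tissues]) * _ML_S_TO_L_H
    kp = np.array([t.kp for t in phys.tissues])
    if np.any(kp <= 0):
        raise ValueError("all tissues need a positive Kp for simulation")
    return v, q, kp


def build_systemic_rhs(model: DispositionModel):
    """Return ``rhs(t, y, gut_inflow_mg_h=0.0) -> dy/dt`` for the 16-state
    disposition system.  ``gut_inflow_mg_h`` is the instantaneous absorption
    flux delivered to the liver with the portal blood."""
    phys = model.physiology
    v, q, kp = _arrays(model)
    v_ven = phys.venous_volume / 1000.0
    v_art = phys.arterial_volume / 1000.0
    # use the self-consistent cardiac output (sum of the distribution
    # flows); the tabulated lung/arterial/venous flow equals it only to its
    # printed rounding (~1e-5 relative), and that mismatch would leak mass
    q_co = phys.total_venous_inflow * _ML_S_TO_L_H
    q_gut = phys.gut_flow * _ML_S_TO_L_H
    cl = model.renal_clearance

    i_lung = TISSUE_NAMES.index("lung")
    i_liver = TISSUE_NAMES.index("liver")
    i_spleen = TISSUE_NAMES.index("spleen")
    q_liver_total = q[i_liver]
    q_ha = phys.hepatic_artery_flow * _ML_S_TO_L_H

    # tissues whose venous outflow goes straight to the venous pool
    direct = np.array(
        [i for i, name in enumerate(TISSUE_NAMES) if name not in ("lung", "spleen")]
    )

    def rhs(t: float, y: np.ndarray, gut_inflow_mg_h: float = 0.0) -> np.ndarray:
        c_ven = y[IDX_VENOUS]
        c_art = y[IDX_ARTERIAL]
        c = y[IDX_TISSUE0 : IDX_TISSUE0 + len(TISSUE_NAMES)]
        c_out = c / kp  # emergent venous concentration of each tissue

        dc = q * (c_art - c_out) / v  # generic perfusion-limited exchange

        # lung is perfused by the whole cardiac output from the venous pool
        dc[i_lung] = q_co * (c_ven - c_out[i_lung]) / v[i_lung]
        # liver: hepatic artery + spleen venous + portal (gut) blood + absorption
        liver_in = (
            q_ha * c_art
            + q[i_spleen] * c_out[i_spleen]
            + q_gut * c_art
            + gut_inflow_mg_h
        )
        dc[i_liver] = (liver_in - q_liver_total * c_out[i_liver]) / v[i_liver]
        # renal elimination: plasma clearance applied to the venous pool
        elim_rate = cl * c_ven

        dy = np.empty_like(y)
        dy[IDX_TISSUE0 : IDX_TISSUE0 + len(TISSUE_NAMES)] = dc
        dy[IDX_VENOUS] = (
            np.dot(q[direct], c_out[direct]) - q_co * c_ven - elim_rate
        ) / v_ven
        dy[IDX_ARTERIAL] = q_co * (c_out[i_lung] - c_art) / v_art
        dy[IDX_ELIMINATED] = elim_rate
        return dy

    return rhs


def systemic_initial_state(model: DispositionModel, iv_dose_mg: float = 0.0) -> np.ndarray:
    """Zero state, with an optional IV bolus deposited in the venous pool."""
    y0 = np.zeros(N_SYSTEMIC)
    if iv_dose_mg:
        y0[IDX_VENOUS] = iv_dose_mg / (model.physiology.venous_volume / 1000.0)
    return y0


def body_burden(model: DispositionModel, y: np.ndarray) -> float:
    """Amount of drug (mg) held in blood and tissues for one state vector."""
    v, _, _ = _arrays(model)
    amount = float(np.dot(v, y[IDX_TISSUE0 : IDX_TISSUE0 + len(TISSUE_NAMES)]))
    amount += y[IDX_VENOUS] * model.physiology.venous_volume / 1000.0
    amount += y[IDX_ARTERIAL] * model.physiology.arterial_volume / 1000.0
    return amount


def mass_balance_check(result, dose_mg: float) -> float:
    """Maximum relative mass-balance error over a simulated trajectory.

    At every time point the administered dose must equal body burden +
    amount eliminated (+ for oral runs: everything still in the gut lumen
    and everything excreted in faeces).  Returns max |residual| / dose;
    zero-dose runs return 0 by convention.
    """
    states = result.states
    if states.size == 0:
        raise ValueError("empty trajectory")
    if dose_mg == 0:
        return 0.0
    v = np.array([t.volume for t in result.model.physiology.tissues]) / 1000.0
    v_ven = result.model.physiology.venous_volume / 1000.0
    v_art = result.model.physiology.arterial_volume / 1000.0
    body = (
        states[:, IDX_TISSUE0 : IDX_TISSUE0 + len(TISSUE_NAMES)] @ v
        + states[:, IDX_VENOUS] * v_ven
        + states[:, IDX_ARTERIAL] * v_art
    )
    total = body + states[:, IDX_ELIMINATED]
    if states.shape[1] > N_SYSTEMIC:
        # oral run: add lumen + faecal amounts; the cumulative-absorbed
        # column (second to last) is already counted in body + eliminated
        gut = states[:, N_SYSTEMIC:]
        total = total + gut.sum(axis=1) - gut[:, -2]
    return float(np.max(np.abs(total - dose_mg)) / dose_mg)
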