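"""Segmental gastrointestinal transit and absorption model.

Nine serial lumen compartments — stomach, duodenum, jejunum 1–2, ileum 1–3,
caecum, ascending colon — each holding undissolved and dissolved drug mass.
Material moves down the chain by first-order transit at 1/transit_time.
Dissolved drug is absorbed by two parallel routes:

* passive permeation, first-order in dissolved mass with rate constant
  ``ka = 2 * Peff / r * passive_scale`` (cylindrical lumen surface-to-volume
  geometry), and
* saturable carrier-mediated uptake by the intestinal oligopeptide
  transporter PEPT1, a Michaelis–Menten flux
  ``Vmax * expression * C / (Km + C)`` distributed over the small-intestinal
  segments in proportion to their absolute PEPT1 expression content
  (zero in stomach, caecum and colon).

The carrier capacity carries a single dimensionless ``global_scale``
calibrated so the fraction absorbed of a standard oral dose reaches its
target; see :func:`calibrate_transporter_scale`.

Undissolved drug dissolves instantly or by first-order release
parameterized by T85% (time to 85% dissolved), gated off at the solubility
limit; supersaturated solution re-precipitates with the mean precipitation
time (inert for a drug this soluble at therapeutic doses — the lumen never
supersaturates).

Absorbed flux is handed to the liver through the portal inflow port of the
systemic model.  Gut state layout (mg): 9 undissolved, 9 dissolved,
cumulative absorbed, cumulative excreted in faeces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
import numpy as np

from .params import DrugProperties, ParameterError, read_params_file

__all__ = [
    "SEGMENT_NAMES",
    "N_GUT",
    "GutSegment",
    "TransporterKinetics",
    "DissolutionSpec",
    "GutModel",
    "load_human_gut",
    "transporter_flux",
    "passive_absorption_rate",
    "dissolution_transfer",
    "build_gut_rhs",
    "compute_fa",
    "calibrate_transporter_scale",
]

SEGMENT_NAMES: tuple[str, ...] = (
    "stomach",
    "duodenum",
    "jejunum1",
    "jejunum2",
    "ileum1",
    "ileum2",
    "ileum3",
    "caecum",
    "colon",
)

N_SEG = len(SEGMENT_NAMES)
#: gut state size: undissolved + dissolved per segment, absorbed, excreted
N_GUT = 2 * N_SEG + 2
IDX_ABSORBED = 2 * N_SEG
IDX_EXCRETED = 2 * N_SEG + 1

_S_TO_H = 3600.0


@dataclass(frozen=True)
class GutSegment:
    """One lumen compartment: transit time (h), radius/length (cm), resting
    fluid volume (mL), absolute PEPT1 expression (mg), passive scale."""

    name: str
    transit_time: float
    radius: float
    length: float
    fluid_volume: float
    pept1_expression: float
    passive_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.transit_time <= 0:
            raise ParameterError(f"{self.name}: transit time must be > 0")
        if self.radius <= 0 or self.length <= 0:
            raise ParameterError(f"{self.name}: geometry must be positive")
        if self.fluid_volume <= 0:
            raise ParameterError(f"{self.name}: fluid volume must be > 0")
        if self.pept1_expression < 0 or self.passive_scale < 0:
            raise ParameterError(f"{self.name}: expression/scale must be >= 0")


@dataclass(frozen=True)
class TransporterKinetics:
    """PEPT1 Michaelis–Menten kinetics: Km (mg/L), Vmax per mg of expressed
    transporter (ug/s/mg), and the calibrated global capacity multiplier."""

    km: float
    vmax_per_expression: float
    global_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.km <= 0:
            raise ParameterError("Km must be > 0")
        if self.vmax_per_expression < 0 or self.global_scale < 0:
            raise ParameterError("Vmax and global scale must be >= 0")


@dataclass(frozen=True)
class DissolutionSpec:
    """Dissolution mode: 'instant', or 'first_order' with T85% in hours."""

    mode: str = "instant"
    t85: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("instant", "first_order"):
            raise ParameterError(f"unknown dissolution mode {self.mode!r}")
        if self.mode == "first_order" and (self.t85 is None or self.t85 <= 0):
            raise ParameterError("first_order dissolution needs t85 > 0")

    @property
    def rate_constant(self) -> float:
        """First-order dissolution constant k_d = ln(1/0.15) / T85% (1/h)."""
        if self.mode != "first_order":
            raise ParameterError("rate constant defined only for first_order mode")
        return float(np.log(1.0 / 0.15) / self.t85)


@dataclass(frozen=True)
class GutModel:
    """Segments + transporter kinetics + dissolution + drug, ready to couple
    to the systemic model."""

    segments: tuple[GutSegment, ...]
    kinetics: TransporterKinetics
    dissolution: DissolutionSpec
    drug: DrugProperties
    pept1_enabled: bool = True

    def __post_init__(self) -> None:
        if not self.segments:
            raise ParameterError("segment list must not be empty")

    def with_scale(self, global_scale: float) -> "GutModel":
        return replace(self, kinetics=replace(self.kinetics, global_scale=global_scale))

    def without_transporter(self) -> "GutModel":
        return replace(self, pept1_enabled=False)

    def with_dissolution(self, spec: DissolutionSpec) -> "GutModel":
        return replace(self, dissolution=spec)


def load_human_gut(
    drug: DrugProperties,
    dissolution: DissolutionSpec | None = None,
    pept1_enabled: bool = True,
    overrides: dict[str, float] | None = None,
) -> GutModel:
    """Bundled fasted-human gut model (calibrated transporter scale)."""
    text = resources.files("cefapbpk.data").joinpath("gut_human.params").read_text()
    raw = read_params_file(text)
    if overrides:
        for key, value in overrides.items():
            if key not in raw:
                raise ParameterError(f"unknown gut override key {key!r}")
            raw[key] = repr(float(value))
    segments = tuple(
        GutSegment(
            name=name,
            transit_time=float(raw[f"{name}.transit_h"]),
            radius=float(raw[f"{name}.radius_cm"]),
            length=float(raw[f"{name}.length_cm"]),
            fluid_volume=float(raw[f"{name}.fluid_ml"]),
            pept1_expression=float(raw[f"{name}.pept1_mg"]),
            passive_scale=float(raw[f"{name}.passive_scale"]),
        )
        for name in SEGMENT_NAMES
    )
    kin = TransporterKinetics(
        km=float(raw["transporter.km_mg_l"]),
        vmax_per_expression=float(raw["transporter.vmax_ug_s_mg"]),
        global_scale=float(raw["transporter.global_scale"]),
    )
    return GutModel(
        segments=segments,
        kinetics=kin,
        dissolution=dissolution or DissolutionSpec("instant"),
        drug=drug,
        pept1_enabled=pept1_enabled,
    )


# ---------------------------------------------------------------------------
# elementary rate laws
# ---------------------------------------------------------------------------

def transporter_flux(
    c_lumen: float, segment: GutSegment, kin: TransporterKinetics
) -> float:
    """Carrier-mediated uptake flux (mg/h) at lumen concentration c (mg/L).

    Michaelis–Menten in concentration, scaled by the segment's PEPT1
    expression content and the calibrated global capacity multiplier.
    At c = Km the flux is exactly half its saturation plateau.
    """
    if c_lumen < 0:
        raise ValueError("negative lumen concentration")
    vmax_mg_h = (
        kin.global_scale
        * kin.vmax_per_expression
        * segment.pept1_expression
        * _S_TO_H
        / 1000.0
    )
    return vmax_mg_h * c_lumen / (kin.km + c_lumen)


def passive_absorption_rate(dissolved: float, segment: GutSegment, peff: float) -> float:
    """Passive transmucosal absorption (mg/h), first-order in dissolved mass.

    ka = (2 Peff / r) * passive_scale, the cylindrical surface-to-volume
    form, converted from 1/s to 1/h.
    """
    if segment.radius <= 0:
        raise ValueError("segment radius must be positive")
    if dissolved < 0:
        raise ValueError("negative dissolved mass")
    ka = 2.0 * peff / segment.radius * segment.passive_scale * _S_TO_H
    return ka * dissolved


def dissolution_transfer(
    undissolved: float,
    c_lumen: float,
    spec: DissolutionSpec,
    solubility_mg_ml: float,
) -> float:
    """Solid→solution transfer rate (mg/h).

    First-order release at k_d = ln(1/0.15)/T85%, throttled by the linear
    driving force (1 - C/Cs)+ so the rate closes continuously at the
    solubility limit.  Instant mode deposits the dose already dissolved and
    re-dissolves any precipitated solid with a fast rate constant.
    """
    if undissolved < 0:
        raise ValueError("negative undissolved mass")
    k_d = 500.0 if spec.mode == "instant" else spec.rate_constant
    driving = max(1.0 - c_lumen / (solubility_mg_ml * 1000.0), 0.0)
    return k_d * undissolved * driving


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def build_gut_rhs(gut: GutModel):
    """Return ``rhs(t, g) -> (dg/dt, absorbed_flux_mg_h)`` over the gut
    state vector (9 undissolved, 9 dissolved, absorbed, excreted)."""
    segs = gut.segments
    n = len(segs)
    k_transit = np.array([1.0 / s.transit_time for s in segs])
    v_fluid_l = np.array([s.fluid_volume for s in segs]) / 1000.0
    ka_passive = np.array(
        [2.0 * gut.drug.passive_peff / s.radius * s.passive_scale * _S_TO_H for s in segs]
    )
    ka_passive[0] = 0.0  # no absorption from the stomach
    kin = gut.kinetics
    vmax_mg_h = (
        kin.global_scale
        * kin.vmax_per_expression
        * np.array([s.pept1_expression for s in segs])
        * _S_TO_H
        / 1000.0
    )
    if not gut.pept1_enabled:
        vmax_mg_h = np.zeros(n)
    km = kin.km
    sol_mg_l = gut.drug.solubility * 1000.0
    first_order = gut.dissolution.mode == "first_order"
    # instant mode still needs a (fast) solid->solution path so that any
    # precipitated or solubility-capped material re-dissolves as absorption
    # frees up luminal capacity; 500/h makes dissolution never rate-limiting
    k_d = gut.dissolution.rate_constant if first_order else 500.0
    k_precip = _S_TO_H / gut.drug.mean_precipitation_time  # 1/h

    def rhs(t: float, g: np.ndarray):
        undis = g[:n]
        dis = g[n : 2 * n]
        c = np.maximum(dis, 0.0) / v_fluid_l  # mg/L

        # linear driving force (1 - C/Cs)+ closes the gate smoothly at the
        # solubility limit (a hard on/off gate makes the integrator chatter)
        dissolve = k_d * np.maximum(undis, 0.0) * np.maximum(1.0 - c / sol_mg_l, 0.0)
        # re-precipitation of any supersaturated solution (inert in practice)
        excess = np.maximum(dis - sol_mg_l * v_fluid_l, 0.0)
        precip = k_precip * excess

        passive = ka_passive * np.maximum(dis, 0.0)
        carrier = vmax_mg_h * c / (km + c)
        absorbed_flux = float(np.sum(passive + carrier))

        d_undis = -k_transit * undis - dissolve + precip
        d_undis[1:] += k_transit[:-1] * undis[:-1]
        d_dis = -k_transit * dis + dissolve - precip - passive - carrier
        d_dis[1:] += k_transit[:-1] * dis[:-1]

        dg = np.empty_like(g)
        dg[:n] = d_undis
        dg[n : 2 * n] = d_dis
        dg[IDX_ABSORBED] = absorbed_flux
        dg[IDX_EXCRETED] = k_transit[-1] * (undis[-1] + dis[-1])
        return dg, absorbed_flux

    return rhs


def gut_initial_state(gut: GutModel, oral_dose_mg: float) -> np.ndarray:
    """Dose deposited in the stomach: dissolved for instant mode, solid for
    first-order release."""
    g0 = np.zeros(N_GUT)
    if gut.dissolution.mode == "instant":
        g0[N_SEG] = oral_dose_mg  # stomach dissolved
    else:
        g0[0] = oral_dose_mg  # stomach undissolved
    return g0


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def compute_fa(result) -> float:
    """Fraction of the oral dose absorbed across the gut wall."""
    if result.dose.route != "oral":
        raise ValueError("fraction absorbed is defined for oral simulations only")
    if result.dose.amount == 0:
        return 0.0
    absorbed = result.gut_states[:, IDX_ABSORBED]
    return float(absorbed[-1] / result.dose.amount)


def calibrate_transporter_scale(
    model,
    gut: GutModel,
    dose,
    target_fa: float = 0.999,
    t_end: float = 48.0,
    bracket: tuple[float, float] = (0.0, 1e5),
    tol: float = 0.002,
    max_iter: int = 60,
) -> float:
    """Find the transporter capacity multiplier giving the target fraction
    absorbed, by bisection (Fa is monotone non-decreasing in the scale).

    Mirrors the original model-building step in which the carrier Vmax was
    optimized once against the oral data and then held fixed.
    """
    from .engine import simulate  # local import to avoid a cycle

    if not 0.0 < target_fa < 1.0:
        raise ValueError("target Fa must be in (0, 1)")

    def fa_at(scale: float) -> float:
        res = simulate(model, gut.with_scale(scale), dose, t_end=t_end)
        return compute_fa(res)

    lo, hi = bracket
    fa_lo = fa_at(lo)
    if fa_lo > target_fa:
        raise ValueError(
            f"passive-only Fa {fa_lo:.4f} already exceeds target {target_fa:.4f}"
        )
    fa_hi = fa_at(hi)
    if fa_hi < target_fa:
        raise ValueError(
            f"target Fa {target_fa:.4f} unreachable within bracket (max {fa_hi:.4f})"
        )
    # bisect to the crossing Fa(scale) = target; converging on the bracket
    # (not just |Fa - target|) matters because Fa saturates at 1 and any
    # huge capacity would otherwise satisfy a loose Fa tolerance
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fa_mid = fa_at(mid)
        if fa_mid < target_fa:
            lo = mid
        else:
            hi = mid
        if hi - lo <= tol * hi and abs(fa_mid - target_fa) <= 5 * tol:
            break
    return 0.5 * (lo + hi)
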