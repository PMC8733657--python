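"""Typed registry of species physiology, drug properties, and partition
coefficients.

All whole-body parameters live in bundled flat ``key = value`` files (one per
species, one for the drug, one for the Kp set) and are validated on load.
Flows are stored in mL/s and volumes in mL, as tabulated; the ODE layer
converts to L and hours.

Two closed-form quantities are derived here:

* the structural steady-state volume of distribution,
  ``Vss = sum_t Kp_t * V_t + (1 - Hct) * (V_arterial + V_venous)``,
  i.e. the Kp-weighted tissue volumes plus the *plasma* share of the two
  blood pools (with a blood:plasma ratio of 1, blood and plasma
  concentrations coincide, so the plasma convention is the consistent one);
* body weight from dose arithmetic (total dose / dose per kg), which is how
  the per-species body weights used in allometric scaling are fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "TISSUE_NAMES",
    "SPECIES",
    "TissueCompartment",
    "SpeciesPhysiology",
    "DrugProperties",
    "DoseEvent",
    "read_params_file",
    "load_kp",
    "load_drug_properties",
    "load_species_physiology",
    "derive_body_weight",
    "compute_pbpk_vss",
]

#: The 13 distribution tissues (lung included; the two blood pools are not
#: tissues).  Order is the state-vector order used by the ODE layer.
TISSUE_NAMES: tuple[str, ...] = (
    "lung",
    "adipose",
    "muscle",
    "liver",
    "spleen",
    "heart",
    "brain",
    "kidney",
    "skin",
    "repro_organ",
    "red_marrow",
    "yellow_marrow",
    "rest_of_body",
)

SPECIES: tuple[str, ...] = ("mouse", "rat", "human")


class ParameterError(ValueError):
    """Invalid or inconsistent model parameter."""


# ---------------------------------------------------------------------------
# flat key=value dialect
# ---------------------------------------------------------------------------

def read_params_file(path_or_text: str | Path) -> dict[str, str]:
    """Parse the flat ``key = value`` parameter dialect.

    Blank lines and ``#`` comments are ignored; keys may be dotted
    (``kidney.volume_ml``).  Returns raw string values; callers coerce.
    """
    if isinstance(path_or_text, Path):
        text = path_or_text.read_text()
    elif "\n" in path_or_text or "=" in path_or_text:
        text = path_or_text
    else:
        text = Path(path_or_text).read_text()
    out: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParameterError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if not key or not value:
            raise ParameterError(f"line {lineno}: empty key or value in {raw!r}")
        if key in out:
            raise ParameterError(f"line {lineno}: duplicate key {key!r}")
        out[key] = value
    return out


def _bundled(name: str) -> dict[str, str]:
    text = resources.files("cefapbpk.data").joinpath(name).read_text()
    return read_params_file(text)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueCompartment:
    """A perfusion-limited tissue: volume (mL), blood flow (mL/s), Kp."""

    name: str
    volume: float
    blood_flow: float
    kp: float

    def __post_init__(self) -> None:
        if self.name not in TISSUE_NAMES:
            raise ParameterError(f"unknown tissue {self.name!r}")
        if self.volume <= 0:
            raise ParameterError(f"{self.name}: volume must be > 0")
        if self.blood_flow < 0:
            raise ParameterError(f"{self.name}: blood flow must be >= 0")
        if self.kp < 0:
            raise ParameterError(f"{self.name}: Kp must be >= 0")


@dataclass(frozen=True)
class SpeciesPhysiology:
    """Whole-body physiology of one species.

    ``tissues`` holds the 13 distribution tissues in :data:`TISSUE_NAMES`
    order.  ``gut_flow`` is the portal (splanchnic) flow of the gut wall,
    which carries no distribution volume and drains into the liver;
    ``cardiac_output`` is the common lung/arterial/venous flow.
    """

    species: str
    tissues: tuple[TissueCompartment, ...]
    arterial_volume: float
    venous_volume: float
    cardiac_output: float
    gut_flow: float
    haematocrit: float
    body_weight: float

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ParameterError(f"unknown species {self.species!r}")
        if tuple(t.name for t in self.tissues) != TISSUE_NAMES:
            raise ParameterError("tissues must be the 13 canonical tissues in order")
        if not 0 < self.haematocrit < 1:
            raise ParameterError("haematocrit must be in (0, 1)")
        if self.body_weight <= 0:
            raise ParameterError("body weight must be > 0")
        for value, label in (
            (self.arterial_volume, "arterial volume"),
            (self.venous_volume, "venous volume"),
            (self.cardiac_output, "cardiac output"),
        ):
            if value <= 0:
                raise ParameterError(f"{label} must be > 0")
        if self.gut_flow < 0:
            raise ParameterError("gut flow must be >= 0")
        if self.hepatic_artery_flow < -1e-12:
            raise ParameterError("liver flow smaller than spleen + gut flow")
        total = self.total_venous_inflow
        if abs(total - self.cardiac_output) > 0.02 * self.cardiac_output:
            raise ParameterError(
                f"tissue flows ({total:.5g} mL/s) do not reconcile with "
                f"cardiac output ({self.cardiac_output:.5g} mL/s) within 2%"
            )

    @property
    def tissue(self) -> dict[str, TissueCompartment]:
        return {t.name: t for t in self.tissues}

    @property
    def lung(self) -> TissueCompartment:
        return self.tissues[0]

    @property
    def hepatic_artery_flow(self) -> float:
        """Arterial inflow to the liver: the tabulated liver flow is total
        hepatic outflow, from which the spleen and gut portal flows are
        subtracted."""
        t = {x.name: x for x in self.tissues}
        return t["liver"].blood_flow - t["spleen"].blood_flow - self.gut_flow

    @property
    def total_venous_inflow(self) -> float:
        """Sum of flows draining directly into the venous pool (all tissues
        except lung and spleen; spleen drains through the liver)."""
        return sum(
            t.blood_flow for t in self.tissues if t.name not in ("lung", "spleen")
        )

    def with_kp(self, kp: Mapping[str, float]) -> "SpeciesPhysiology":
        """Return a copy with tissue Kp values replaced from a mapping."""
        unknown = set(kp) - set(TISSUE_NAMES)
        if unknown:
            raise ParameterError(f"unknown tissue(s) in Kp map: {sorted(unknown)}")
        new = tuple(
            replace(t, kp=float(kp.get(t.name, t.kp))) for t in self.tissues
        )
        return replace(self, tissues=new)

    # -- serialization -----------------------------------------------------

    def to_params_text(self) -> str:
        lines = [
            f"species = {self.species}",
            f"body_weight_kg = {self.body_weight!r}",
            f"haematocrit = {self.haematocrit!r}",
            f"cardiac_output_ml_s = {self.cardiac_output!r}",
            f"arterial_volume_ml = {self.arterial_volume!r}",
            f"venous_volume_ml = {self.venous_volume!r}",
            f"gut.flow_ml_s = {self.gut_flow!r}",
        ]
        for t in self.tissues:
            lines.append(f"{t.name}.volume_ml = {t.volume!r}")
            lines.append(f"{t.name}.flow_ml_s = {t.blood_flow!r}")
            lines.append(f"{t.name}.kp = {t.kp!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_params_text(cls, text: str) -> "SpeciesPhysiology":
        raw = read_params_file(text)
        kp = {name: float(raw.pop(f"{name}.kp", "nan")) for name in TISSUE_NAMES}
        phys = _physiology_from_raw(raw)
        if all(k == k for k in kp.values()):  # all kp present (no NaN)
            phys = phys.with_kp(kp)
        return phys


@dataclass(frozen=True)
class DrugProperties:
    """Cefadroxil physicochemical and disposition properties.

    Units: MW g/mol, solubility mg/mL, Peff cm/s, precipitation time s,
    diffusion coefficient cm^2/s, particle density g/mL, renal clearance L/h.
    ``pka_list`` holds (value, "acid"|"base") pairs.
    """

    molecular_weight: float
    log_p: float
    pka_list: tuple[tuple[float, str], ...]
    fup: float
    blood_plasma_ratio: float
    solubility: float
    passive_peff: float
    mean_precipitation_time: float
    diffusion_coefficient: float
    particle_density: float
    renal_clearance: float

    def __post_init__(self) -> None:
        if not 0 < self.fup <= 1:
            raise ParameterError("fup must be in (0, 1]")
        for value, label in (
            (self.molecular_weight, "molecular weight"),
            (self.blood_plasma_ratio, "blood:plasma ratio"),
            (self.solubility, "solubility"),
            (self.mean_precipitation_time, "precipitation time"),
            (self.diffusion_coefficient, "diffusion coefficient"),
            (self.particle_density, "particle density"),
        ):
            if value <= 0:
                raise ParameterError(f"{label} must be > 0")
        if self.passive_peff < 0 or self.renal_clearance < 0:
            raise ParameterError("Peff and renal clearance must be >= 0")


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: route 'iv_bolus' or 'oral', amount in mg."""

    route: str
    amount: float
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.route not in ("iv_bolus", "oral"):
            raise ParameterError(f"unknown route {self.route!r}")
        if self.amount < 0 or self.time < 0:
            raise ParameterError("dose amount and time must be >= 0")


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------

def load_kp(overrides: Mapping[str, float] | None = None) -> dict[str, float]:
    """Bundled tissue:plasma partition coefficients (same for all species)."""
    kp = {name: float(v) for name, v in _bundled("kp.params").items()}
    if overrides:
        unknown = set(overrides) - set(TISSUE_NAMES)
        if unknown:
            raise ParameterError(f"unknown tissue(s): {sorted(unknown)}")
        kp.update({k: float(v) for k, v in overrides.items()})
    return kp


def load_drug_properties(
    species: str, overrides: Mapping[str, float] | None = None
) -> DrugProperties:
    """Bundled cefadroxil properties with the species' renal clearance."""
    if species not in SPECIES:
        raise ParameterError(f"unknown species {species!r}")
    raw = _bundled("drug.params")
    values: dict[str, float] = {
        "molecular_weight": float(raw["molecular_weight"]),
        "log_p": float(raw["log_p"]),
        "fup": float(raw["fup"]),
        "blood_plasma_ratio": float(raw["blood_plasma_ratio"]),
        "solubility": float(raw["solubility_mg_ml"]),
        "passive_peff": float(raw["passive_peff_cm_s"]),
        "mean_precipitation_time": float(raw["mean_precipitation_time_s"]),
        "diffusion_coefficient": float(raw["diffusion_coefficient_cm2_s"]),
        "particle_density": float(raw["particle_density_g_ml"]),
        "renal_clearance": float(raw[f"renal_clearance_l_h.{species}"]),
    }
    if overrides:
        unknown = set(overrides) - set(values)
        if unknown:
            raise ParameterError(f"unknown drug parameter(s): {sorted(unknown)}")
        values.update({k: float(v) for k, v in overrides.items()})
    pka = tuple(
        (float(raw[key]), "acid" if "acid" in key else "base")
        for key in sorted(k for k in raw if k.startswith("pka_"))
    )
    return DrugProperties(pka_list=pka, **values)


def _physiology_from_raw(raw: Mapping[str, str]) -> SpeciesPhysiology:
    tissues = tuple(
        TissueCompartment(
            name=name,
            volume=float(raw[f"{name}.volume_ml"]),
            blood_flow=float(raw[f"{name}.flow_ml_s"]),
            kp=1.0,
        )
        for name in TISSUE_NAMES
    )
    return SpeciesPhysiology(
        species=str(raw["species"]),
        tissues=tissues,
        arterial_volume=float(raw["arterial_volume_ml"]),
        venous_volume=float(raw["venous_volume_ml"]),
        cardiac_output=float(raw["cardiac_output_ml_s"]),
        gut_flow=float(raw["gut.flow_ml_s"]),
        haematocrit=float(raw["haematocrit"]),
        body_weight=float(raw["body_weight_kg"]),
    )


def load_species_physiology(
    species: str,
    overrides: Mapping[str, float] | None = None,
    kp: Mapping[str, float] | None = None,
) -> SpeciesPhysiology:
    """Load a species' physiology with bundled Kp values attached.

    ``overrides`` uses the dotted file keys (e.g. ``"kidney.volume_ml"``,
    ``"kidney.kp"``, ``"haematocrit"``); ``kp`` replaces partition
    coefficients wholesale after loading.
    """
    if species not in SPECIES:
        raise ParameterError(f"unknown species {species!r}")
    raw = dict(_bundled(f"{species}.params"))
    kp_map = load_kp()
    kp_overrides: dict[str, float] = {}
    if overrides:
        for key, value in overrides.items():
            tissue, _, attr = key.partition(".")
            if attr == "kp":
                if tissue not in TISSUE_NAMES:
                    raise ParameterError(f"unknown tissue in override {key!r}")
                kp_overrides[tissue] = float(value)
            elif key in raw:
                if float(value) <= 0 and key != "gut.flow_ml_s":
                    raise ParameterError(f"override {key!r} must be positive")
                raw[key] = repr(float(value))
            else:
                raise ParameterError(f"unknown override key {key!r}")
    phys = _physiology_from_raw(raw).with_kp(kp_map)
    if kp_overrides:
        phys = phys.with_kp(kp_overrides)
    if kp is not None:
        phys = phys.with_kp(kp)
    return phys


# ---------------------------------------------------------------------------
# closed-form derived quantities
# ---------------------------------------------------------------------------

def derive_body_weight(total_dose: float, dose_per_kg: float) -> float:
    """Body weight (kg) implied by a total dose (mg) and a per-kg dose
    (mg/kg)."""
    if total_dose <= 0 or dose_per_kg <= 0:
        raise ParameterError("doses must be > 0")
    return total_dose / dose_per_kg


def compute_pbpk_vss(phys: SpeciesPhysiology) -> float:
    """Structural steady-state volume of distribution in litres.

    ``Vss = sum_t Kp_t * V_t`` over the 13 tissues (lung included) plus the
    plasma fraction ``(1 - Hct)`` of the arterial and venous blood volumes.
    The gut wall carries no volume and is excluded.
    """
    tissue_sum = sum(t.kp * t.volume for t in phys.tissues)
    plasma = (1.0 - phys.haematocrit) * (phys.arterial_volume + phys.venous_volume)
    return (tissue_sum + plasma) / 1000.0


def export_parameter_table(phys: SpeciesPhysiology) -> "pandas.DataFrame":  # noqa: F821
    """Effective per-tissue parameter table (volume, flow, Kp) as a DataFrame."""
    import pandas as pd

    rows = [
        {"tissue": t.name, "volume_ml": t.volume, "flow_ml_s": t.blood_flow, "kp": t.kp}
        for t in phys.tissues
    ]
    return pd.DataFrame(rows)
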