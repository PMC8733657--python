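"""Whole-body PBPK model of cefadroxil in mouse, rat, and human.

A perfusion-limited 14-tissue + 2-blood-pool disposition model with renal
elimination, coupled for oral dosing to a nine-segment gastrointestinal
transit model with dissolution, passive permeation, and saturable
PEPT1-mediated uptake, plus the surrounding analysis workflow: fold-error
model qualification, noncompartmental PK metrics, clearance calibration,
parameter-sensitivity sweeps, allometric scaling, transporter-knockout and
dissolution-rate experiments.
"""

from .params import (
    DoseEvent,
    DrugProperties,
    SpeciesPhysiology,
    TissueCompartment,
    TISSUE_NAMES,
    compute_pbpk_vss,
    derive_body_weight,
    load_drug_properties,
    load_kp,
    load_species_physiology,
)
from .systemic import DispositionModel, build_systemic_rhs, mass_balance_check
from .gut import (
    DissolutionSpec,
    GutModel,
    GutSegment,
    TransporterKinetics,
    calibrate_transporter_scale,
    compute_fa,
    load_human_gut,
)
from .engine import PKMetrics, SimResult, pk_metrics, simulate
from .validation import (
    ObservedProfile,
    ValidationReport,
    aafe,
    acceptance_check,
    afe,
    fold_errors,
    validate_profile,
)
from .calibration import (
    AllometricFit,
    PSAResult,
    ReleaseRateComparison,
    allometric_fit,
    compare_release_rates,
    fit_clearance,
    psa_sweep,
)
from .synthetic import NoiseModel, generate_observed_profile, generate_tissue_timepoints

__version__ = "0.1.0"


def build_model(species: str, **overrides) -> DispositionModel:
    """Convenience: bundled physiology + drug for one species."""
    return DispositionModel(
        load_species_physiology(species), load_drug_properties(species)
    )
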