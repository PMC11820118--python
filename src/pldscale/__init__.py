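"""pldscale: scaling-law analysis of prion-like domain phase separation.

From slab density profiles to binodals, critical temperatures, fitted
mutation scaling laws and delta_Tc predictions, plus the aromatic
patterning order parameter sigma_aro and the Mpipi coarse-grained energy
terms. A synthetic-data module generates every input the pipeline
consumes.
"""

from importlib import resources as _resources

from .sequence_tools import (
    CANONICAL_RESIDUES,
    WEAK_REPLACEMENTS,
    ChargeModel,
    CompositionProfile,
    MutationSpec,
    PLDSequence,
    ResidueClass,
    RESIDUE_CLASSES,
    classify_residue,
    composition_profile,
    design_variant,
    format_variant_label,
    infer_mutation,
    parse_variant_label,
    read_fasta,
    write_fasta,
)
from .patterning import (
    PatterningResult,
    analyze_patterning,
    segment_stats,
    sigma_T,
    sigma_aro,
    sigma_max_profile,
    sticker_count,
)
from .mpipi_potential import (
    BeadConfiguration,
    EnergyBreakdown,
    MpipiParamTable,
    bond_energy,
    debye_kappa,
    electrostatic_energy,
    load_params,
    total_energy,
    wang_frenkel_energy,
)
from .binodal import (
    COEXISTENCE_EXPONENT,
    CoexistencePoint,
    CriticalPoint,
    DeltaTc,
    DensityProfile,
    PhaseDensities,
    delta_tc,
    extract_coexisting_densities,
    fit_critical_point,
    predict_binodal,
)
from .scaling import (
    Ansatz,
    PUBLISHED_LAWS,
    ScalingLaw,
    VariantObservation,
    ansatz_x,
    build_table1,
    cumulative_prediction,
    fit_scaling_constant,
    lookup_law,
    predict_delta_tc,
    select_ansatz,
)
from .synthetic_data import (
    BinodalTruth,
    FamilyTruth,
    ProfileTruth,
    SequenceTruth,
    synth_coexistence_points,
    synth_density_profile,
    synth_pld_sequence,
    synth_variant_family,
)
from .app import RunConfig, generate_synthetic_study, run_pipeline

__version__ = "0.1.0"


def example_param_table():
    """Path to the shipped synthetic Mpipi parameter fixture."""
    return _resources.files("pldscale").joinpath("data/mpipi_synthetic_params.yaml")
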