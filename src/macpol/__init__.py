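"""macpol: mechanistic multi-pathway model of macrophage M1/M2 polarization.

A reaction-network simulator for the integrated IFN-γ / IL-4 / hypoxia
signaling network of macrophages, with the perturbation semantics,
M1/M2 scoring, PRCC global sensitivity analysis and calibration/bootstrap
machinery used in its analysis workflows.
"""

from .model import (ModelDefinition, ParameterSet, RateLaw, ReactionDef,
                    SpeciesDef, assemble_rhs, structural_report)
from .simulate import (OxygenCondition, SimulationResult, StimulusEvent,
                       dose_to_copies, equilibrate, run_scenario)
from .scenarios import (NormalizationMode, PerturbationSpec, Scenario,
                        apply_perturbations, extract_markers, m1m2_score)
from .sensitivity import PRCCResult, SamplingPlan, lhs_sample, prcc, score_sensitivity
from .calibrate import (CalibDataset, CopyNumberPrior, FitResult, bootstrap_fit,
                        check_initial_conditions, fit, objective, pattern_search)
from .toys import ToySpec, make_synthetic_datasets, make_toy
from .fullmodel import (M1_PANEL, M2_PANEL, build_full_model,
                        default_copy_number_priors)
from .tables import load_model_tables, write_model_tables
from .sbml import read_sbml, write_sbml
from .presets import SCENARIO_PRESETS, get_preset
from .registry import build_calibration_registry, registry_summary

__version__ = "0.1.0"

__all__ = [
    "ModelDefinition", "ParameterSet", "RateLaw", "ReactionDef", "SpeciesDef",
    "assemble_rhs", "structural_report",
    "OxygenCondition", "SimulationResult", "StimulusEvent",
    "dose_to_copies", "equilibrate", "run_scenario",
    "NormalizationMode", "PerturbationSpec", "Scenario",
    "apply_perturbations", "extract_markers", "m1m2_score",
    "PRCCResult", "SamplingPlan", "lhs_sample", "prcc", "score_sensitivity",
    "CalibDataset", "CopyNumberPrior", "FitResult", "bootstrap_fit",
    "check_initial_conditions", "fit", "objective", "pattern_search",
    "ToySpec", "make_synthetic_datasets", "make_toy",
    "M1_PANEL", "M2_PANEL", "build_full_model", "default_copy_number_priors",
    "load_model_tables", "write_model_tables", "read_sbml", "write_sbml",
    "SCENARIO_PRESETS", "get_preset",
    "build_calibration_registry", "registry_summary",
    "load_model",
    "__version__",
]


def load_model(source):
    """Load a ModelDefinition from SBML (.xml), TSV tables, or 'full'."""
    from .cli import load_model as _load

    return _load(source)
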