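"""jcoupling: NMR scalar coupling constant prediction from 3D structures.

Atom-pair geometric descriptors plus toolkit molecular descriptors feed one
gradient-boosted regression model per coupling type (1J/2J/3J over HH, CH,
NH pairs).  See :class:`ScalarCouplingModel` for the main entry point.
"""

from .io import (
    COUPLING_TYPES,
    CouplingRecord,
    CouplingTable,
    FormatError,
    MolecularStructure,
    normalize_coupling_type,
    read_couplings_csv,
    read_structures_csv,
    read_xyz,
    write_predictions_csv,
    write_xyz,
)
from .graph import (
    BondGraph,
    bond_path_length,
    classify_coupling,
    enumerate_pairs,
    perceive_bonds,
)
from .descriptors import (
    DescriptorVector,
    FeaturizationError,
    SENTINEL_DISTANCE,
    feature_names,
    featurize,
    featurize_table,
    variance_filter,
)
from .model import (
    BoostingParams,
    MetricsReport,
    ModelBundle,
    ScalarCouplingModel,
    ScalarCouplingResults,
    evaluate,
    importance,
    predict,
    run_per_type_pipeline,
    split_by_molecule,
    train,
)
from .synthetic import (
    SimulatorParams,
    generate_structures,
    karplus_coupling,
    make_fixture_dataset,
    simulate_couplings,
    template_structure,
)

__version__ = "0.1.0"

__all__ = [
    "COUPLING_TYPES",
    "CouplingRecord",
    "CouplingTable",
    "FormatError",
    "MolecularStructure",
    "normalize_coupling_type",
    "read_couplings_csv",
    "read_structures_csv",
    "read_xyz",
    "write_predictions_csv",
    "write_xyz",
    "BondGraph",
    "bond_path_length",
    "classify_coupling",
    "enumerate_pairs",
    "perceive_bonds",
    "DescriptorVector",
    "FeaturizationError",
    "SENTINEL_DISTANCE",
    "feature_names",
    "featurize",
    "featurize_table",
    "variance_filter",
    "BoostingParams",
    "MetricsReport",
    "ModelBundle",
    "ScalarCouplingModel",
    "ScalarCouplingResults",
    "evaluate",
    "importance",
    "predict",
    "run_per_type_pipeline",
    "split_by_molecule",
    "train",
    "SimulatorParams",
    "generate_structures",
    "karplus_coupling",
    "make_fixture_dataset",
    "simulate_couplings",
    "template_structure",
]


def dataset_census(structures, couplings) -> dict:
    """Basic counts of a dataset: molecules, coupling records, records per type.

    Useful for checking a downloaded copy of the champs-scalar-coupling data
    against its published census (85003 molecules, 4 658 147 records,
    43363 of type 1JNH, ...).
    """
    per_type = {t: 0 for t in COUPLING_TYPES}
    for rec in couplings:
        per_type[rec.coupling_type] += 1
    return {
        "n_molecules": len(structures),
        "n_records": len(couplings),
        "per_type": per_type,
    }
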