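"""fuzzygrn — context-dependent gene regulatory networks as fuzzy
Petri-net transitions.

The package models gene regulatory interactions not as binary TF→TG edges
but as multi-input transitions gated by context signals, with
semi-quantitative (weak/medium/strong) effects on target expression,
literature evidence with a binding+expression confidence classification, a
fuzzy execution engine, and curation-completeness analytics based on
first-order Hill saturation.
"""

from importlib import resources

from .analytics import (
    CurationCurve,
    HillFit,
    HillSaturationModel,
    OverlapReport,
    SummaryTable,
    anchor_fit,
    articles_for,
    completeness,
    curation_curve,
    evidence_overlap,
    fit_hill,
    summarize,
)
from .curation import (
    ConfidenceLabel,
    EvidenceRecord,
    classify_confidence,
    discretize_fold_change,
    infer_transition_type,
)
from .engine import (
    EngineParams,
    FuzzyMembership,
    SimulationResult,
    SystemState,
    differential_response,
    fuzzify,
    simulate,
    step,
    transition_firing_degree,
)
from .io_formats import (
    FlatFileBundle,
    FlatFormatError,
    export_graphml,
    export_sbml_qual,
    parse_sbml_qual_topology,
    read_network,
    validate_sbml_qual,
    write_network,
)
from .model import (
    Entity,
    Network,
    RegulatoryState,
    Transition,
    TransitionInput,
    TransitionOutput,
    UnknownEntityError,
    Violation,
    ancestors,
    query_by_input,
    validate_network,
)
from .synth import SynthConfig, generate_network, make_table1_fixture, simulate_curation

__version__ = "0.1.0"


def load_pck1_fixture() -> Network:
    """The packaged PCK1 gluconeogenesis example network.

    PCK1 (PEP carboxykinase) is activated by CAT8, SIP4, RDS2, ERT1 and
    GSM1 only during growth on a non-fermentable carbon source (ethanol
    present, glucose absent); on glucose the gating context never holds, so
    a CAT8 knockout leaves PCK1 expression untouched.  Effect strengths and
    quote anchors in the fixture are illustrative, not curated values.
    """
    base = resources.files("fuzzygrn").joinpath("data/pck1")
    return read_network(
        FlatFileBundle(
            entities=base / "entities.tsv",
            transitions=base / "transitions.tsv",
            evidence=base / "evidence.tsv",
        )
    )
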