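"""casepy: computer-assisted structure elucidation from 13C-centric NMR data.

The package covers the backend chain of a CASE workflow: a
structure-and-spectrum knowledge base, dereplication by spectral matching,
a spherically grown fragment library with bit-string screening,
statistics-driven constraint detection, exhaustive constitutional-isomer
generation under correlation constraints, and HOSE-code shift prediction
with candidate ranking.
"""

from importlib import resources

from .chem_model import (
    Atom,
    HoseCode,
    MolecularFormula,
    MoleculeGraph,
    canonical_signature,
    hose_code,
    hybridization_of,
    parse_formula,
)
from .constraint_detection import (
    AtomConstraint,
    DetectionParams,
    detect_constraints,
    detect_hhb,
    detect_hybridizations,
    detect_neighbours,
)
from .dereplication import MatchParams, SpectrumMatch, dereplicate, match_spectra
from .fragment_library import (
    Fragment,
    ShiftBitset,
    fragment_record,
    rank_fragments,
    screen_fragments,
    subspectrum_bitset,
)
from .fixtures import FixtureSpec, make_fixture_kb
from .knowledge_base import (
    AssignedSignal,
    AssignedSpectrum,
    HoseLibrary,
    KbRecord,
    StatsStore,
    accumulate_statistics,
    assign_equivalence,
    build_hose_library,
    ingest_record,
    read_assigned_sdf,
    write_assigned_sdf,
)
from .peaklist import PeakListDocument, read_peaklist, write_peaklist
from .prediction_ranking import (
    PredictedSpectrum,
    RankedCandidate,
    predict_spectrum,
    rank_candidates,
)
from .structure_generation import (
    CorrelationSet,
    ElucidationProblem,
    build_problem,
    generate,
    problem_from_formula,
    verify_solution,
)

__version__ = "0.1.0"


def bundled_peaklist_path(name: str):
    """Path to one of the bundled synthetic query fixtures.

    Available names: ``testcase2_synthetic``, ``testcase15_synthetic``.
    """
    return resources.files("casepy.data") / f"{name}.json"
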