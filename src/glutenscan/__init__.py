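"""glutenscan — immunogenic gluten peptide profiling.

Filter and deduplicate peptide identifications, classify them into cereal
protein families, scan them against celiac-disease epitope / monoclonal
antibody / IgE motif inventories with perfect-match and exactly-one-mismatch
semantics (overlapping events counted), and compare the immunogenic load of
two flours. An in silico protease digester and a synthetic gliadin-like
proteome generator with planted ground truth make every stage testable
without any proteomic download.
"""

from importlib import resources

from .digestion import CLEAVAGE_RULES, DigestSpec, Fragment, cleavage_sites, digest
from .ingest import (
    FilterSpec,
    PeptideRecord,
    ProteinFamily,
    ReportParseError,
    UniquePeptideSet,
    classify_protein_family,
    count_family_peptides,
    filter_peptides,
    parse_peptide_report,
)
from .motifs import (
    MotifCategory,
    MotifDatabase,
    MotifParseError,
    MotifRecord,
    MotifValidationError,
    load_default_motif_db,
    load_motif_db,
    motifs_by_category,
    save_motif_db,
)
from .scan import (
    EventCountTable,
    FlourComparison,
    MatchEvent,
    MatchMode,
    compare_flours,
    count_events,
    read_event_table,
    scan_oracle,
    scan_peptide,
    write_event_table,
)
from .simulate import (
    GenerationError,
    GroundTruth,
    ScoreModel,
    SyntheticSpec,
    generate_peptide_report,
    generate_proteome,
    write_proteome_fasta,
)

__version__ = "0.1.0"

REFERENCE_SAMPLES = (
    "wheat_chymotrypsin",
    "tritordeum_chymotrypsin",
    "wheat_trypsin",
    "tritordeum_trypsin",
)


def load_reference_counts(sample: str) -> EventCountTable:
    """Load one of the packaged published event-count tables.

    These are the reported motif-event counts for white wheat and tritordeum
    flours under chymotrypsin/trypsin digestion; they let the two-flour
    comparison be reproduced without access to the underlying LC-MS/MS
    identifications. ``sample`` is one of :data:`REFERENCE_SAMPLES`.
    """
    if sample not in REFERENCE_SAMPLES:
        raise ValueError(f"unknown reference sample {sample!r}; one of {REFERENCE_SAMPLES}")
    ref = resources.files("glutenscan").joinpath(f"data/reference_counts/{sample}.tsv")
    with resources.as_file(ref) as p:
        return read_event_table(p)
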