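"""Peptide identification report ingestion, filtering and family sorting.

A peptide report is a tab-separated export of search-engine identifications,
one row per (peptide, protein) assignment, with an expectation score
(``pep_expect``; lower is more confident) and the protein's taxon and
free-text description. The standard study filters are applied here:

* keep identifications with ``pep_expect`` strictly below a threshold
  (default 0.05);
* keep only proteins annotated for the allowed cereal taxa (default
  *Triticum aestivum*, *Triticum turgidum* and *Hordeum* spp.);
* keep only proteins supported by more than one distinct peptide sequence
  (default: at least 2), evaluated after the score and taxon filters;
* deduplicate to unique peptide sequences.

Surviving unique peptides are classified into grain protein families
(omega-/alpha-/gamma-gliadins, HMW/LMW glutenin subunits, and the non-gluten
ATI / avenin / globulin / LTP / serpin classes) by a keyword table scanned
in a fixed precedence order.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .motifs import VALID_RESIDUES

__all__ = [
    "PeptideRecord",
    "FilterSpec",
    "UniquePeptideSet",
    "ProteinFamily",
    "ReportParseError",
    "parse_peptide_report",
    "filter_peptides",
    "classify_protein_family",
    "count_family_peptides",
    "load_family_keywords",
]

REPORT_COLUMNS = [
    "sequence",
    "protein_accession",
    "protein_description",
    "taxon",
    "pep_expect",
    "enzyme",
]

VALID_ENZYMES = ("chymotrypsin", "trypsin")


class ReportParseError(ValueError):
    """A peptide report file is malformed."""


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide identification row (one peptide-protein assignment)."""

    sequence: str
    protein_accession: str
    protein_description: str
    taxon: str
    pep_expect: float
    enzyme: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError("peptide sequence must be non-empty")
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"peptide {seq!r}: non-standard residues {sorted(bad)}"
            )
        if self.pep_expect < 0:
            raise ValueError(f"pep_expect must be >= 0, got {self.pep_expect}")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class FilterSpec:
    """Study filters applied to a peptide report.

    ``max_pep_expect`` is an exclusive threshold (a score exactly equal to it
    is rejected). ``min_peptides_per_protein`` counts distinct peptide
    sequences per accession among rows that already passed the score and
    taxon filters. ``allowed_taxa`` entries are matched case-insensitively as
    substrings so that e.g. ``"Hordeum"`` covers ``"Hordeum vulgare"`` and
    ``"Hordeum spp."``.
    """

    max_pep_expect: float = 0.05
    min_peptides_per_protein: int = 2
    allowed_taxa: tuple[str, ...] = ("Triticum aestivum", "Triticum turgidum", "Hordeum")

    def __post_init__(self) -> None:
        if self.max_pep_expect <= 0:
            raise ValueError("max_pep_expect must be > 0")
        if self.min_peptides_per_protein < 1:
            raise ValueError("min_peptides_per_protein must be >= 1")
        object.__setattr__(self, "allowed_taxa", tuple(self.allowed_taxa))

    def taxon_allowed(self, taxon: str) -> bool:
        t = taxon.lower()
        return any(pattern.lower() in t for pattern in self.allowed_taxa)


@dataclass
class UniquePeptideSet:
    """Filtered, deduplicated peptide sequences for one flour x enzyme sample.

    ``provenance`` maps each unique sequence to the surviving report rows it
    came from, so every sequence stays traceable.
    """

    sample_label: str
    sequences: list[str] = field(default_factory=list)
    provenance: dict[str, list[PeptideRecord]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("UniquePeptideSet sequences must be unique")
        for seq in self.sequences:
            if not self.provenance.get(seq):
                raise ValueError(f"sequence {seq!r} has no provenance records")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)


class ProteinFamily(str, enum.Enum):
    """Grain protein family, in match-precedence order (highest first)."""

    OMEGA_GLIADIN = "omega_gliadin"
    ALPHA_GLIADIN = "alpha_gliadin"
    GAMMA_GLIADIN = "gamma_gliadin"
    HMW_GLUTENIN = "HMW_glutenin"
    LMW_GLUTENIN = "LMW_glutenin"
    ATI = "ATI"
    AVENIN = "avenin"
    LTP = "LTP"
    SERPIN = "serpin"
    GLOBULIN = "globulin"
    OTHER = "other"


#: Precedence used when a peptide maps to several proteins of different
#: families: the first family in this order wins, keeping counts
#: deterministic.
FAMILY_PRECEDENCE: tuple[ProteinFamily, ...] = tuple(ProteinFamily)


def parse_peptide_report(path: Union[str, Path, io.TextIOBase]) -> list[PeptideRecord]:
    """Parse a tab-separated peptide report into records, one per row.

    No filtering is performed; row count is preserved. Comment lines
    (starting with ``#``) are ignored.

    Raises
    ------
    ReportParseError
        On a missing column, or a non-numeric ``pep_expect`` (the error
        names the offending 1-based data row).
    """
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", dtype=str, keep_default_na=False
        )
    except pd.errors.EmptyDataError:
        raise ReportParseError(f"{path}: empty file (no header row)") from None
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ReportParseError(f"{path}: missing column(s) {missing}")
    records: list[PeptideRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            score = float(getattr(row, "pep_expect"))
        except ValueError:
            raise ReportParseError(
                f"{path}: data row {i}: non-numeric pep_expect "
                f"{getattr(row, 'pep_expect')!r}"
            ) from None
        records.append(
            PeptideRecord(
                sequence=row.sequence,
                protein_accession=row.protein_accession,
                protein_description=row.protein_description,
                taxon=row.taxon,
                pep_expect=score,
                enzyme=row.enzyme,
            )
        )
    return records


def write_peptide_report(
    records: Iterable[PeptideRecord], path: Union[str, Path]
) -> None:
    """Write records back to the tab-separated report format."""
    rows = [
        (
            r.sequence,
            r.protein_accession,
            r.protein_description,
            r.taxon,
            repr(r.pep_expect) if isinstance(r.pep_expect, float) else r.pep_expect,
            r.enzyme,
        )
        for r in records
    ]
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def filter_peptides(
    records: Sequence[PeptideRecord],
    spec: FilterSpec = FilterSpec(),
    sample_label: str = "sample",
) -> UniquePeptideSet:
    """Apply the study filters and deduplicate to unique peptides.

    Order of operations: score filter (strict ``< max_pep_expect``), taxon
    filter, then protein-support filter (accessions backed by at least
    ``min_peptides_per_protein`` distinct surviving sequences), then
    deduplication. The result is independent of input row order: sequences
    are emitted in sorted order.
    """
    stage1 = [
        r
        for r in records
        if r.pep_expect < spec.max_pep_expect and spec.taxon_allowed(r.taxon)
    ]
    support: dict[str, set[str]] = {}
    for r in stage1:
        support.setdefault(r.protein_accession, set()).add(r.sequence)
    survivors = [
        r
        for r in stage1
        if len(support[r.protein_accession]) >= spec.min_peptides_per_protein
    ]
    provenance: dict[str, list[PeptideRecord]] = {}
    for r in survivors:
        provenance.setdefault(r.sequence, []).append(r)
    sequences = sorted(provenance)
    # sort provenance rows for order-independence of the full structure
    for seq in sequences:
        provenance[seq] = sorted(
            provenance[seq], key=lambda r: (r.protein_accession, r.pep_expect)
        )
    return UniquePeptideSet(
        sample_label=sample_label, sequences=sequences, provenance=provenance
    )


# --- protein family classification -----------------------------------------


def _default_keyword_path():
    return resources.files("glutenscan").joinpath("data/family_keywords.tsv")


def load_family_keywords(
    path: Union[str, Path, None] = None,
) -> list[tuple[ProteinFamily, str]]:
    """Load the keyword -> family table (tab-separated: family, keyword).

    Rows are returned in file order; classification scans them in family
    precedence order, then row order, and returns the first hit.
    """
    if path is None:
        ref = _default_keyword_path()
        with resources.as_file(ref) as p:
            return load_family_keywords(p)
    rows: list[tuple[ProteinFamily, str]] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fam_str, keyword = line.split("\t")
            rows.append((ProteinFamily(fam_str), keyword.strip().lower()))
    return rows


_DEFAULT_KEYWORDS: list[tuple[ProteinFamily, str]] | None = None


def _keyword_table() -> list[tuple[ProteinFamily, str]]:
    global _DEFAULT_KEYWORDS
    if _DEFAULT_KEYWORDS is None:
        _DEFAULT_KEYWORDS = load_family_keywords()
    return _DEFAULT_KEYWORDS


def classify_protein_family(
    description: str,
    keywords: Sequence[tuple[ProteinFamily, str]] | None = None,
) -> ProteinFamily:
    """Classify a protein description into exactly one family.

    The keyword table is scanned in family precedence order (omega > alpha >
    gamma gliadins > HMW > LMW glutenins > ATI > avenin > LTP > serpin >
    globulin); the first keyword contained (case-insensitively) in the
    description wins. Unmatched descriptions fall back to ``other``.
    """
    table = _keyword_table() if keywords is None else list(keywords)
    desc = description.lower()
    for family in FAMILY_PRECEDENCE:
        for fam, keyword in table:
            if fam is family and keyword in desc:
                return family
    return ProteinFamily.OTHER


def count_family_peptides(
    upset: UniquePeptideSet,
    keywords: Sequence[tuple[ProteinFamily, str]] | None = None,
) -> dict[ProteinFamily, int]:
    """Count unique peptides per protein family.

    Each unique peptide is counted exactly once. A peptide shared by proteins
    of different families is assigned to the highest-precedence family among
    its contributing proteins, so the counts always sum to the set size.
    """
    counts: dict[ProteinFamily, int] = {f: 0 for f in ProteinFamily}
    for seq in upset.sequences:
        families = {
            classify_protein_family(r.protein_description, keywords)
            for r in upset.provenance[seq]
        }
        best = min(families, key=FAMILY_PRECEDENCE.index)
        counts[best] += 1
    return counts
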