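"""Searchable immunological motif inventory.

The scanning stage of the pipeline looks for short amino-acid sequences of
immunological interest inside identified peptides: canonical celiac-disease
T-cell epitopes (9-mer cores, native glutamine forms), the innate-response
p31-43 alpha-gliadin peptide, the recognition sites of the R5 / G12 / A1
monoclonal antibodies used in gluten ELISA quantification, and IgE-binding
sites associated with wheat allergies (baker's asthma, WDEIA, atopic
dermatitis).

Motif sequences are data, not code: the packaged default database
(``data/motifs.tsv``) is a curated reconstruction from the cited literature,
each row carrying a source tag, and is fully user-replaceable via
:func:`load_motif_db`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

__all__ = [
    "MotifCategory",
    "MotifRecord",
    "MotifDatabase",
    "MotifValidationError",
    "MotifParseError",
    "VALID_RESIDUES",
    "load_motif_db",
    "load_default_motif_db",
    "motifs_by_category",
    "save_motif_db",
]

#: The 20 standard one-letter amino-acid codes.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class MotifCategory(str, enum.Enum):
    """Immunological category of a searchable motif."""

    CD_EPITOPE = "CD_epitope"
    P31_43 = "p31_43"
    MOAB_R5 = "moAb_R5"
    MOAB_G12 = "moAb_G12"
    MOAB_A1 = "moAb_A1"
    IGE_SITE = "IgE_site"

    @classmethod
    def coerce(cls, value: Union[str, "MotifCategory"]) -> "MotifCategory":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            raise MotifValidationError(
                f"unknown motif category {value!r}; expected one of "
                f"{[c.value for c in cls]}"
            ) from None


class MotifValidationError(ValueError):
    """A motif record or database violates an invariant."""


class MotifParseError(ValueError):
    """A motif file is malformed."""


@dataclass(frozen=True)
class MotifRecord:
    """One searchable motif.

    Parameters
    ----------
    motif_id : str
        Short unique identifier (e.g. ``DQ2.5-glia-a1a``).
    category : MotifCategory
        One of the six immunological categories.
    sequence : str
        Uppercase amino-acid string over the standard 20-letter alphabet.
        Lower-case input is upper-cased at construction; matching downstream
        is strict.
    source : str
        Free-text citation tag for provenance.
    """

    motif_id: str
    category: MotifCategory
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", MotifCategory.coerce(self.category))
        seq = self.sequence.upper()
        if not seq:
            raise MotifValidationError(f"motif {self.motif_id!r}: empty sequence")
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise MotifValidationError(
                f"motif {self.motif_id!r}: non-standard residues {sorted(bad)} "
                f"in sequence {seq!r}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MotifDatabase:
    """Ordered collection of :class:`MotifRecord` with uniqueness invariants.

    Duplicate motif ids and duplicate ``(category, sequence)`` pairs are
    rejected; record order is preserved (and is the order queries return).
    """

    records: list[MotifRecord] = field(default_factory=list)
    version: str = ""

    def __post_init__(self) -> None:
        seen_ids: set[str] = set()
        seen_pairs: set[tuple[MotifCategory, str]] = set()
        for rec in self.records:
            if rec.motif_id in seen_ids:
                raise MotifValidationError(f"duplicate motif_id {rec.motif_id!r}")
            pair = (rec.category, rec.sequence)
            if pair in seen_pairs:
                raise MotifValidationError(
                    f"duplicate (category, sequence) pair "
                    f"({rec.category.value}, {rec.sequence}) at motif "
                    f"{rec.motif_id!r}"
                )
            seen_ids.add(rec.motif_id)
            seen_pairs.add(pair)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_category(self, category: Union[str, MotifCategory]) -> list[MotifRecord]:
        cat = MotifCategory.coerce(category)
        return [r for r in self.records if r.category is cat]


_HEADER = ["motif_id", "category", "sequence", "source"]


def load_motif_db(path: Union[str, Path], version: str = "") -> MotifDatabase:
    """Load a motif database from a tab-separated file.

    The file must be UTF-8 with header ``motif_id<TAB>category<TAB>sequence
    <TAB>source``; lines starting with ``#`` and blank lines are ignored.
    Record order in the file is preserved.

    Raises
    ------
    MotifParseError
        Malformed row (wrong column count, missing header), with the
        offending 1-based line number.
    MotifValidationError
        Unknown category, invalid sequence alphabet, or duplicate records.
    """
    path = Path(path)
    records: list[MotifRecord] = []
    with path.open("r", encoding="utf-8") as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if [f.strip() for f in fields] != _HEADER:
                    expected = "\t".join(_HEADER)
                    raise MotifParseError(
                        f"{path}: line {lineno}: expected header "
                        f"{expected!r}, got {line!r}"
                    )
                header_seen = True
                continue
            if len(fields) != len(_HEADER):
                raise MotifParseError(
                    f"{path}: line {lineno}: expected {len(_HEADER)} "
                    f"tab-separated fields, got {len(fields)}"
                )
            motif_id, category, sequence, source = (f.strip() for f in fields)
            records.append(MotifRecord(motif_id, category, sequence, source))
        if not header_seen:
            raise MotifParseError(f"{path}: empty file (no header row)")
    return MotifDatabase(records=records, version=version or path.name)


def save_motif_db(db: MotifDatabase, path: Union[str, Path]) -> None:
    """Serialize a database back to the tab-separated interchange format."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for rec in db.records:
            fh.write(
                f"{rec.motif_id}\t{rec.category.value}\t{rec.sequence}\t{rec.source}\n"
            )


def load_default_motif_db() -> MotifDatabase:
    """Load the packaged default motif inventory.

    The default database covers all six categories; it is a literature-curated
    reconstruction (see the source tags per row) and is meant to be replaced
    by users with their own inventory where needed.
    """
    ref = resources.files("glutenscan").joinpath("data/motifs.tsv")
    with resources.as_file(ref) as p:
        return load_motif_db(p, version="glutenscan-default")


def motifs_by_category(
    db: MotifDatabase, category: Union[str, MotifCategory]
) -> list[MotifRecord]:
    """All records of ``category`` in load order (empty list allowed)."""
    return db.by_category(category)


def iter_categories() -> Iterable[MotifCategory]:
    return iter(MotifCategory)
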