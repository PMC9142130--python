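"""Synthetic gliadin-like proteomes with planted motifs and known truth.

The generator emulates the input the real study pipeline consumes — a flour
proteome digested into peptides and exported as an identification report —
but with complete ground truth: every motif occurrence is either *planted*
at a recorded position (optionally carrying exactly one random substitution)
or a background coincidence that a brute-force oracle can enumerate.

Background residues are drawn from a proline/glutamine-enriched composition
that mimics gliadin repeat regions. This matters: a Q/P-rich background can
produce chance matches for short motifs, so correctness downstream is always
defined against oracle enumeration over the generated peptides, never
against the planted positions alone.

All randomness flows from the single ``seed`` in :class:`SyntheticSpec`
(child streams are spawned deterministically for the proteome and the
report), so identical specs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .digestion import DigestSpec, Fragment, digest
from .ingest import FilterSpec, PeptideRecord, ProteinFamily, UniquePeptideSet, filter_peptides
from .motifs import MotifCategory, MotifDatabase, VALID_RESIDUES
from .scan import MatchEvent, MatchMode, scan_oracle

__all__ = [
    "SyntheticSpec",
    "ScoreModel",
    "SyntheticProtein",
    "SyntheticProteome",
    "Plant",
    "GroundTruth",
    "PeptideTruth",
    "GenerationError",
    "generate_proteome",
    "generate_peptide_report",
    "write_proteome_fasta",
    "write_ground_truth_tsv",
]


class GenerationError(RuntimeError):
    """Requested planting density cannot be satisfied without forbidden overlap."""


#: Gliadin-repeat-like background composition (Q/P-enriched), normalized at use.
BACKGROUND_COMPOSITION: dict[str, float] = {
    "Q": 0.365, "P": 0.160, "L": 0.070, "S": 0.050, "F": 0.040,
    "V": 0.040, "I": 0.040, "A": 0.030, "G": 0.030, "Y": 0.025,
    "T": 0.025, "N": 0.025, "E": 0.020, "H": 0.015, "R": 0.015,
    "K": 0.012, "C": 0.013, "M": 0.010, "D": 0.010, "W": 0.005,
}

#: Default family composition, gliadin-heavy as in a wheat flour extract.
DEFAULT_FAMILY_MIX: dict[ProteinFamily, float] = {
    ProteinFamily.ALPHA_GLIADIN: 0.25,
    ProteinFamily.GAMMA_GLIADIN: 0.15,
    ProteinFamily.OMEGA_GLIADIN: 0.08,
    ProteinFamily.HMW_GLUTENIN: 0.10,
    ProteinFamily.LMW_GLUTENIN: 0.10,
    ProteinFamily.ATI: 0.08,
    ProteinFamily.AVENIN: 0.04,
    ProteinFamily.GLOBULIN: 0.06,
    ProteinFamily.LTP: 0.05,
    ProteinFamily.SERPIN: 0.04,
    ProteinFamily.OTHER: 0.05,
}

#: Default planting intensity (expected motifs per protein, per category).
DEFAULT_PLANTED_DENSITY: dict[MotifCategory, float] = {
    MotifCategory.CD_EPITOPE: 1.0,
    MotifCategory.P31_43: 0.1,
    MotifCategory.MOAB_R5: 0.4,
    MotifCategory.MOAB_G12: 0.4,
    MotifCategory.MOAB_A1: 0.2,
    MotifCategory.IGE_SITE: 0.4,
}

FAMILY_DESCRIPTIONS: dict[ProteinFamily, str] = {
    ProteinFamily.OMEGA_GLIADIN: "omega-gliadin storage protein, synthetic",
    ProteinFamily.ALPHA_GLIADIN: "alpha-gliadin storage protein, synthetic",
    ProteinFamily.GAMMA_GLIADIN: "gamma-gliadin storage protein, synthetic",
    ProteinFamily.HMW_GLUTENIN: "high molecular weight glutenin subunit, synthetic",
    ProteinFamily.LMW_GLUTENIN: "low molecular weight glutenin subunit, synthetic",
    ProteinFamily.ATI: "alpha-amylase/trypsin inhibitor, synthetic",
    ProteinFamily.AVENIN: "avenin-like protein, synthetic",
    ProteinFamily.LTP: "non-specific lipid transfer protein, synthetic",
    ProteinFamily.SERPIN: "serpin, synthetic",
    ProteinFamily.GLOBULIN: "globulin, synthetic",
    ProteinFamily.OTHER: "uncharacterized protein, synthetic",
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic flour proteome."""

    n_proteins: int = 100
    family_mix: dict[ProteinFamily, float] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_MIX)
    )
    protein_length: tuple[int, int] = (200, 350)
    planted_density: dict[MotifCategory, float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_DENSITY)
    )
    substitution_rate: float = 0.0
    seed: int = 0
    allow_overlap: bool = False
    taxon: str = "Triticum aestivum"

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        total = sum(self.family_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"family_mix proportions sum to {total}, not 1")
        if not (0.0 <= self.substitution_rate <= 1.0):
            raise ValueError("substitution_rate must be in [0, 1]")
        lo, hi = self.protein_length
        if not (1 <= lo <= hi):
            raise ValueError("protein_length must be a valid (min, max) range")
        if any(d < 0 for d in self.planted_density.values()):
            raise ValueError("planted densities must be non-negative")


@dataclass(frozen=True)
class ScoreModel:
    """Expectation-score mixture attached to synthetic report rows.

    True fragments draw ``pep_expect`` uniformly from
    ``[true_low, true_high]``; for every true row an additional decoy row
    (shuffled sequence, its own accession) is emitted with probability
    ``decoy_fraction``, scored uniformly from ``[decoy_low, decoy_high]``.
    With the default bounds decoys always fail the 0.05 score filter, so the
    filter stage has real work to do.
    """

    true_low: float = 1e-4
    true_high: float = 0.04
    decoy_fraction: float = 0.1
    decoy_low: float = 0.05
    decoy_high: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.true_low <= self.true_high):
            raise ValueError("need 0 <= true_low <= true_high")
        if not (0 <= self.decoy_low <= self.decoy_high):
            raise ValueError("need 0 <= decoy_low <= decoy_high")
        if not (0.0 <= self.decoy_fraction <= 1.0):
            raise ValueError("decoy_fraction must be in [0, 1]")


@dataclass(frozen=True)
class Plant:
    """One planted motif occurrence in one protein."""

    protein_id: str
    motif_id: str
    category: MotifCategory
    position: int
    planted_sequence: str
    mutated: bool
    mutated_position: int | None


@dataclass(frozen=True)
class SyntheticProtein:
    protein_id: str
    family: ProteinFamily
    sequence: str

    @property
    def description(self) -> str:
        return FAMILY_DESCRIPTIONS[self.family]


@dataclass
class SyntheticProteome:
    spec: SyntheticSpec
    proteins: list[SyntheticProtein]

    def __iter__(self):
        return iter(self.proteins)

    def __len__(self):
        return len(self.proteins)


@dataclass
class GroundTruth:
    """Protein-level truth: where every motif was planted, and how."""

    plants: list[Plant] = field(default_factory=list)

    def plants_for(self, protein_id: str) -> list[Plant]:
        return [p for p in self.plants if p.protein_id == protein_id]


@dataclass(frozen=True)
class ContainedPlant:
    """A plant whose full window survived digestion inside one peptide."""

    plant: Plant
    peptide: str
    offset: int  # plant start within the peptide


@dataclass
class PeptideTruth:
    """Peptide-level truth after digestion, scoring and filtering.

    ``expected_events`` holds, per reported mode, the oracle-enumerated
    events over the surviving unique peptides x the full motif database —
    i.e. planted occurrences *and* background coincidences. ``contained``
    lists the plants whose windows survived intact inside some surviving
    peptide (a plant spanning a cleavage boundary with no covering fragment
    is excluded).
    """

    survivors: UniquePeptideSet
    contained: list[ContainedPlant] = field(default_factory=list)
    expected_events: dict[MatchMode, list[MatchEvent]] = field(default_factory=dict)
    motif_categories: dict[str, MotifCategory] = field(default_factory=dict)

    def expected_counts(self, mode: Union[str, MatchMode]) -> dict[MotifCategory, int]:
        """Oracle-expected event counts per category for ``mode``."""
        mode = MatchMode.coerce(mode)
        if mode not in self.expected_events:
            raise ValueError(f"no expected events computed for mode {mode.value}")
        out: dict[MotifCategory, int] = {c: 0 for c in MotifCategory}
        for e in self.expected_events[mode]:
            out[self.motif_categories[e.motif_id]] += 1
        return out


ALPHABET = np.array(sorted(VALID_RESIDUES), dtype="U1")


def _composition_vector() -> np.ndarray:
    probs = np.array([BACKGROUND_COMPOSITION[a] for a in ALPHABET], dtype=float)
    return probs / probs.sum()


def generate_proteome(
    spec: SyntheticSpec, db: MotifDatabase
) -> tuple[SyntheticProteome, GroundTruth]:
    """Generate a synthetic proteome with planted motif occurrences.

    Background residues are drawn from the Q/P-enriched composition, then
    motifs are planted at recorded, non-overlapping positions (overlap only
    when ``spec.allow_overlap``); with probability ``substitution_rate`` a
    plant carries exactly one random substitution at a recorded motif
    position. Plants never straddle protein termini; they may straddle
    cleavage sites (tracked later at the peptide level).

    Raises
    ------
    GenerationError
        If a protein cannot accommodate the drawn number of plants without
        forbidden overlap.
    """
    rng = np.random.default_rng([spec.seed, 0])
    probs = _composition_vector()
    active = [
        (cat, dens)
        for cat, dens in spec.planted_density.items()
        if dens > 0
    ]
    for cat, _ in active:
        if not db.by_category(cat):
            raise ValueError(
                f"motif database has no {MotifCategory.coerce(cat).value} records "
                "but a nonzero planting density was requested"
            )
    families = list(spec.family_mix)
    fam_probs = np.array([spec.family_mix[f] for f in families], dtype=float)
    fam_probs = fam_probs / fam_probs.sum()
    width = max(4, len(str(spec.n_proteins)))
    proteins: list[SyntheticProtein] = []
    plants: list[Plant] = []
    lo, hi = spec.protein_length
    for i in range(spec.n_proteins):
        pid = f"SYNP{i:0{width}d}"
        family = families[rng.choice(len(families), p=fam_probs)]
        length = int(rng.integers(lo, hi + 1))
        residues = rng.choice(ALPHABET, size=length, p=probs)
        occupied: list[tuple[int, int]] = []
        for cat, dens in active:
            category = MotifCategory.coerce(cat)
            k = int(rng.poisson(dens))
            motifs = db.by_category(category)
            for _ in range(k):
                motif = motifs[int(rng.integers(len(motifs)))]
                mlen = len(motif.sequence)
                if mlen > length:
                    raise GenerationError(
                        f"motif {motif.motif_id} longer than protein {pid}"
                    )
                placed = False
                for _try in range(200):
                    pos = int(rng.integers(0, length - mlen + 1))
                    if spec.allow_overlap or all(
                        pos + mlen <= s or pos >= e for s, e in occupied
                    ):
                        placed = True
                        break
                if not placed:
                    raise GenerationError(
                        f"could not place motif {motif.motif_id} in protein "
                        f"{pid} without overlap; lower planted_density or "
                        "set allow_overlap"
                    )
                occupied.append((pos, pos + mlen))
                planted = list(motif.sequence)
                mutated = bool(rng.random() < spec.substitution_rate)
                mut_pos: int | None = None
                if mutated:
                    mut_pos = int(rng.integers(mlen))
                    choices = [a for a in ALPHABET if a != planted[mut_pos]]
                    planted[mut_pos] = choices[int(rng.integers(len(choices)))]
                residues[pos : pos + mlen] = planted
                plants.append(
                    Plant(
                        protein_id=pid,
                        motif_id=motif.motif_id,
                        category=category,
                        position=pos,
                        planted_sequence="".join(planted),
                        mutated=mutated,
                        mutated_position=mut_pos,
                    )
                )
        proteins.append(SyntheticProtein(pid, family, "".join(residues)))
    return SyntheticProteome(spec=spec, proteins=proteins), GroundTruth(plants=plants)


def generate_peptide_report(
    proteome: SyntheticProteome,
    truth: GroundTruth,
    digest_spec: DigestSpec = DigestSpec(),
    score_model: ScoreModel = ScoreModel(),
    filter_spec: FilterSpec = FilterSpec(),
    db: MotifDatabase | None = None,
    sample_label: str = "synthetic",
    compute_expected_events: bool = True,
) -> tuple[list[PeptideRecord], PeptideTruth]:
    """Digest the proteome into a scored identification report, with truth.

    Each digestion fragment becomes one report row (accession, family-derived
    description, the proteome's taxon, a drawn ``pep_expect``, the digestion
    enzyme); decoy rows are injected per ``score_model``. The returned
    :class:`PeptideTruth` is restricted to peptides surviving ``filter_spec``
    and, when ``compute_expected_events`` and ``db`` are given, carries the
    oracle-enumerated expected events over those peptides.
    """
    rng = np.random.default_rng([proteome.spec.seed, 1])
    records: list[PeptideRecord] = []
    fragments: dict[str, list[Fragment]] = {}
    decoy_i = 0
    for prot in proteome:
        frags = digest(prot.sequence, digest_spec)
        fragments[prot.protein_id] = frags
        for frag in frags:
            score = float(rng.uniform(score_model.true_low, score_model.true_high))
            records.append(
                PeptideRecord(
                    sequence=frag.peptide,
                    protein_accession=prot.protein_id,
                    protein_description=prot.description,
                    taxon=proteome.spec.taxon,
                    pep_expect=score,
                    enzyme=digest_spec.enzyme,
                )
            )
            if rng.random() < score_model.decoy_fraction:
                shuffled = "".join(
                    rng.permutation(list(frag.peptide)).tolist()
                )
                decoy_score = float(
                    rng.uniform(score_model.decoy_low, score_model.decoy_high)
                )
                records.append(
                    PeptideRecord(
                        sequence=shuffled,
                        protein_accession=f"DECOY{decoy_i:06d}",
                        protein_description="decoy protein, synthetic",
                        taxon=proteome.spec.taxon,
                        pep_expect=decoy_score,
                        enzyme=digest_spec.enzyme,
                    )
                )
                decoy_i += 1
    survivors = filter_peptides(records, filter_spec, sample_label=sample_label)
    surviving = set(survivors.sequences)
    contained: list[ContainedPlant] = []
    for plant in truth.plants:
        mlen = len(plant.planted_sequence)
        for frag in fragments[plant.protein_id]:
            if (
                frag.start <= plant.position
                and plant.position + mlen <= frag.end
                and frag.peptide in surviving
            ):
                contained.append(
                    ContainedPlant(
                        plant=plant,
                        peptide=frag.peptide,
                        offset=plant.position - frag.start,
                    )
                )
                break
    ptruth = PeptideTruth(survivors=survivors, contained=contained)
    if compute_expected_events and db is not None:
        from .scan import REPORT_MODES

        ptruth.motif_categories = {m.motif_id: m.category for m in db}
        for mode in REPORT_MODES:
            events: list[MatchEvent] = []
            for motif in db:
                for pep in survivors:
                    events.extend(scan_oracle(pep, motif, mode))
            ptruth.expected_events[mode] = events
    return records, ptruth


def write_proteome_fasta(
    proteome: SyntheticProteome, path: Union[str, Path]
) -> None:
    """Write proteins as FASTA; the description carries family and taxon."""
    recs = [
        SeqRecord(
            Seq(p.sequence),
            id=p.protein_id,
            description=f"{p.description} [{proteome.spec.taxon}]",
        )
        for p in proteome
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_ground_truth_tsv(
    truth: GroundTruth, path: Union[str, Path], header_lines: Sequence[str] = ()
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("protein_id\tmotif_id\tcategory\tposition\tplanted_sequence\tmutated\tmutated_position\n")
        for p in truth.plants:
            mp = "" if p.mutated_position is None else str(p.mutated_position)
            fh.write(
                f"{p.protein_id}\t{p.motif_id}\t{p.category.value}\t{p.position}"
                f"\t{p.planted_sequence}\t{int(p.mutated)}\t{mp}\n"
            )
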