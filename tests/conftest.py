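import pytest

from glutenscan import (
    MotifCategory,
    MotifDatabase,
    MotifRecord,
    PeptideRecord,
    UniquePeptideSet,
    load_default_motif_db,
)


@pytest.fixture(scope="session")
def default_db() -> MotifDatabase:
    return load_default_motif_db()


def motif(seq: str, motif_id: str = "m1", category=MotifCategory.CD_EPITOPE) -> MotifRecord:
    return MotifRecord(motif_id=motif_id, category=category, sequence=seq, source="test")


def record(
    seq: str,
    accession: str = "P1",
    description: str = "alpha-gliadin",
    taxon: str = "Triticum aestivum",
    pep_expect: float = 0.001,
    enzyme: str = "chymotrypsin",
) -> PeptideRecord:
    return PeptideRecord(
        sequence=seq,
        protein_accession=accession,
        protein_description=description,
        taxon=taxon,
        pep_expect=pep_expect,
        enzyme=enzyme,
    )


def peptide_set(*seqs: str, label: str = "test") -> UniquePeptideSet:
    uniq = sorted(set(seqs))
    return UniquePeptideSet(
        sample_label=label,
        sequences=uniq,
        provenance={s: [record(s)] for s in uniq},
    )
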